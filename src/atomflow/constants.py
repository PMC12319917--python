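"""Single physical-constants table used by every module.

All estimators reference these symbols rather than hard-coding numbers so
that unit plumbing lives in one place.  Values come from scipy.constants
(CODATA 2018); atomic weights come from RDKit's periodic table (IUPAC
standard atomic weights).
"""

from __future__ import annotations

import scipy.constants as _sc

#: Boltzmann constant, J/K
K_B = _sc.k
#: elementary charge, C
E_CHARGE = _sc.e
#: Avogadro constant, 1/mol
N_A = _sc.N_A
#: Planck constant, J s
H_PLANCK = _sc.h
#: speed of light, m/s
C_LIGHT = _sc.c
#: atomic mass unit, kg
AMU = _sc.atomic_mass
#: 1 atm in Pa
ATM = _sc.atm

#: gas constant in kcal/(mol K)
R_KCAL = _sc.R / 4184.0
#: 1 kcal/mol in J (per molecule)
KCAL_MOL_TO_J = 4184.0 / N_A
#: 1 eV in kcal/mol
EV_TO_KCAL_MOL = _sc.e / KCAL_MOL_TO_J
#: Coulomb prefactor q_i q_j / r with q in e and r in Angstrom -> kcal/mol
COULOMB_KCAL = _sc.e**2 / (4.0 * _sc.pi * _sc.epsilon_0 * 1e-10) / KCAL_MOL_TO_J
#: Angstrom^2/fs -> m^2/s
A2_PER_FS_TO_M2_PER_S = 1e-20 / 1e-15
#: 1 cm^-1 in kcal/mol (h c nu_tilde)
CM1_TO_KCAL_MOL = H_PLANCK * C_LIGHT * 100.0 / KCAL_MOL_TO_J
#: kcal/mol/(A^2 amu) -> s^-2, the mass-weighted Hessian eigenvalue conversion
HESSIAN_EIG_TO_S2 = KCAL_MOL_TO_J / (1e-20 * AMU)

KB_KCAL = R_KCAL  # per-mole Boltzmann constant, kcal/(mol K)
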