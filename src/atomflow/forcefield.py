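"""Force-field files, SMARTS atom typing and classical energies/gradients.

The force-field file is a sectioned text format (``*.ff``).  Atom types are
defined by SMARTS substructure patterns; typing a configuration means
matching every rule against the molecular graph and giving each atom the
label of the best-matching rule (highest priority, then longest pattern,
then file order).  Energy terms:

* harmonic bonds ``k_b (r - r0)^2`` and angles ``k_theta (theta - theta0)^2``
* cosine-series torsions ``sum_n k_n (1 + cos(n phi - delta_n))``
* Lennard-Jones 12-6 with cutoff, minimum image and the analytic long-range
  tail correction for periodic systems
* cutoff Coulomb (no Ewald; documented inaccuracy for ionic systems)
* Buckingham ``A exp(-r/rho) - C/r^6`` for ion pairs

All energies are kcal/mol internally; Buckingham parameters may be supplied
in eV (``units = eV`` in the section header) and are converted on parse.
Gradients are analytic for every term and validated against central finite
differences in the test suite.

File format example::

    [types]
    # label  smarts  position  priority
    OH   [OX2H]   0   10
    HO   [OX2H][H]   1   10

    [bonds]
    # type_i  type_j  k(kcal/mol/A^2)  r0(A)
    OH HO  553.0  0.945

    [angles]
    # type_i type_j type_k  k(kcal/mol/rad^2)  theta0(deg)
    HO OH CT  55.0  108.5

    [torsions]
    # t1 t2 t3 t4  k(kcal/mol)  n  delta(deg)   (repeatable for a series)
    HC CT CT HC  0.15  3  0.0

    [nonbonded]
    # type  epsilon(kcal/mol)  sigma(A)  charge(e)
    OH  0.17  3.12  -0.683

    [buckingham]  units = eV
    # type_i type_j  A  rho(A)  C
    Li O  632.1018  0.2906  0.0
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from rdkit import Chem

from .builder import to_rdkit
from .constants import COULOMB_KCAL, EV_TO_KCAL_MOL
from .datamodel import Configuration
from .errors import TypingError, ValidationError


@dataclass(frozen=True)
class AtomTypeRule:
    """SMARTS-based typing rule: the atom at ``matched_position`` in the
    pattern receives ``type_label``."""

    type_label: str
    smarts: str
    matched_position: int = 0
    priority: int = 0

    def compiled(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValidationError(
                f"SMARTS {self.smarts!r} for type {self.type_label!r} does not compile"
            )
        if not 0 <= self.matched_position < patt.GetNumAtoms():
            raise ValidationError(
                f"matched_position {self.matched_position} out of range for "
                f"pattern {self.smarts!r}"
            )
        return patt


@dataclass(frozen=True)
class BuckinghamParams:
    """A exp(-r/rho) - C/r^6 parameters for one ion pair, kcal/mol and A."""

    A: float
    rho: float
    C: float

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValidationError("Buckingham rho must be positive")


@dataclass
class NonbondedSettings:
    """Cutoff scheme for the van der Waals and Coulomb terms."""

    cutoff: float = 10.0  # Angstrom
    tail_correction: bool = True  # applied only to periodic systems
    coulomb_treatment: str = "cutoff"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.coulomb_treatment != "cutoff":
            raise ValidationError("only cutoff Coulomb is supported")


@dataclass
class ForceField:
    """Parsed typing rules plus bonded/nonbonded parameter tables."""

    rules: list = field(default_factory=list)
    bonds: dict = field(default_factory=dict)     # (ti,tj) sorted -> (k, r0)
    angles: dict = field(default_factory=dict)    # (ti,tj,tk) canon -> (k, theta0 rad)
    torsions: dict = field(default_factory=dict)  # (t1..t4) canon -> [(k, n, delta rad)]
    lj: dict = field(default_factory=dict)        # type -> (eps, sigma)
    charges: dict = field(default_factory=dict)   # type -> charge (e)
    buckingham: dict = field(default_factory=dict)  # (ti,tj) sorted -> BuckinghamParams

    def lj_pair(self, ti: str, tj: str) -> tuple[float, float]:
        """Lorentz-Berthelot combination: geometric eps, arithmetic sigma."""
        ei, si = self.lj[ti]
        ej, sj = self.lj[tj]
        return math.sqrt(ei * ej), 0.5 * (si + sj)

    def buckingham_pair(self, ti: str, tj: str) -> Optional[BuckinghamParams]:
        return self.buckingham.get(tuple(sorted((ti, tj))))


def _canon2(a, b):
    return (a, b) if a <= b else (b, a)


def _canon3(a, b, c):
    return (a, b, c) if a <= c else (c, b, a)


def parse_forcefield(text: str) -> ForceField:
    """Parse the sectioned force-field text format (see module docstring)."""
    ff = ForceField()
    section = None
    section_units = {}
    seen_labels: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        # '#' begins a comment only at line start or after whitespace, so
        # SMARTS atomic-number primitives like [#1] survive
        line = re.sub(r"(^|\s)#.*$", "", raw).strip()
        if not line:
            continue
        if line.startswith("["):
            head, _, rest = line.partition("]")
            section = head.strip("[] ").lower()
            section_units[section] = "kcal/mol"
            if "units" in rest:
                section_units[section] = rest.split("=", 1)[1].strip()
            continue
        parts = line.split()
        try:
            if section == "types":
                label, smarts = parts[0], parts[1]
                pos = int(parts[2]) if len(parts) > 2 else 0
                prio = int(parts[3]) if len(parts) > 3 else 0
                if label in seen_labels and seen_labels[label] != smarts:
                    raise ValidationError(
                        f"type label {label!r} defined twice with different "
                        f"patterns ({seen_labels[label]!r} vs {smarts!r})"
                    )
                seen_labels[label] = smarts
                rule = AtomTypeRule(label, smarts, pos, prio)
                rule.compiled()  # fail fast on bad SMARTS
                ff.rules.append(rule)
            elif section == "bonds":
                ff.bonds[_canon2(parts[0], parts[1])] = (float(parts[2]), float(parts[3]))
            elif section == "angles":
                key = _canon3(parts[0], parts[1], parts[2])
                ff.angles[key] = (float(parts[3]), math.radians(float(parts[4])))
            elif section == "torsions":
                key = tuple(parts[:4])
                if key[::-1] < key:
                    key = key[::-1]
                ff.torsions.setdefault(key, []).append(
                    (float(parts[4]), int(parts[5]), math.radians(float(parts[6])))
                )
            elif section == "nonbonded":
                ff.lj[parts[0]] = (float(parts[1]), float(parts[2]))
                if len(parts) > 3:
                    ff.charges[parts[0]] = float(parts[3])
            elif section == "buckingham":
                scale = EV_TO_KCAL_MOL if section_units.get(section) == "eV" else 1.0
                ff.buckingham[_canon2(parts[0], parts[1])] = BuckinghamParams(
                    float(parts[2]) * scale, float(parts[3]), float(parts[4]) * scale
                )
            elif section is None:
                raise ValidationError("parameter line before any [section]")
            else:
                raise ValidationError(f"unknown section {section!r}")
        except (IndexError, ValueError) as exc:
            raise ValidationError(f"malformed line {lineno}: {raw!r} ({exc})") from exc
    return ff


def load_forcefield(path) -> ForceField:
    return parse_forcefield(Path(path).read_text())


def assign_atom_types(config: Configuration, ff: ForceField) -> Configuration:
    """Give every atom exactly one force-field type via SMARTS matching.

    Precedence among rules matching the same atom: highest priority, then
    longest SMARTS pattern, then earliest in the file.  Any atom left
    untyped is an error listing its index and element.
    """
    mol = to_rdkit(config)
    best: dict[int, tuple] = {}
    for order, rule in enumerate(ff.rules):
        patt = rule.compiled()
        for match in mol.GetSubstructMatches(patt, uniquify=False):
            idx = match[rule.matched_position]
            rank = (rule.priority, len(rule.smarts), -order)
            if idx not in best or rank > best[idx][0]:
                best[idx] = (rank, rule.type_label)
    untyped = [i for i in range(config.n_atoms) if i not in best]
    if untyped:
        detail = ", ".join(f"{i} ({config.atom_set[i].element})" for i in untyped)
        raise TypingError(f"no typing rule matches atoms: {detail}")
    for i, atom in enumerate(config.atom_set):
        atom.ff_type = best[i][1]
        if best[i][1] in ff.charges:
            atom.partial_charge = ff.charges[best[i][1]]
    return config


def buckingham_energy(r: float, params: BuckinghamParams) -> float:
    """phi(r) = A exp(-r/rho) - C/r^6, in the parameter energy unit."""
    if r <= 0:
        raise ValidationError("Buckingham distance must be positive")
    return params.A * math.exp(-r / params.rho) - params.C / r**6


# ---------------------------------------------------------------------------
# nonbonded energy + gradient
# ---------------------------------------------------------------------------

def _pair_vectors(config: Configuration):
    """All i<j displacement vectors under minimum image (orthorhombic)."""
    x = config.coordinates
    n = len(x)
    ii, jj = np.triu_indices(n, k=1)
    d = x[ii] - x[jj]
    if config.cell.periodic:
        box = config.cell.lengths
        d -= box * np.round(d / box)
    return ii, jj, d


def lj_tail_correction(counts: dict[str, int], ff: ForceField, volume: float,
                       cutoff: float) -> float:
    """Analytic LJ tail beyond the cutoff, summed over type pairs.

    U_tail = sum_ab (8/3) pi (N_a N_b / V) eps_ab sigma_ab^3
             [ (1/3)(sigma_ab/r_c)^9 - (sigma_ab/r_c)^3 ]
    """
    total = 0.0
    types = sorted(counts)
    for ti in types:
        for tj in types:
            eps, sig = ff.lj_pair(ti, tj)
            sr3 = (sig / cutoff) ** 3
            total += (8.0 / 3.0) * math.pi * counts[ti] * counts[tj] / volume \
                * eps * sig**3 * (sr3**3 / 3.0 - sr3)
    return total


def nonbonded_energy(
    config: Configuration,
    settings: NonbondedSettings,
    ff: ForceField,
    exclude_bonded: bool = True,
) -> tuple[float, np.ndarray]:
    """LJ + Coulomb within the cutoff (minimum image) with optional tail.

    Excludes 1-2 and 1-3 pairs when ``exclude_bonded``.  Returns energy
    (kcal/mol) and the per-atom gradient (kcal/mol/A).
    """
    if config.cell.periodic:
        half = config.cell.lengths.min() / 2.0
        if settings.cutoff > half + 1e-9:
            raise ValidationError(
                f"cutoff {settings.cutoff} exceeds half the shortest cell "
                f"edge ({half:.4f})"
            )
    types = [a.ff_type for a in config.atom_set]
    if any(t is None for t in types):
        raise TypingError("configuration must be typed before energy evaluation")
    charges = np.array([a.partial_charge or 0.0 for a in config.atom_set])

    ii, jj, d = _pair_vectors(config)
    r2 = (d * d).sum(axis=1)
    mask = r2 < settings.cutoff**2
    if exclude_bonded:
        from .datamodel import topology  # local import to avoid cycle at import time

        excluded = {b.key for b in config.bond_set}
        for (a, _, c) in topology(config)[0]:
            excluded.add((a, c) if a < c else (c, a))
        if excluded:
            keys = ii.astype(np.int64) * config.n_atoms + jj
            excl = np.array([i * config.n_atoms + j for i, j in excluded])
            mask &= ~np.isin(keys, excl)
    ii, jj, d, r2 = ii[mask], jj[mask], d[mask], r2[mask]
    r = np.sqrt(r2)

    eps = np.empty(len(ii))
    sig = np.empty(len(ii))
    buck = np.zeros((len(ii), 3))  # A, rho, C rows; zero when LJ applies
    is_buck = np.zeros(len(ii), dtype=bool)
    pair_cache: dict[tuple, tuple] = {}
    for k, (a, b) in enumerate(zip(ii, jj)):
        key = _canon2(types[a], types[b])
        if key not in pair_cache:
            bp = ff.buckingham.get(key)
            if bp is not None:
                pair_cache[key] = ("buck", bp.A, bp.rho, bp.C)
            else:
                e, s = ff.lj_pair(*key)
                pair_cache[key] = ("lj", e, s, 0.0)
        kind, p1, p2, p3 = pair_cache[key]
        if kind == "buck":
            is_buck[k] = True
            buck[k] = (p1, p2, p3)
            eps[k] = sig[k] = 0.0
        else:
            eps[k], sig[k] = p1, p2

    energy = 0.0
    grad = np.zeros((config.n_atoms, 3))
    # Lennard-Jones
    lj_sel = ~is_buck
    if lj_sel.any():
        sr6 = (sig[lj_sel] / r[lj_sel]) ** 6
        e_lj = 4.0 * eps[lj_sel] * (sr6**2 - sr6)
        energy += e_lj.sum()
        # dU/dr = 4 eps (-12 sr12 + 6 sr6)/r
        dudr = 4.0 * eps[lj_sel] * (-12.0 * sr6**2 + 6.0 * sr6) / r[lj_sel]
        gvec = (dudr / r[lj_sel])[:, None] * d[lj_sel]
        np.add.at(grad, ii[lj_sel], gvec)
        np.add.at(grad, jj[lj_sel], -gvec)
    # Buckingham
    if is_buck.any():
        A, rho, C = buck[is_buck].T
        rb = r[is_buck]
        e_b = A * np.exp(-rb / rho) - C / rb**6
        energy += e_b.sum()
        dudr = -A / rho * np.exp(-rb / rho) + 6.0 * C / rb**7
        gvec = (dudr / rb)[:, None] * d[is_buck]
        np.add.at(grad, ii[is_buck], gvec)
        np.add.at(grad, jj[is_buck], -gvec)
    # Coulomb (cutoff)
    qq = charges[ii] * charges[jj]
    sel = qq != 0.0
    if sel.any():
        e_c = COULOMB_KCAL * qq[sel] / r[sel]
        energy += e_c.sum()
        dudr = -COULOMB_KCAL * qq[sel] / r2[sel]
        gvec = (dudr / r[sel])[:, None] * d[sel]
        np.add.at(grad, ii[sel], gvec)
        np.add.at(grad, jj[sel], -gvec)
    # tail correction
    if settings.tail_correction and config.cell.periodic:
        counts: dict[str, int] = {}
        for t in types:
            if t in ff.lj:
                counts[t] = counts.get(t, 0) + 1
        if counts:
            energy += lj_tail_correction(counts, ff, config.cell.volume,
                                         settings.cutoff)
    return float(energy), grad


# ---------------------------------------------------------------------------
# bonded energy + gradient
# ---------------------------------------------------------------------------

def bonded_energy(config: Configuration, ff: ForceField) -> tuple[float, np.ndarray]:
    """Harmonic bonds/angles plus cosine-series torsions; analytic gradient."""
    from .datamodel import topology

    types = [a.ff_type for a in config.atom_set]
    if any(t is None for t in types):
        raise TypingError("configuration must be typed before energy evaluation")
    x = config.coordinates
    energy = 0.0
    grad = np.zeros_like(x)

    def mi(v):
        if config.cell.periodic:
            box = config.cell.lengths
            return v - box * np.round(v / box)
        return v

    for bond in config.bond_set:
        key = _canon2(types[bond.i], types[bond.j])
        if key not in ff.bonds:
            raise ValidationError(f"missing bond parameters for type pair {key}")
        k, r0 = ff.bonds[key]
        d = mi(x[bond.i] - x[bond.j])
        r = np.linalg.norm(d)
        energy += k * (r - r0) ** 2
        g = 2.0 * k * (r - r0) * d / r
        grad[bond.i] += g
        grad[bond.j] -= g

    angles, dihedrals = topology(config)
    for (i, j, k_) in angles:
        key = _canon3(types[i], types[j], types[k_])
        if key not in ff.angles:
            raise ValidationError(f"missing angle parameters for type triple {key}")
        ka, theta0 = ff.angles[key]
        u = mi(x[i] - x[j])
        v = mi(x[k_] - x[j])
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cos_t = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        theta = math.acos(cos_t)
        energy += ka * (theta - theta0) ** 2
        sin_t = math.sqrt(max(1.0 - cos_t**2, 1e-24))
        dE = 2.0 * ka * (theta - theta0)
        # d(theta)/dx via standard angle-derivative expressions
        du = (cos_t * u / nu - v / nv) / (nu * sin_t)
        dv = (cos_t * v / nv - u / nu) / (nv * sin_t)
        grad[i] += dE * du
        grad[k_] += dE * dv
        grad[j] -= dE * (du + dv)

    for (i, j, k_, l) in dihedrals:
        key = (types[i], types[j], types[k_], types[l])
        if key[::-1] < key:
            key = key[::-1]
        terms = ff.torsions.get(key)
        if terms is None:
            raise ValidationError(f"missing torsion parameters for type quadruple {key}")
        b1 = mi(x[j] - x[i])
        b2 = mi(x[k_] - x[j])
        b3 = mi(x[l] - x[k_])
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        phi = math.atan2((np.cross(n1, n2) @ b2) / nb2, n1 @ n2)
        dE = 0.0
        for (kt, n, delta) in terms:
            energy += kt * (1.0 + math.cos(n * phi - delta))
            dE += -kt * n * math.sin(n * phi - delta)
        # standard analytic dihedral derivatives
        sq1 = n1 @ n1
        sq2 = n2 @ n2
        gi = -nb2 / sq1 * n1
        gl = nb2 / sq2 * n2
        s = (b1 @ b2) / (nb2**2)
        t = (b3 @ b2) / (nb2**2)
        gj = -(1.0 + s) * gi + t * gl
        gk = s * gi - (1.0 + t) * gl
        grad[i] += dE * gi
        grad[j] += dE * gj
        grad[k_] += dE * gk
        grad[l] += dE * gl

    return float(energy), grad


def total_energy(config: Configuration, ff: ForceField,
                 settings: NonbondedSettings | None = None) -> tuple[float, np.ndarray]:
    """Bonded + nonbonded energy and gradient."""
    if settings is None:
        settings = NonbondedSettings(tail_correction=config.cell.periodic)
    e1, g1 = bonded_energy(config, ff)
    e2, g2 = nonbonded_energy(config, settings, ff)
    return e1 + e2, g1 + g2


def typed_dump_csv(config: Configuration, path) -> None:
    """Write (index, element, type, charge) rows for a typed configuration."""
    import pandas as pd

    pd.DataFrame(
        [(i, a.element, a.ff_type, a.partial_charge)
         for i, a in enumerate(config.atom_set)],
        columns=["index", "element", "ff_type", "partial_charge"],
    ).to_csv(path, index=False)
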