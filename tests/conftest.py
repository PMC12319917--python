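"""Shared fixtures: molecules, a small transferable force field, stores."""

import numpy as np
import pytest

from atomflow import builder
from atomflow.forcefield import parse_forcefield

ETHANOL_FF = """
[types]
CT3  [CX4H3]      0  10
CT2  [CX4H2]      0  10
OH   [OX2H]       0  10
HO   [OX2H][#1]   1  10
HC   [#1][#6]     0   5

[bonds]
CT3 CT2  268.0 1.529
CT2 OH   320.0 1.41
OH  HO   553.0 0.945
CT3 HC   340.0 1.09
CT2 HC   340.0 1.09

[angles]
CT3 CT2 OH  50.0 109.5
HC CT3 CT2  37.5 110.7
HC CT2 CT3  37.5 110.7
HC CT2 OH   35.0 109.5
HC CT3 HC   33.0 107.8
HC CT2 HC   33.0 107.8
CT2 OH HO   55.0 108.5

[torsions]
HC CT3 CT2 OH  0.15 3 0.0
HC CT3 CT2 HC  0.15 3 0.0
HC CT2 OH HO   0.18 3 0.0
CT3 CT2 OH HO  0.16 3 0.0

[nonbonded]
CT3 0.066 3.5  -0.18
CT2 0.066 3.5   0.145
OH  0.17  3.12 -0.683
HO  0.0001 1.0  0.418
HC  0.03  2.5   0.06
"""


@pytest.fixture(scope="session")
def ethanol():
    return builder.structure_from_smiles("CCO", seed=11)


@pytest.fixture(scope="session")
def ethanol_ff():
    return parse_forcefield(ETHANOL_FF)


@pytest.fixture(scope="session")
def typed_ethanol(ethanol, ethanol_ff):
    from atomflow.forcefield import assign_atom_types

    cfg = builder.structure_from_smiles("CCO", seed=11)
    return assign_atom_types(cfg, ethanol_ff)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250920)
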