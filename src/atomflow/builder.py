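"""Liquid-cell and droplet construction.

Sizing logic: the user supplies component molecules (SMILES), mixing
ratios, an initial density guess and a target atom count (default 2000).
Molecule counts are chosen so the total atom count lands as close as
possible to the target while preserving the ratios; the outer cubic edge
follows from the total mass and the density guess,
``L = (m / rho)^(1/3)``.  Packing then places rigid molecules with random
rotations and translations inside a *reduced* region (edge ``L - margin``)
so that no atoms end up too close once the structure is made periodic at
the full edge L.

For ethanol at 0.7 g/ml and ~2000 atoms this yields 222 molecules, a
packing cube of 26.9492 A and a final periodic cell of 28.9492 A.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from . import constants
from .datamodel import AROMATIC, Atom, AtomSet, Bond, BondSet, Cell, Configuration
from .errors import PackingError, ValidationError

_RD_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC,
}
_TO_RD_ORDERS = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                 3: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC}


def structure_from_smiles(smiles: str, seed: int = 2025) -> Configuration:
    """Build a 3-D configuration from SMILES with explicit hydrogens.

    Embedding is delegated to RDKit (ETKDG); formal charges are preserved
    on the configuration total charge and per-atom partial charges are left
    unset.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"cannot parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if mol.GetNumAtoms() == 1:
        conf = Chem.Conformer(1)
        conf.SetAtomPosition(0, (0.0, 0.0, 0.0))
        mol.AddConformer(conf)
    else:
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise ValidationError(f"3-D embedding failed for SMILES {smiles!r}")
    conformer = mol.GetConformer()
    atoms = AtomSet(Atom(a.GetSymbol()) for a in mol.GetAtoms())
    bonds = BondSet(
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _RD_ORDERS[b.GetBondType()])
        for b in mol.GetBonds()
    )
    coords = np.array([list(conformer.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    charge = Chem.GetFormalCharge(mol)
    return Configuration(atoms, bonds, coords, charge=charge, name=smiles)


def to_rdkit(config: Configuration) -> Chem.Mol:
    """Configuration -> sanitized RDKit molecule (for SMARTS matching)."""
    mol = Chem.RWMol()
    for atom in config.atom_set:
        a = Chem.Atom(atom.element)
        a.SetNoImplicit(True)
        mol.AddAtom(a)
    for bond in config.bond_set:
        mol.AddBond(bond.i, bond.j, _TO_RD_ORDERS[bond.order])
    m = mol.GetMol()
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_ALL
                     ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
    return m


@dataclass
class PackingPlan:
    """Resolved packing recipe: components with counts, shape and sizes."""

    components: list  # (Configuration, count) pairs
    density_guess: float  # g/cm^3
    shape: str = "cubic-periodic"  # or "spherical-droplet"
    target_atoms: int = 2000
    inner_margin: float = 2.0  # Angstrom
    outer_edge: float = 0.0  # Angstrom (cubic) -- computed
    radius: float = 0.0  # Angstrom (droplet) -- computed

    @property
    def total_atoms(self) -> int:
        return sum(mol.n_atoms * count for mol, count in self.components)

    @property
    def total_mass(self) -> float:
        """amu"""
        return sum(mol.total_mass * count for mol, count in self.components)

    def summary(self) -> dict:
        return {
            "components": [(mol.name, count) for mol, count in self.components],
            "density_guess_g_per_cm3": self.density_guess,
            "shape": self.shape,
            "n_atoms": self.total_atoms,
            "outer_edge_angstrom": self.outer_edge,
            "radius_angstrom": self.radius,
            "inner_margin_angstrom": self.inner_margin,
        }


def plan_cell(
    components,
    density_guess: float,
    target_atoms: int = 2000,
    shape: str = "cubic-periodic",
    inner_margin: float = 2.0,
) -> PackingPlan:
    """Choose molecule counts and the cell size from a density guess.

    ``components`` is a list of (Configuration, ratio) pairs.  A global
    scale factor ``target_atoms / atoms-per-ratio-unit`` is rounded half-up
    and applied to the ratios.  The outer cubic edge satisfies
    ``rho = mass / L^3``; a droplet gets the equal-volume sphere radius.
    """
    if density_guess <= 0:
        raise ValidationError("density_guess must be positive")
    if shape not in ("cubic-periodic", "spherical-droplet"):
        raise ValidationError(f"unknown shape {shape!r}")
    comps = [(mol, float(ratio)) for mol, ratio in components]
    for mol, ratio in comps:
        if mol.n_atoms == 0:
            raise ValidationError("component molecule has no atoms")
        if ratio <= 0:
            raise ValidationError("component ratios must be positive")
    atoms_per_unit = sum(mol.n_atoms * ratio for mol, ratio in comps)
    scale = target_atoms / atoms_per_unit
    counts = [max(1, math.floor(ratio * scale + 0.5)) for _, ratio in comps]
    plan = PackingPlan(
        components=[(mol, count) for (mol, _), count in zip(comps, counts)],
        density_guess=density_guess,
        shape=shape,
        target_atoms=target_atoms,
        inner_margin=inner_margin,
    )
    mass_g = plan.total_mass / constants.N_A
    volume_cm3 = mass_g / density_guess
    volume_A3 = volume_cm3 * 1e24
    plan.outer_edge = volume_A3 ** (1.0 / 3.0)
    plan.radius = (3.0 * volume_A3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return plan


def _lattice_sites(n: int, region_lo: np.ndarray, region_size: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """>= n roughly-cubic lattice sites filling the region, shuffled."""
    dims = np.array([max(1, math.ceil(n ** (1 / 3)))] * 3)
    # shrink axes while still holding n molecules, to keep spacing generous
    for ax in range(3):
        while dims.prod() // dims[ax] * (dims[ax] - 1) >= n and dims[ax] > 1:
            dims[ax] -= 1
    spacing = region_size / dims
    grid = np.array(list(itertools.product(*(range(d) for d in dims))), dtype=float)
    sites = region_lo + (grid + 0.5) * spacing
    rng.shuffle(sites)
    return sites, spacing


def pack(
    plan: PackingPlan,
    seed: int,
    clash_distance: float = 2.0,
    max_attempts: int = 60,
    max_sweeps: int = 400,
) -> Configuration:
    """Randomly pack rigid molecules into the reduced region.

    Molecules are assigned to a shuffled lattice of sites spanning the
    packing region (cube of edge ``outer_edge - inner_margin`` centred in
    the outer cell, or sphere of ``radius - inner_margin``), each with a
    random rigid rotation and a random jitter about its site.  Orientations
    and jitters that leave any intermolecular atom-atom distance below
    ``clash_distance`` — including across periodic images of the outer cell
    for the cubic shape — are rejected and resampled, sweeping over the
    remaining offenders until the whole packing is clash-free.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cubic = plan.shape == "cubic-periodic"
    L = plan.outer_edge

    molecules = []
    for mol, count in plan.components:
        centred = mol.coordinates - mol.coordinates.mean(axis=0)
        molecules.extend([(mol, centred)] * count)
    n_mol = len(molecules)

    reach = np.array([np.linalg.norm(c, axis=1).max() for _, c in molecules])
    if cubic:
        inner = L - plan.inner_margin
        lo = plan.inner_margin / 2.0
        region_lo = np.full(3, lo)
        region_size = np.full(3, inner)
        all_sites, spacing = _lattice_sites(n_mol, region_lo, region_size, rng)
    else:
        r_inner = plan.radius - plan.inner_margin
        # molecule centres can sit at most r_inner - reach from the origin
        r_allow = max(r_inner - reach.max(), 0.5 * r_inner)
        for m in itertools.count(max(1, math.ceil(n_mol ** (1 / 3)))):
            spacing = np.full(3, 2 * r_allow / m)
            grid = np.array(list(itertools.product(range(m), repeat=3)), dtype=float)
            pts = -r_allow + (grid + 0.5) * spacing
            pts = pts[np.linalg.norm(pts, axis=1) <= r_allow]
            if len(pts) >= n_mol:
                break
        rng.shuffle(pts)
        all_sites = pts
    sites = all_sites[:n_mol].copy()
    vacant = [all_sites[i].copy() for i in range(n_mol, len(all_sites))]
    jitter = 0.3 * spacing

    def candidates(mi: int, k: int) -> np.ndarray:
        """k random rigid placements of molecule mi that stay in the region."""
        centred = molecules[mi][1]
        quat = rng.normal(size=(k, 4))
        rots = Rotation.from_quat(quat / np.linalg.norm(quat, axis=1, keepdims=True))
        jit = rng.uniform(-jitter, jitter, size=(k, 3))
        trials = rots.as_matrix() @ centred.T  # (k, 3, n_at)
        trials = trials.transpose(0, 2, 1) + sites[mi] + jit[:, None, :]
        if cubic:
            ok = ((trials >= region_lo).all(axis=(1, 2))
                  & (trials <= region_lo + region_size).all(axis=(1, 2)))
        else:
            ok = np.linalg.norm(trials, axis=2).max(axis=1) <= r_inner
        trials = trials[ok]
        if cubic:
            trials = trials % L
        return trials

    def sample(mi: int) -> np.ndarray:
        for k in (16, 64, 256, 1024):
            got = candidates(mi, k)
            if len(got):
                return got[0]
            if not cubic:
                sites[mi] = sites[mi] * 0.85  # pull a boundary site inward
        raise PackingError(
            f"molecule {mi} cannot fit inside the packing region; "
            "the region is too small for this molecule"
        )

    # site-based neighbour lists: molecules never leave their site vicinity,
    # so the lists only change when a molecule relocates to a vacant site
    site_reach = reach + np.linalg.norm(jitter)
    neighbours: list[np.ndarray] = []

    def rebuild_neighbours() -> None:
        neighbours.clear()
        dsite = sites[:, None, :] - sites[None, :, :]
        if cubic:
            dsite -= L * np.round(dsite / L)
        dsite = np.linalg.norm(dsite, axis=-1)
        cut = site_reach[:, None] + site_reach[None, :] + clash_distance
        for i in range(n_mol):
            nb = np.where((dsite[i] < cut[i]) & (np.arange(n_mol) != i))[0]
            neighbours.append(nb)

    rebuild_neighbours()

    coords: list = [None] * n_mol

    def batch_min_dist(trials: np.ndarray, mi: int) -> np.ndarray:
        """Minimum intermolecular distance for each trial placement of mi."""
        nb = [j for j in neighbours[mi] if coords[j] is not None]
        if not nb:
            return np.full(len(trials), np.inf)
        others = np.concatenate([coords[j] for j in nb])
        diff = trials[:, :, None, :] - others[None, None, :, :]
        if cubic:
            diff -= L * np.round(diff / L)
        return np.sqrt((diff * diff).sum(-1)).min(axis=(1, 2))

    def min_dist(mi: int) -> float:
        return float(batch_min_dist(coords[mi][None], mi)[0])

    # clash-aware initial placement: best of a candidate batch per molecule
    for mi in range(n_mol):
        trials = candidates(mi, max_attempts)
        if not len(trials):
            trials = sample(mi)[None]
        dists = batch_min_dist(trials, mi)
        coords[mi] = trials[int(np.argmax(dists))]

    def try_relocate(mi: int) -> bool:
        """Move a jammed molecule to a vacant lattice site, if one admits a
        clash-free placement (checked against every other molecule)."""
        others = np.concatenate([coords[j] for j in range(n_mol) if j != mi])
        old_site = sites[mi].copy()
        order = rng.permutation(len(vacant)) if vacant else []
        for vi in order:
            sites[mi] = vacant[vi]
            trials = candidates(mi, max_attempts)
            if not len(trials):
                continue
            diff = trials[:, :, None, :] - others[None, None, :, :]
            if cubic:
                diff -= L * np.round(diff / L)
            dists = np.sqrt((diff * diff).sum(-1)).min(axis=(1, 2))
            pick = int(np.argmax(dists))
            if dists[pick] >= clash_distance:
                coords[mi] = trials[pick]
                vacant[vi] = old_site
                rebuild_neighbours()
                return True
        sites[mi] = old_site
        return False

    bad = [i for i in range(n_mol) if min_dist(i) < clash_distance]
    best_bad, stalled = len(bad), 0
    for _ in range(max_sweeps):
        if not bad:
            break
        if len(bad) < best_bad:
            best_bad, stalled = len(bad), 0
        else:
            stalled += 1
            if stalled > 60:  # no progress: the region is too dense to repair
                break
        for mi in bad:
            best_d = min_dist(mi)
            if best_d >= clash_distance:
                continue
            trials = candidates(mi, max_attempts)
            if len(trials):
                dists = batch_min_dist(trials, mi)
                pick = int(np.argmax(dists))
                if dists[pick] > best_d:
                    coords[mi] = trials[pick]
                    best_d = float(dists[pick])
            if best_d < clash_distance and stalled >= 3:
                try_relocate(mi)
        bad = [i for i in range(n_mol) if min_dist(i) < clash_distance]
    if bad:
        n_ok = n_mol - len(bad)
        mass = sum(m.total_mass for m, _ in molecules)
        vol = L**3 if cubic else 4 / 3 * math.pi * plan.radius**3
        density = mass / constants.N_A / (vol * 1e-24)
        raise PackingError(
            f"could not resolve clashes for {len(bad)}/{n_mol} molecules "
            f"({n_ok} placed cleanly at target density {density:.3f} g/cm^3); "
            "increase the cell or lower clash_distance"
        )

    molecule_ids = [mi + 1 for mi, (mol, _) in enumerate(molecules)
                    for _ in range(mol.n_atoms)]
    coords = np.vstack(coords)
    atoms = AtomSet()
    bonds = BondSet()
    offset = 0
    for mol, _ in molecules:
        for a in mol.atom_set:
            atoms.append(Atom(a.element, a.mass, a.partial_charge, a.ff_type, a.name))
        for b in mol.bond_set:
            bonds.append(Bond(b.i + offset, b.j + offset, b.order))
        offset += mol.n_atoms
    cell = Cell.cubic(L) if cubic else Cell()
    packed = Configuration(atoms, bonds, coords, cell, name="packed")
    packed.molecule_ids = molecule_ids
    return packed


def write_plan_summary(plan: PackingPlan, path, seed: int | None = None) -> None:
    summary = plan.summary()
    if seed is not None:
        summary["seed"] = seed
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
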