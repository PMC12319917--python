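"""Systems/configurations data model with shared atom and bond sets.

A :class:`System` is a collection of atoms, molecules and/or crystals
described by one or more :class:`Configuration` snapshots.  Configurations
of the same system may share an :class:`AtomSet` (same atoms, different
coordinates — e.g. conformers) or carry different atom and bond sets
entirely (e.g. the reactant and product of a reaction).  Charge and spin
multiplicity are per-configuration properties.

Persistence is an embedded relational store (sqlite) whose tables mirror
the junction-table layout: ``atom``/``atomset_atom`` and
``bond``/``bondset_bond`` keep sets shareable between configurations, and
the round trip is bit-exact for every numeric field.
"""

from __future__ import annotations

import itertools
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
from rdkit import Chem

from .errors import StoreError, ValidationError

_PT = Chem.GetPeriodicTable()

AROMATIC = "aromatic"
_BOND_ORDERS = {1, 2, 3, AROMATIC}


def atomic_weight(element: str) -> float:
    """Standard atomic weight (amu) for a chemical symbol."""
    try:
        z = _PT.GetAtomicNumber(element)
    except Exception:
        raise ValidationError(f"unknown element symbol {element!r}") from None
    if z <= 0:
        raise ValidationError(f"unknown element symbol {element!r}")
    return _PT.GetAtomicWeight(z)


@dataclass
class Atom:
    """One atom: element symbol, mass (amu) and optional per-atom labels."""

    element: str
    mass: float | None = None
    partial_charge: float | None = None
    ff_type: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        weight = atomic_weight(self.element)  # validates the symbol
        if self.mass is None:
            self.mass = weight
        if self.mass <= 0:
            raise ValidationError(f"mass must be positive, got {self.mass}")


@dataclass(frozen=True)
class Bond:
    """A bond between atom indices ``i`` and ``j`` within an atom set."""

    i: int
    j: int
    order: Union[int, str] = 1

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValidationError(f"bond endpoints must differ, got ({self.i}, {self.j})")
        if self.order not in _BOND_ORDERS:
            raise ValidationError(f"bond order must be 1, 2, 3 or {AROMATIC!r}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


class AtomSet(list):
    """A shareable, ordered collection of :class:`Atom`.

    Identity matters: two configurations referencing the same AtomSet object
    share atoms (not copies).
    """

    def __init__(self, atoms: Iterable[Atom] = ()):  # noqa: D107
        super().__init__(atoms)


class BondSet(list):
    """A shareable, ordered collection of :class:`Bond` (no duplicate pairs)."""

    def __init__(self, bonds: Iterable[Bond] = ()):  # noqa: D107
        super().__init__()
        for b in bonds:
            self.append(b)

    def append(self, bond: Bond) -> None:  # noqa: D102
        if any(b.key == bond.key for b in self):
            raise ValidationError(f"duplicate bond {bond.key}")
        super().append(bond)


@dataclass
class Cell:
    """Periodic cell: lengths in Angstrom, angles in degrees."""

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.periodic:
            if min(self.a, self.b, self.c) <= 0:
                raise ValidationError("periodic cell lengths must be positive")
            for ang in (self.alpha, self.beta, self.gamma):
                if not 0 < ang < 180:
                    raise ValidationError("cell angles must lie in (0, 180) degrees")

    @classmethod
    def cubic(cls, edge: float) -> "Cell":
        return cls(edge, edge, edge, periodic=True)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def volume(self) -> float:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cos = np.cos([al, be, ga])
        factor = 1 - cos[0] ** 2 - cos[1] ** 2 - cos[2] ** 2 + 2 * cos[0] * cos[1] * cos[2]
        return float(self.a * self.b * self.c * np.sqrt(max(factor, 0.0)))


class Configuration:
    """A snapshot: atom set, bond set, coordinates (Angstrom), cell, charge, spin."""

    def __init__(
        self,
        atom_set: AtomSet,
        bond_set: BondSet | None = None,
        coordinates: Optional[np.ndarray] = None,
        cell: Cell | None = None,
        charge: int = 0,
        spin_multiplicity: int = 1,
        symmetry: str | None = None,
        name: str = "default",
    ):
        self.atom_set = atom_set
        self.bond_set = bond_set if bond_set is not None else BondSet()
        n = len(atom_set)
        if coordinates is None:
            coordinates = np.zeros((n, 3))
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.shape != (n, 3):
            raise ValidationError(
                f"coordinate shape {coordinates.shape} does not match {n} atoms"
            )
        self.coordinates = coordinates.copy()
        self.cell = cell if cell is not None else Cell()
        self.charge = int(charge)
        if spin_multiplicity < 1:
            raise ValidationError("spin multiplicity must be a positive integer")
        self.spin_multiplicity = int(spin_multiplicity)
        self.symmetry = symmetry
        self.name = name
        for b in self.bond_set:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValidationError(f"bond {b.key} references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_set)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atom_set]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atom_set])

    @property
    def total_mass(self) -> float:
        """Mass in amu (g/mol)."""
        return float(self.masses.sum())

    def formula(self) -> str:
        counts: dict[str, int] = {}
        for el in self.elements:
            counts[el] = counts.get(el, 0) + 1
        order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{e}{counts[e] if counts[e] > 1 else ''}" for e in order)

    def graph(self) -> nx.Graph:
        """Molecular graph with ``element`` node and ``order`` edge attributes."""
        g = nx.Graph()
        for i, a in enumerate(self.atom_set):
            g.add_node(i, element=a.element)
        for b in self.bond_set:
            g.add_edge(b.i, b.j, order=b.order)
        return g


class System:
    """A named, ordered collection of configurations."""

    def __init__(self, name: str = "system"):
        self.name = name
        self.configurations: list[Configuration] = []

    def add_configuration(self, config: Configuration) -> Configuration:
        if any(c.name == config.name for c in self.configurations):
            raise ValidationError(
                f"configuration name {config.name!r} already used in system {self.name!r}"
            )
        self.configurations.append(config)
        return config

    def get(self, name: str) -> Configuration:
        for c in self.configurations:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass
class Subset:
    """An arbitrary collection of atoms in a configuration."""

    configuration: Configuration
    atom_indices: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices", frozenset(self.atom_indices))
        n = self.configuration.n_atoms
        if any(not 0 <= i < n for i in self.atom_indices):
            raise ValidationError("subset indices out of range for configuration")


@dataclass
class Template:
    """A prototype used to find identical substructures and transfer attributes."""

    prototype: Configuration
    transfer_attributes: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.prototype.graph()
        if self.prototype.n_atoms and not nx.is_connected(g):
            raise ValidationError("template prototype must be a connected molecular graph")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def new_configuration(
    system: System,
    atoms: Iterable[Atom] | AtomSet | None = None,
    bonds: Iterable[Bond] | BondSet | None = None,
    coordinates: Optional[np.ndarray] = None,
    share_atoms_from: Configuration | None = None,
    name: str | None = None,
    **kwargs,
) -> Configuration:
    """Create and register a configuration, optionally sharing an atom set.

    When ``share_atoms_from`` is given the new configuration references the
    *same* AtomSet object (not a copy); only the coordinates are new.
    """
    if share_atoms_from is not None:
        if share_atoms_from not in system.configurations:
            raise ValidationError(
                "share_atoms_from must reference a configuration of the same system"
            )
        atom_set = share_atoms_from.atom_set
        if bonds is None:
            bond_set = share_atoms_from.bond_set
        else:
            bond_set = bonds if isinstance(bonds, BondSet) else BondSet(bonds)
        if coordinates is None:
            coordinates = share_atoms_from.coordinates
    else:
        atom_set = atoms if isinstance(atoms, AtomSet) else AtomSet(atoms or ())
        bond_set = bonds if isinstance(bonds, BondSet) else BondSet(bonds or ())
    if name is None:
        name = f"conf_{len(system.configurations) + 1}"
    config = Configuration(atom_set, bond_set, coordinates, name=name, **kwargs)
    return system.add_configuration(config)


def find_molecules(config: Configuration) -> list[list[int]]:
    """Partition atoms into connected components (individual molecules).

    Components are ordered by their smallest atom index; atoms within a
    component are sorted.  Isolated atoms form singleton components.
    """
    comps = [sorted(c) for c in nx.connected_components(config.graph())]
    return sorted(comps, key=lambda c: c[0])


def topology(config: Configuration) -> tuple[list[tuple], list[tuple]]:
    """Angles (i-j-k) and dihedrals (i-j-k-l) implied by the bond graph.

    Each angle/dihedral appears once; the reversed orientation is not
    duplicated (the canonical orientation has the smaller outer index first).
    """
    g = config.graph()
    angles = []
    for j in g.nodes:
        for i, k in itertools.combinations(sorted(g.neighbors(j)), 2):
            angles.append((i, j, k))
    dihedrals = []
    for j, k in g.edges:
        if j > k:
            j, k = k, j
        for i in g.neighbors(j):
            if i == k:
                continue
            for l in g.neighbors(k):
                if l == j or l == i:
                    continue
                cand = (i, j, k, l)
                if cand[::-1] < cand:
                    cand = cand[::-1]
                dihedrals.append(cand)
    return sorted(set(angles)), sorted(set(dihedrals))


def match_template(template: Template, config: Configuration) -> list[dict[int, int]]:
    """Find every substructure of ``config`` matching the template prototype.

    Matching is element- and bond-order-preserving subgraph monomorphism,
    independent of atom order.  Matches covering the same atom set (template
    automorphisms) are de-duplicated.  Returns mappings
    ``{prototype index: configuration index}``.
    """
    proto = template.prototype.graph()
    target = config.graph()
    nm = nx.algorithms.isomorphism.categorical_node_match("element", None)
    em = nx.algorithms.isomorphism.categorical_edge_match("order", None)
    gm = nx.algorithms.isomorphism.GraphMatcher(target, proto, node_match=nm, edge_match=em)
    seen: set[frozenset] = set()
    out: list[dict[int, int]] = []
    for mapping in gm.subgraph_monomorphisms_iter():
        inv = {p: c for c, p in mapping.items()}
        key = frozenset(inv.values())
        if key not in seen:
            seen.add(key)
            out.append(dict(sorted(inv.items())))
    out.sort(key=lambda m: sorted(m.values()))
    return out


def apply_template(template: Template, config: Configuration) -> int:
    """Transfer names/charges/ff_types through every match; return match count."""
    matches = match_template(template, config)
    for mapping in matches:
        for p_idx, attrs in template.transfer_attributes.items():
            atom = config.atom_set[mapping[p_idx]]
            for key, val in attrs.items():
                setattr(atom, key, val)
    return len(matches)


# ---------------------------------------------------------------------------
# persistence (embedded relational store)
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE system (id INTEGER PRIMARY KEY, name TEXT NOT NULL);
CREATE TABLE atomset (id INTEGER PRIMARY KEY);
CREATE TABLE atom (
    id INTEGER PRIMARY KEY, element TEXT NOT NULL, mass REAL NOT NULL,
    partial_charge REAL, ff_type TEXT, name TEXT);
CREATE TABLE atomset_atom (
    atomset INTEGER REFERENCES atomset(id), atom INTEGER REFERENCES atom(id),
    idx INTEGER NOT NULL);
CREATE TABLE bondset (id INTEGER PRIMARY KEY);
CREATE TABLE bond (
    id INTEGER PRIMARY KEY, i INTEGER NOT NULL, j INTEGER NOT NULL,
    bond_order TEXT NOT NULL);
CREATE TABLE bondset_bond (
    bondset INTEGER REFERENCES bondset(id), bond INTEGER REFERENCES bond(id),
    idx INTEGER NOT NULL);
CREATE TABLE cell (
    id INTEGER PRIMARY KEY, a REAL, b REAL, c REAL,
    alpha REAL, beta REAL, gamma REAL, periodic INTEGER);
CREATE TABLE configuration (
    id INTEGER PRIMARY KEY, system INTEGER REFERENCES system(id),
    name TEXT, atomset INTEGER, bondset INTEGER, cell INTEGER,
    charge INTEGER, spin_multiplicity INTEGER, symmetry TEXT, idx INTEGER);
CREATE TABLE coordinates (
    configuration INTEGER REFERENCES configuration(id),
    idx INTEGER NOT NULL, x REAL, y REAL, z REAL);
"""

_TABLES = (
    "system", "atomset", "atom", "atomset_atom", "bondset", "bond",
    "bondset_bond", "cell", "configuration", "coordinates",
)


def _ensure_schema(conn: sqlite3.Connection) -> None:
    have = {r[0] for r in conn.execute("SELECT name FROM sqlite_master WHERE type='table'")}
    if not have:
        conn.executescript(_SCHEMA)
        return
    for table in _TABLES:
        if table not in have:
            raise StoreError(f"store file is missing table {table!r}")


def persist(system: System, store_path) -> None:
    """Write a system to the embedded relational store (full precision)."""
    path = Path(store_path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(path)
    try:
        conn.executescript(_SCHEMA)
        cur = conn.execute("INSERT INTO system (name) VALUES (?)", (system.name,))
        sys_id = cur.lastrowid
        atomset_ids: dict[int, int] = {}
        bondset_ids: dict[int, int] = {}
        for idx, config in enumerate(system.configurations):
            aset = config.atom_set
            if id(aset) not in atomset_ids:
                cur = conn.execute("INSERT INTO atomset DEFAULT VALUES")
                as_id = cur.lastrowid
                atomset_ids[id(aset)] = as_id
                for i, atom in enumerate(aset):
                    cur = conn.execute(
                        "INSERT INTO atom (element, mass, partial_charge, ff_type, name)"
                        " VALUES (?, ?, ?, ?, ?)",
                        (atom.element, atom.mass, atom.partial_charge, atom.ff_type, atom.name),
                    )
                    conn.execute(
                        "INSERT INTO atomset_atom (atomset, atom, idx) VALUES (?, ?, ?)",
                        (as_id, cur.lastrowid, i),
                    )
            bset = config.bond_set
            if id(bset) not in bondset_ids:
                cur = conn.execute("INSERT INTO bondset DEFAULT VALUES")
                bs_id = cur.lastrowid
                bondset_ids[id(bset)] = bs_id
                for i, bond in enumerate(bset):
                    cur = conn.execute(
                        "INSERT INTO bond (i, j, bond_order) VALUES (?, ?, ?)",
                        (bond.i, bond.j, str(bond.order)),
                    )
                    conn.execute(
                        "INSERT INTO bondset_bond (bondset, bond, idx) VALUES (?, ?, ?)",
                        (bs_id, cur.lastrowid, i),
                    )
            cell = config.cell
            cur = conn.execute(
                "INSERT INTO cell (a, b, c, alpha, beta, gamma, periodic)"
                " VALUES (?, ?, ?, ?, ?, ?, ?)",
                (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma,
                 int(cell.periodic)),
            )
            cell_id = cur.lastrowid
            cur = conn.execute(
                "INSERT INTO configuration (system, name, atomset, bondset, cell,"
                " charge, spin_multiplicity, symmetry, idx)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (sys_id, config.name, atomset_ids[id(aset)], bondset_ids[id(bset)],
                 cell_id, config.charge, config.spin_multiplicity, config.symmetry, idx),
            )
            conf_id = cur.lastrowid
            conn.executemany(
                "INSERT INTO coordinates (configuration, idx, x, y, z) VALUES (?, ?, ?, ?, ?)",
                [(conf_id, i, float(x), float(y), float(z))
                 for i, (x, y, z) in enumerate(config.coordinates)],
            )
        conn.commit()
    finally:
        conn.close()


def load(store_path) -> System:
    """Load a system, reconstructing atom-set/bond-set sharing by reference."""
    path = Path(store_path)
    if not path.exists():
        raise StoreError(f"no store file at {path}")
    conn = sqlite3.connect(path)
    try:
        try:
            _ensure_schema(conn)
            rows = conn.execute("SELECT id, name FROM system ORDER BY id").fetchall()
        except sqlite3.DatabaseError as exc:
            raise StoreError(f"not a valid store file: {exc}") from exc
        if not rows:
            return System("empty")
        sys_id, sys_name = rows[0]
        system = System(sys_name)
        atomsets: dict[int, AtomSet] = {}
        bondsets: dict[int, BondSet] = {}
        for (conf_id, name, as_id, bs_id, cell_id, charge, spin, symmetry) in conn.execute(
            "SELECT id, name, atomset, bondset, cell, charge, spin_multiplicity,"
            " symmetry FROM configuration WHERE system=? ORDER BY idx", (sys_id,)
        ).fetchall():
            if as_id not in atomsets:
                atoms = AtomSet()
                for (el, mass, pc, fft, aname) in conn.execute(
                    "SELECT a.element, a.mass, a.partial_charge, a.ff_type, a.name"
                    " FROM atomset_atom j JOIN atom a ON a.id=j.atom"
                    " WHERE j.atomset=? ORDER BY j.idx", (as_id,)
                ):
                    atoms.append(Atom(el, mass, pc, fft, aname))
                atomsets[as_id] = atoms
            if bs_id not in bondsets:
                bonds = BondSet()
                for (i, j, order) in conn.execute(
                    "SELECT b.i, b.j, b.bond_order FROM bondset_bond jt"
                    " JOIN bond b ON b.id=jt.bond WHERE jt.bondset=? ORDER BY jt.idx",
                    (bs_id,),
                ):
                    bonds.append(Bond(i, j, order if order == AROMATIC else int(order)))
                bondsets[bs_id] = bonds
            (a, b, c, al, be, ga, per) = conn.execute(
                "SELECT a, b, c, alpha, beta, gamma, periodic FROM cell WHERE id=?",
                (cell_id,),
            ).fetchone()
            coords = np.array([
                r for r in conn.execute(
                    "SELECT x, y, z FROM coordinates WHERE configuration=? ORDER BY idx",
                    (conf_id,),
                )
            ], dtype=float).reshape(-1, 3)
            config = Configuration(
                atomsets[as_id], bondsets[bs_id], coords,
                Cell(a, b, c, al, be, ga, bool(per)),
                charge=charge, spin_multiplicity=spin, symmetry=symmetry, name=name,
            )
            system.configurations.append(config)
        return system
    finally:
        conn.close()
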