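"""Data-model contracts: sharing, persistence fidelity, graph operations."""

import itertools

import numpy as np
import pytest

from atomflow import builder
from atomflow.datamodel import (
    AROMATIC, Atom, AtomSet, Bond, BondSet, Cell, Configuration, System,
    Template, find_molecules, load, match_template, new_configuration,
    persist, topology,
)
from atomflow.errors import StoreError, ValidationError


def water(name="w"):
    atoms = AtomSet([Atom("O"), Atom("H"), Atom("H")])
    bonds = BondSet([Bond(0, 1), Bond(0, 2)])
    coords = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
    return Configuration(atoms, bonds, coords, name=name)


class TestConstruction:
    def test_ethanol_from_smiles_counts(self, ethanol):
        assert ethanol.n_atoms == 9
        assert len(ethanol.bond_set) == 8
        assert ethanol.formula() == "C2H6O"

    def test_invalid_element_rejected(self):
        with pytest.raises(ValidationError):
            Atom("Xx")

    def test_self_bond_and_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            Bond(2, 2)
        with pytest.raises(ValidationError):
            BondSet([Bond(0, 1), Bond(1, 0)])

    def test_periodic_cell_invariants(self):
        with pytest.raises(ValidationError):
            Cell(0.0, 5.0, 5.0, periodic=True)
        with pytest.raises(ValidationError):
            Cell(5, 5, 5, alpha=181.0, periodic=True)
        assert Cell.cubic(10.0).volume == pytest.approx(1000.0)


class TestSharing:
    def test_shared_atom_set_is_same_object(self, ethanol):
        system = System("conformers")
        c1 = new_configuration(system, ethanol.atom_set, ethanol.bond_set,
                               ethanol.coordinates, name="a")
        c2 = new_configuration(system, share_atoms_from=c1, name="b")
        assert c2.atom_set is c1.atom_set

    def test_perturbing_shared_conformer_leaves_original_unchanged(self, ethanol):
        system = System("conformers")
        c1 = new_configuration(system, ethanol.atom_set, ethanol.bond_set,
                               ethanol.coordinates, name="a")
        before = c1.coordinates.copy()
        c2 = new_configuration(system, share_atoms_from=c1, name="b")
        c2.coordinates += 1.0
        assert np.array_equal(c1.coordinates, before)

    def test_sharing_across_systems_rejected(self, ethanol):
        s1, s2 = System("one"), System("two")
        c1 = new_configuration(s1, ethanol.atom_set, ethanol.bond_set,
                               ethanol.coordinates, name="a")
        with pytest.raises(ValidationError, match="same system"):
            new_configuration(s2, share_atoms_from=c1)

    def test_isomerization_same_atoms_different_bonds(self):
        # methyl isocyanide vs acetonitrile: one system, two bond sets
        system = System("CH3NC->CH3CN")
        atoms = AtomSet([Atom("C"), Atom("N"), Atom("C"),
                         Atom("H"), Atom("H"), Atom("H")])
        reactant_bonds = BondSet([Bond(0, 1), Bond(1, 2, 3),
                                  Bond(0, 3), Bond(0, 4), Bond(0, 5)])
        product_bonds = BondSet([Bond(0, 2), Bond(2, 1, 3),
                                 Bond(0, 3), Bond(0, 4), Bond(0, 5)])
        r = new_configuration(system, atoms, reactant_bonds, name="reactant")
        p = new_configuration(system, share_atoms_from=r, bonds=product_bonds,
                              name="product")
        assert p.atom_set is r.atom_set
        assert p.bond_set is not r.bond_set
        assert {b.key for b in r.bond_set} != {b.key for b in p.bond_set}

    def test_duplicate_configuration_names_rejected(self, ethanol):
        system = System("s")
        new_configuration(system, ethanol.atom_set, ethanol.bond_set, name="x")
        with pytest.raises(ValidationError):
            new_configuration(system, ethanol.atom_set, ethanol.bond_set, name="x")


class TestPersistence:
    def test_round_trip_bit_exact_randomized(self, rng, tmp_path):
        for trial in range(3):
            system = System(f"random_{trial}")
            n = int(rng.integers(2, 30))
            atoms = AtomSet([Atom(rng.choice(["C", "N", "O", "H"]),
                                  partial_charge=float(rng.normal()))
                             for _ in range(n)])
            bonds = BondSet([Bond(i, i + 1, order=int(rng.integers(1, 4)))
                             for i in range(n - 1)])
            coords = rng.normal(size=(n, 3)) * 10
            cell = Cell(*rng.uniform(5, 20, 3), periodic=True)
            new_configuration(system, atoms, bonds, coords, cell=cell,
                              charge=int(rng.integers(-2, 3)),
                              spin_multiplicity=int(rng.integers(1, 4)))
            path = tmp_path / f"sys_{trial}.db"
            persist(system, path)
            loaded = load(path)
            got = loaded.configurations[0]
            assert np.array_equal(got.coordinates, coords)
            assert got.cell.a == cell.a and got.cell.gamma == cell.gamma
            assert [a.element for a in got.atom_set] == [a.element for a in atoms]
            assert [a.partial_charge for a in got.atom_set] == \
                   [a.partial_charge for a in atoms]
            assert [(b.i, b.j, b.order) for b in got.bond_set] == \
                   [(b.i, b.j, b.order) for b in bonds]
            assert got.charge == system.configurations[0].charge
            assert got.spin_multiplicity == system.configurations[0].spin_multiplicity

    def test_shared_atom_sets_survive_round_trip(self, ethanol, tmp_path):
        system = System("share")
        c1 = new_configuration(system, ethanol.atom_set, ethanol.bond_set,
                               ethanol.coordinates, name="a")
        new_configuration(system, share_atoms_from=c1,
                          coordinates=ethanol.coordinates + 1.0, name="b")
        path = tmp_path / "share.db"
        persist(system, path)
        loaded = load(path)
        a, b = loaded.configurations
        assert a.atom_set is b.atom_set
        assert not np.array_equal(a.coordinates, b.coordinates)

    def test_aromatic_bond_order_round_trips(self, tmp_path):
        benzene = builder.structure_from_smiles("c1ccccc1")
        system = System("arom")
        new_configuration(system, benzene.atom_set, benzene.bond_set,
                          benzene.coordinates)
        persist(system, tmp_path / "b.db")
        got = load(tmp_path / "b.db").configurations[0]
        n_arom = sum(1 for b in got.bond_set if b.order == AROMATIC)
        assert n_arom == 6

    def test_empty_system_round_trips(self, tmp_path):
        persist(System("void"), tmp_path / "e.db")
        loaded = load(tmp_path / "e.db")
        assert loaded.name == "void"
        assert loaded.configurations == []

    def test_foreign_file_names_problem(self, tmp_path):
        bad = tmp_path / "garbage.db"
        bad.write_text("this is not a database")
        with pytest.raises(StoreError):
            load(bad)

    def test_missing_table_named(self, tmp_path):
        import sqlite3

        path = tmp_path / "partial.db"
        conn = sqlite3.connect(path)
        conn.execute("CREATE TABLE system (id INTEGER PRIMARY KEY, name TEXT)")
        conn.commit()
        conn.close()
        with pytest.raises(StoreError, match="atom"):
            load(path)


class TestFindMolecules:
    def test_three_waters(self):
        atoms = AtomSet()
        bonds = BondSet()
        for m in range(3):
            base = 3 * m
            for el in ("O", "H", "H"):
                atoms.append(Atom(el))
            bonds.append(Bond(base, base + 1))
            bonds.append(Bond(base, base + 2))
        cfg = Configuration(atoms, bonds)
        comps = find_molecules(cfg)
        assert [len(c) for c in comps] == [3, 3, 3]
        assert comps[0] == [0, 1, 2]

    def test_single_ethanol(self, ethanol):
        comps = find_molecules(ethanol)
        assert len(comps) == 1 and len(comps[0]) == 9

    def test_isolated_atoms_are_singletons(self):
        cfg = Configuration(AtomSet([Atom("Ar"), Atom("Ar")]), BondSet())
        assert find_molecules(cfg) == [[0], [1]]

    def test_matches_union_find_oracle_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 25))
            edges = set()
            for _ in range(int(rng.integers(0, n * 2))):
                i, j = rng.integers(0, n, 2)
                if i != j:
                    edges.add((min(i, j), max(i, j)))
            cfg = Configuration(AtomSet([Atom("C") for _ in range(n)]),
                                BondSet([Bond(int(i), int(j)) for i, j in edges]))
            # independent union-find
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i, j in edges:
                parent[find(i)] = find(j)
            n_oracle = len({find(i) for i in range(n)})
            assert len(find_molecules(cfg)) == n_oracle


class TestTopology:
    def test_water_one_angle_no_dihedrals(self):
        angles, dihedrals = topology(water())
        assert angles == [(1, 0, 2)]
        assert dihedrals == []

    def test_linear_chain(self):
        cfg = Configuration(AtomSet([Atom("C") for _ in range(4)]),
                            BondSet([Bond(0, 1), Bond(1, 2), Bond(2, 3)]))
        angles, dihedrals = topology(cfg)
        assert len(angles) == 2
        assert dihedrals == [(0, 1, 2, 3)]

    def test_ethane_hcch_dihedrals_vs_enumeration(self):
        ethane = builder.structure_from_smiles("CC")
        angles, dihedrals = topology(ethane)
        elements = ethane.elements
        hcch = [d for d in dihedrals
                if (elements[d[0]], elements[d[1]], elements[d[2]], elements[d[3]])
                == ("H", "C", "C", "H")]
        # exhaustive oracle: every (H on C1, H on C2) pair once
        adj = {i: set() for i in range(ethane.n_atoms)}
        for b in ethane.bond_set:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
        carbons = [i for i, e in enumerate(elements) if e == "C"]
        c1, c2 = carbons
        expected = sum(1 for h1 in adj[c1] if elements[h1] == "H"
                       for h2 in adj[c2] if elements[h2] == "H")
        assert expected == 9
        assert len(hcch) == 9
        # no duplicates under reversal anywhere
        assert len(set(dihedrals)) == len(dihedrals)
        assert all(d[::-1] not in set(dihedrals) or d == d[::-1] for d in dihedrals)


def brute_force_matches(proto, config):
    """Permutation-search oracle for substructure matching (<= 8 atoms)."""
    pg = proto.graph()
    cg = config.graph()
    pn = list(pg.nodes)
    results = set()
    for cand in itertools.permutations(cg.nodes, len(pn)):
        mapping = dict(zip(pn, cand))
        if any(pg.nodes[p]["element"] != cg.nodes[mapping[p]]["element"]
               for p in pn):
            continue
        ok = True
        for (u, v, data) in pg.edges(data=True):
            mu, mv = mapping[u], mapping[v]
            if not cg.has_edge(mu, mv) or cg.edges[mu, mv]["order"] != data["order"]:
                ok = False
                break
        if ok:
            results.add(frozenset(mapping.values()))
    return results


class TestTemplateMatching:
    def test_two_ethanols_two_matches(self, ethanol):
        box = Configuration(
            AtomSet([Atom(a.element) for a in ethanol.atom_set] * 2),
            BondSet([Bond(b.i + off, b.j + off, b.order)
                     for off in (0, 9) for b in ethanol.bond_set]),
            np.vstack([ethanol.coordinates, ethanol.coordinates + 20.0]),
        )
        matches = match_template(Template(ethanol), box)
        assert len(matches) == 2

    def test_water_template_vs_ethanol_no_match(self, ethanol):
        assert match_template(Template(water()), ethanol) == []

    def test_methyl_template_matches_once_in_ethanol(self, ethanol):
        methyl = Configuration(
            AtomSet([Atom("C"), Atom("H"), Atom("H"), Atom("H")]),
            BondSet([Bond(0, 1), Bond(0, 2), Bond(0, 3)]),
        )
        matches = match_template(Template(methyl), ethanol)
        assert len(matches) == 1

    def test_matches_equal_brute_force_on_small_molecules(self):
        targets = [builder.structure_from_smiles(s)
                   for s in ("CO", "CCO", "OCO")]
        protos = [
            Configuration(AtomSet([Atom("O"), Atom("H")]), BondSet([Bond(0, 1)])),
            Configuration(AtomSet([Atom("C"), Atom("O")]), BondSet([Bond(0, 1)])),
            water(),
        ]
        for target in targets:
            for proto in protos:
                got = {frozenset(m.values())
                       for m in match_template(Template(proto), target)}
                assert got == brute_force_matches(proto, target)

    def test_attribute_transfer_through_mapping(self, ethanol):
        from atomflow.datamodel import apply_template

        hydroxyl = Configuration(
            AtomSet([Atom("O"), Atom("H")]), BondSet([Bond(0, 1)]))
        tmpl = Template(hydroxyl, transfer_attributes={
            0: {"ff_type": "OH", "partial_charge": -0.683},
            1: {"ff_type": "HO"},
        })
        cfg = builder.structure_from_smiles("CCO")
        n = apply_template(tmpl, cfg)
        assert n == 1
        typed = [(a.element, a.ff_type) for a in cfg.atom_set
                 if a.ff_type is not None]
        assert ("O", "OH") in typed and ("H", "HO") in typed

    def test_disconnected_template_rejected(self):
        with pytest.raises(ValidationError):
            Template(Configuration(AtomSet([Atom("C"), Atom("C")]), BondSet()))
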