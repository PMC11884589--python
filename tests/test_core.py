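"""Data-model tests: perception, formulas, canonical keys, graph diffs, XYZ."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rpskit.core import (
    COVALENT_RADII,
    DegenerateGeometryError,
    Geometry,
    MolecularGraph,
    canonical_graph_key,
    graph_diff,
    hill_formula,
    is_closed_shell_realizable,
    perceive_bonds,
    read_xyz,
    write_xyz,
)


def geom(symbols, coords):
    return Geometry.from_symbols(symbols, np.asarray(coords, float))


class TestGeometry:
    def test_shape_and_finiteness_validated(self):
        with pytest.raises(ValueError):
            Geometry((1, 1), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            Geometry((1,), np.array([[np.nan, 0, 0]]))

    def test_forces_must_match_positions(self):
        with pytest.raises(ValueError):
            Geometry((1, 1), np.zeros((2, 3)), forces=np.zeros((3, 3)))

    def test_unsupported_element_rejected(self):
        with pytest.raises(ValueError):
            Geometry((26,), np.zeros((1, 3)))

    def test_positions_frozen_and_input_not_aliased(self):
        raw = np.zeros((1, 3))
        g = Geometry((1,), raw)
        raw[0, 0] = 5.0  # caller's array stays independent
        assert g.positions[0, 0] == 0.0
        with pytest.raises(ValueError):
            g.positions[0, 0] = 1.0


class TestPerceiveBonds:
    def test_far_apart_hydrogens_unbonded(self):
        g = geom(["H", "H"], [[0, 0, 0], [10, 0, 0]])
        assert perceive_bonds(g, 1.2).bonds == frozenset()

    def test_h2_bond_length_vs_scaled_radius_sum(self):
        # 0.74 Å against 1.2 × (r_H + r_H) = 0.744 Å from the shipped table
        cutoff = 1.2 * 2 * COVALENT_RADII["H"]
        assert 0.74 < cutoff
        g = geom(["H", "H"], [[0, 0, 0], [0.74, 0, 0]])
        assert perceive_bonds(g, 1.2).bonds == frozenset({(0, 1)})

    def test_toy_water_has_two_oh_bonds(self, water):
        graph = perceive_bonds(water, 1.2)
        assert graph.bonds == frozenset({(0, 1), (0, 2)})

    def test_overlapping_atoms_degenerate(self):
        g = geom(["H", "H"], [[0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            perceive_bonds(g, 1.2)

    def test_scale_range_enforced(self, water):
        for bad in (0.9, 1.0, 1.6):
            with pytest.raises(ValueError):
                perceive_bonds(water, bad)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        symbols = rng.choice(["H", "C", "O", "N"], size=5).tolist()
        pos = rng.uniform(-2, 2, (5, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        if d[np.triu_indices(5, 1)].min() < 0.2:
            return
        g = Geometry.from_symbols(symbols, pos)
        perm = rng.permutation(5)
        g2 = Geometry.from_symbols(
            [symbols[i] for i in np.argsort(perm)], pos[np.argsort(perm)]
        )
        b1 = perceive_bonds(g, 1.2)
        b2 = perceive_bonds(g2, 1.2)
        inv = np.argsort(perm)  # new index -> old atom
        back_mapped = frozenset(
            tuple(sorted((int(inv[i]), int(inv[j])))) for i, j in b2.bonds
        )
        assert b1.bonds == back_mapped


class TestHillFormula:
    @pytest.mark.parametrize(
        "symbols,expected",
        [
            (["C", "H", "H", "H", "H"], "CH4"),
            (["H", "H", "O"], "H2O"),
            (["O", "H", "N"], "HNO"),
            (["C"] * 4 + ["H"] * 4 + ["Cl", "N", "O"], "C4H4ClNO"),
        ],
    )
    def test_examples(self, symbols, expected):
        assert hill_formula(symbols) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hill_formula([])


def brute_isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Independent exhaustive permutation isomorphism oracle."""
    if sorted(a.elements) != sorted(b.elements) or len(a.bonds) != len(b.bonds):
        return False
    n = a.n_atoms
    for perm in itertools.permutations(range(n)):
        if any(a.elements[i] != b.elements[perm[i]] for i in range(n)):
            continue
        mapped = {tuple(sorted((perm[i], perm[j]))) for i, j in a.bonds}
        if mapped == set(b.bonds):
            return True
    return False


def random_graph(rng, n):
    symbols = rng.choice(["H", "C", "N", "O"], size=n).tolist()
    caps = {"H": 1, "C": 4, "N": 3, "O": 2}
    bonds = set()
    deg = [0] * n
    pairs = list(itertools.combinations(range(n), 2))
    rng.shuffle(pairs)
    for i, j in pairs:
        if rng.random() < 0.45 and deg[i] < caps[symbols[i]] and deg[j] < caps[symbols[j]]:
            bonds.add((i, j))
            deg[i] += 1
            deg[j] += 1
    return MolecularGraph(tuple(symbols), frozenset(bonds))


class TestCanonicalKey:
    def test_permuted_graph_same_key(self):
        g = MolecularGraph(("C", "O", "H", "H"), frozenset({(0, 1), (0, 2), (0, 3)}))
        perm = [2, 0, 3, 1]
        assert canonical_graph_key(g) == canonical_graph_key(g.permuted(perm))

    def test_different_element_multisets_differ(self):
        w = MolecularGraph(("O", "H", "H"), frozenset({(0, 1), (0, 2)}))
        a = MolecularGraph(("N", "H", "H"), frozenset({(0, 1), (0, 2)}))
        assert canonical_graph_key(w) != canonical_graph_key(a)

    def test_regular_graph_pair_distinguished(self):
        # one 6-cycle vs two triangles: identical degree sequences and
        # element multisets; only a genuine canonical form separates them
        cycle = MolecularGraph(
            ("C",) * 6, frozenset({(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)})
        )
        triangles = MolecularGraph(
            ("C",) * 6, frozenset({(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)})
        )
        assert canonical_graph_key(cycle) != canonical_graph_key(triangles)

    def test_key_equality_iff_isomorphism_on_random_graphs(self):
        rng = np.random.default_rng(42)
        graphs = [random_graph(rng, int(rng.integers(2, 7))) for _ in range(30)]
        # include relabeled copies to exercise the "equal" direction
        for g in graphs[:8]:
            perm = rng.permutation(g.n_atoms).tolist()
            graphs.append(g.permuted(perm))
        keys = [canonical_graph_key(g) for g in graphs]
        for (i, a), (j, b) in itertools.combinations(enumerate(graphs), 2):
            if a.n_atoms != b.n_atoms:
                continue
            assert (keys[i] == keys[j]) == brute_isomorphic(a, b)


class TestGraphDiff:
    def test_identical_graphs_empty_diff(self, water):
        g = perceive_bonds(water, 1.2)
        assert graph_diff(g, g) == (set(), set())

    def test_h2_dissociation_single_removal(self):
        a = MolecularGraph(("H", "H"), frozenset({(0, 1)}))
        b = MolecularGraph(("H", "H"), frozenset())
        assert graph_diff(a, b) == (set(), {(0, 1)})

    def test_mismatched_atom_lists_rejected(self):
        a = MolecularGraph(("H", "H"), frozenset({(0, 1)}))
        b = MolecularGraph(("O", "H"), frozenset({(0, 1)}))
        with pytest.raises(ValueError):
            graph_diff(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_set_arithmetic_oracle_and_swaps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        elements = tuple(rng.choice(["C", "N", "O"], size=n).tolist())
        pairs = list(itertools.combinations(range(n), 2))
        b1 = frozenset(p for p in pairs if rng.random() < 0.3)
        b2 = frozenset(p for p in pairs if rng.random() < 0.3)
        a = MolecularGraph(elements, b1, strict=False)
        b = MolecularGraph(elements, b2, strict=False)
        added, removed = graph_diff(a, b)
        assert added == set(b2) - set(b1)
        assert removed == set(b1) - set(b2)
        assert graph_diff(b, a) == (removed, added)


class TestClosedShell:
    @pytest.mark.parametrize(
        "elements,bonds,ok",
        [
            (("H", "H"), {(0, 1)}, True),  # H2
            (("H", "H"), set(), False),  # two radicals
            (("O", "H", "H"), {(0, 1), (0, 2)}, True),  # water
            (("O", "H"), {(0, 1)}, False),  # hydroxyl radical
            (("C", "O"), {(0, 1)}, False),  # deficiencies 3 vs 1 cannot pair up
            (("C", "H", "H", "O"), {(0, 1), (0, 2), (0, 3)}, True),  # H2C=O
        ],
    )
    def test_cases(self, elements, bonds, ok):
        g = MolecularGraph(elements, frozenset(bonds))
        assert is_closed_shell_realizable(g) is ok


class TestXYZ:
    def test_multiframe_roundtrip(self, tmp_path, water):
        labeled = water.with_labels(-10.2, np.zeros((3, 3)), level_tag="toy")
        bare = water.with_positions(water.positions)  # labels dropped
        path = tmp_path / "frames.xyz"
        write_xyz(path, [labeled, bare])
        frames = read_xyz(path)
        assert len(frames) == 2
        np.testing.assert_allclose(frames[0].positions, water.positions, atol=1e-9)
        assert frames[0].energy == pytest.approx(-10.2)
        assert frames[0].level_tag == "toy"
        assert frames[1].energy is None
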