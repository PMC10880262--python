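"""Jukes-Cantor distances, neighbor joining, and clade checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satarch.phylo import (
    DistanceMatrix,
    clade_partition_check,
    jc_distance,
    jc_inverse,
    neighbor_joining,
    pairwise_distances,
    parse_newick,
    topologies_equal,
)


def random_additive_tree(n, rng):
    """Random unrooted binary tree with positive branch lengths; returns
    (leaf labels, leaf-to-leaf path-length matrix, newick)."""
    import networkx as nx

    G = nx.Graph()
    G.add_edge("L0", "L1", w=float(rng.uniform(0.05, 1.0)))
    edges = [("L0", "L1")]
    inner = 0
    for k in range(2, n):
        u, v = edges[int(rng.integers(len(edges)))]
        G.remove_edge(u, v)
        edges.remove((u, v))
        mid = f"I{inner}"
        inner += 1
        for a, b in ((u, mid), (mid, v), (mid, f"L{k}")):
            G.add_edge(a, b, w=float(rng.uniform(0.05, 1.0)))
            edges.append((a, b))
    import networkx as nx

    leaves = [f"L{i}" for i in range(n)]
    dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="w"))
    m = np.array([[dist[a][b] for b in leaves] for a in leaves])
    return leaves, m


class TestJukesCantor:
    def test_known_values(self):
        assert jc_distance(0.0) == 0.0
        assert jc_distance(0.10) == pytest.approx(0.1073, abs=2e-4)

    def test_saturation_errors_unless_capped(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_distance(0.75)
        assert jc_distance(0.80, d_max=5.0) == 5.0

    def test_distance_exceeds_p_and_is_monotone(self):
        grid = np.linspace(0.01, 0.74, 40)
        d = [jc_distance(p) for p in grid]
        assert all(di >= pi for di, pi in zip(d, grid))
        assert all(b > a for a, b in zip(d, d[1:]))

    @given(st.floats(min_value=0.0, max_value=0.70))
    @settings(max_examples=50, derandomize=True)
    def test_inverse_round_trip(self, p):
        assert jc_inverse(jc_distance(p)) == pytest.approx(p, abs=1e-12)


class TestPairwiseDistances:
    def test_identical_sequences_give_zero_matrix(self):
        dm = pairwise_distances(["ACGTACGT" * 15] * 3)
        assert not dm.matrix.any()

    def test_twelve_of_120_diff_sites(self, library):
        cons = library["MiSat120_cons"].sequence
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        # scattered substitutions: minimal alignment is 12 mismatch columns
        mutated = "".join(
            flip[b] if i % 10 == 0 else b for i, b in enumerate(cons)
        )
        dm = pairwise_distances([cons, mutated, cons])
        assert dm.matrix[0, 1] == pytest.approx(jc_distance(0.10), abs=1e-9)

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_saturated_pair_capped_with_warning(self):
        import warnings

        a = "A" * 100
        b = "C" * 100
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            dm = pairwise_distances([a, b, a], d_max=4.0)
        assert dm.matrix[0, 1] == 4.0
        assert any("saturated" in str(x.message) for x in w)


class TestNeighborJoining:
    def test_four_taxon_topology(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        nwk = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert topologies_equal(nwk, "((A:1,B:2):1,(C:3,D:4):0);")

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        nwk = neighbor_joining(DistanceMatrix(list("ABC"), d))
        tree = parse_newick(nwk)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    def test_tie_break_is_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("ABCD"), d)
        assert neighbor_joining(dm) == neighbor_joining(dm)

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(list("ABC"), np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_recovered_exactly(self, seed):
        """NJ is consistent: tree distances reproduce any additive matrix."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        leaves, m = random_additive_tree(n, rng)
        nwk = neighbor_joining(DistanceMatrix(leaves, m))
        tree = parse_newick(nwk)
        tipd = tree.tip_tip_distances()
        ids = list(tipd.ids)
        got = np.array([[tipd[ids.index(a), ids.index(b)] for b in leaves] for a in leaves])
        np.testing.assert_allclose(got, m, atol=1e-8)

    def test_matches_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(123)
        leaves, m = random_additive_tree(8, rng)
        m = (m + m.T) / 2  # remove float asymmetry from path summation
        ours = neighbor_joining(DistanceMatrix(leaves, m))
        theirs = str(skbio_nj(SkbioDM(m, ids=leaves)))
        assert topologies_equal(ours, theirs)

    def test_newick_reparses_to_same_leafset(self):
        rng = np.random.default_rng(7)
        leaves, m = random_additive_tree(9, rng)
        nwk = neighbor_joining(DistanceMatrix(leaves, m))
        tree = parse_newick(nwk)
        assert {t.name for t in tree.tips()} == set(leaves)


class TestCladePartition:
    def test_perfect_split(self):
        ok, purity = clade_partition_check(
            "((A:1,B:1):1,(C:1,D:1):1);", {"A": "x", "B": "x", "C": "y", "D": "y"})
        assert ok and purity == 1.0

    def test_crossed_groups(self):
        ok, purity = clade_partition_check(
            "((A:1,B:1):1,(C:1,D:1):1);", {"A": "x", "C": "x", "B": "y", "D": "y"})
        assert not ok
        assert purity == 0.75

    def test_box_and_variant_monomers_separate(self, library, motif):
        """Monomers sharing a derived box-variant haplotype split from
        intact-box monomers into near-pure clades (mutations at disjoint
        position sets: shared box disruptions vs private noise)."""
        rng = np.random.default_rng(42)
        unit = library["MiSat120_cons"]
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        shared = list(unit.sequence)
        for off in (unit.box_offset + 2, unit.box_offset + 8, unit.box_offset + 14,
                    unit.box_offset + 15, unit.box_offset + 16):
            shared[off] = flip[shared[off]]
        shared = "".join(shared)

        def with_private_noise(base):
            s = list(base)
            for i in rng.choice(40, size=2, replace=False):  # outside the box
                s[i] = flip[s[i]]
            return "".join(s)

        seqs, labels, groups = [], [], {}
        for k in range(8):
            seqs.append(with_private_noise(unit.sequence))
            labels.append(f"box{k}")
            groups[f"box{k}"] = "box"
        for k in range(8):
            seqs.append(with_private_noise(shared))
            labels.append(f"nobox{k}")
            groups[f"nobox{k}"] = "nobox"
        dm = pairwise_distances(seqs, labels)
        nwk = neighbor_joining(dm)
        _ok, purity = clade_partition_check(nwk, groups)
        assert purity >= 0.9
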