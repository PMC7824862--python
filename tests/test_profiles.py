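import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import canberra as scipy_canberra

from jumbophage.families import ProteinFamily
from jumbophage.io import PhageGenome
from jumbophage.profiles import (
    Dendrogram,
    DistanceMatrix,
    PhyleticMatrix,
    build_matrix,
    canberra,
    cut_tree,
    dedupe_patterns,
    pairwise_distances,
    to_newick,
    upgma_cluster,
    ward_cluster,
    zscore_tree,
)


def _genomes(ids):
    return [PhageGenome(phage_id=p, genome_length=1000) for p in ids]


def _family(fid, members):
    phages = {m.split("|")[0] for m in members}
    return ProteinFamily(fid, frozenset(members), len(phages))


class TestBuildMatrix:
    def test_presence_row(self):
        fams = [
            _family("F1", {"P1|a", "P2|b"}),
            _family("F2", {"P3|c"}),
        ]
        m = build_matrix(fams, _genomes(["P1", "P2", "P3"]))
        assert m.family_ids == ["F1", "F2"]
        assert m.values.tolist() == [[1, 1, 0], [0, 0, 1]]

    def test_family_absent_everywhere_dropped_with_warning(self):
        fams = [_family("F1", {"P1|a"}), _family("F2", {"PX|z"})]
        with pytest.warns(UserWarning, match="F2"):
            m = build_matrix(fams, _genomes(["P1", "P2"]))
        assert m.family_ids == ["F1"]

    def test_unknown_selection_rejected(self):
        fams = [_family("F1", {"P1|a"})]
        with pytest.raises(ValueError, match="not found"):
            build_matrix(fams, _genomes(["P1"]), selected=["F1", "NOPE"])

    def test_min_phages_filter(self):
        fams = [
            _family("wide", {"P1|a", "P2|b", "P3|c"}),
            _family("narrow", {"P1|d"}),
        ]
        m = build_matrix(fams, _genomes(["P1", "P2", "P3"]), min_phages=2)
        assert m.family_ids == ["wide"]


class TestDedupePatterns:
    def test_identical_columns_collapse(self):
        m = PhyleticMatrix(["F1", "F2"], ["P1", "P2", "P3"], [[1, 1, 0], [0, 0, 1]])
        red, mapping = dedupe_patterns(m)
        assert red.phage_ids == ["P1", "P3"]
        assert mapping == {"P1": ["P1", "P2"], "P3": ["P3"]}

    def test_all_distinct_identity(self):
        m = PhyleticMatrix(["F1", "F2"], ["P1", "P2"], [[1, 0], [0, 1]])
        red, mapping = dedupe_patterns(m)
        assert red.phage_ids == ["P1", "P2"]

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 2, size=(4, 10))
        m = PhyleticMatrix([f"F{i}" for i in range(4)], [f"P{j}" for j in range(10)], vals)
        red, _ = dedupe_patterns(m)
        distinct = {tuple(vals[:, j]) for j in range(10)}
        assert len(red.phage_ids) == len(distinct)


class TestCanberra:
    def test_identity(self):
        assert canberra([1, 0, 1], [1, 0, 1]) == 0.0

    def test_binary_mismatch_count(self):
        assert canberra([1, 0, 1, 0], [1, 1, 0, 0]) == 2.0

    def test_nonbinary_terms(self):
        assert canberra([3, 1], [1, 1]) == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            canberra([1, 0], [1])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=30))
    def test_binary_equals_hamming_on_support(self, pairs):
        p = [a for a, _ in pairs]
        q = [b for _, b in pairs]
        assert canberra(p, q) == sum(a != b for a, b in pairs)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=1, max_size=20
        )
    )
    def test_agrees_with_scipy(self, pairs):
        p = np.array([a for a, _ in pairs], dtype=float)
        q = np.array([b for _, b in pairs], dtype=float)
        assert canberra(p, q) == pytest.approx(scipy_canberra(p, q))


class TestPairwiseDistances:
    def test_identical_phages_distance_zero(self):
        m = PhyleticMatrix(["F1", "F2"], ["P1", "P2"], [[1, 1], [0, 0]])
        dm = pairwise_distances(m, axis="phages")
        assert dm.d[0, 1] == 0.0

    def test_orthogonal_columns(self):
        m = PhyleticMatrix(["F1", "F2", "F3"], ["P1", "P2"], [[1, 0], [0, 1], [0, 1]])
        dm = pairwise_distances(m, axis="phages")
        assert dm.d[0, 1] == 3.0

    def test_families_axis_is_transpose_view(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2, (5, 6))
        m = PhyleticMatrix(
            [f"F{i}" for i in range(5)], [f"P{j}" for j in range(6)], vals
        )
        dm = pairwise_distances(m, axis="families")
        for i, j in itertools.combinations(range(5), 2):
            assert dm.d[i, j] == canberra(vals[i], vals[j])

    def test_symmetry_random(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 2, (7, 9))
        m = PhyleticMatrix(
            [f"F{i}" for i in range(7)], [f"P{j}" for j in range(9)], vals
        )
        dm = pairwise_distances(m)
        assert np.allclose(dm.d, dm.d.T) and np.all(np.diag(dm.d) == 0)

    def test_single_item_axis_rejected(self):
        m = PhyleticMatrix(["F1"], ["P1", "P2"], [[1, 0]])
        with pytest.raises(ValueError):
            pairwise_distances(m, axis="families")


def _brute_force_ward(d0, n, squared):
    """Exhaustive Ward agglomerator: evaluate the Lance-Williams criterion
    over all cluster pairs at every step."""
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            v = d0[i, j] ** 2 if squared else d0[i, j]
            d[(i, j)] = v
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    nxt = n
    for _ in range(n - 1):
        pairs = sorted((v, a, b) for (a, b), v in d.items() if a in active and b in active)
        v, a, b = pairs[0]
        merges.append((a, b, math.sqrt(v) if squared else v, sizes[a] + sizes[b]))
        for c in active - {a, b}:
            dac = d[tuple(sorted((a, c)))]
            dbc = d[tuple(sorted((b, c)))]
            t = sizes[a] + sizes[b] + sizes[c]
            d[(c, nxt)] = (
                (sizes[a] + sizes[c]) * dac + (sizes[b] + sizes[c]) * dbc - sizes[c] * v
            ) / t
        sizes[nxt] = sizes[a] + sizes[b]
        active -= {a, b}
        active.add(nxt)
        nxt += 1
    return merges


def _brute_force_upgma(d0, n):
    """Average linkage by direct average of all leaf-pair distances."""
    members = {i: {i} for i in range(n)}
    active = set(range(n))
    merges = []
    nxt = n
    for _ in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            v = np.mean([d0[i, j] for i in members[a] for j in members[b]])
            key = (v, a, b)
            if best is None or key < best:
                best = key
        v, a, b = best
        members[nxt] = members[a] | members[b]
        merges.append((a, b, v, len(members[nxt])))
        active -= {a, b}
        active.add(nxt)
        nxt += 1
    return merges


def _random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return d


class TestWard:
    def test_two_items_merge_at_distance(self):
        dm = DistanceMatrix(["A", "B"], [[0, 2.5], [2.5, 0]])
        t = ward_cluster(dm, variant="ward_d2")
        assert t.merges == [(0, 1, 2.5, 2)]

    def test_hand_computed_three_points(self):
        # 1-D points {0, 1, 5}: merge (a,b) at 1, then height
        # sqrt((2*25 + 2*16 - 1) / 3) = sqrt(27)
        d = np.array([[0, 1, 5], [1, 0, 4], [5, 4, 0]], dtype=float)
        t = ward_cluster(DistanceMatrix(["a", "b", "c"], d), variant="ward_d2")
        (a, b, h1, _), (_, _, h2, _) = t.merges
        assert (a, b) == (0, 1) and h1 == pytest.approx(1.0)
        assert h2 == pytest.approx(math.sqrt(27))

    @pytest.mark.parametrize("variant,squared", [("ward_d2", True), ("ward_d", False)])
    def test_matches_exhaustive_oracle(self, variant, squared):
        rng = np.random.default_rng(23)
        for n in (4, 5, 6, 7, 8):
            d = _random_distance_matrix(rng, n)
            t = ward_cluster(DistanceMatrix([f"l{i}" for i in range(n)], d), variant=variant)
            oracle = _brute_force_ward(d, n, squared)
            for got, exp in zip(t.merges, oracle):
                assert got[:2] == exp[:2]
                assert got[2] == pytest.approx(exp[2])

    @pytest.mark.parametrize("variant", ["ward_d2", "ward_d"])
    def test_heights_monotone(self, variant):
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = _random_distance_matrix(rng, 12)
            t = ward_cluster(DistanceMatrix([f"l{i}" for i in range(12)], d), variant=variant)
            heights = [h for _, _, h, _ in t.merges]
            assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))

    def test_ward_d2_agrees_with_scipy(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(31)
        d = _random_distance_matrix(rng, 15)
        t = ward_cluster(DistanceMatrix([f"l{i}" for i in range(15)], d))
        z = linkage(squareform(d), method="ward")
        assert np.allclose([m[2] for m in t.merges], z[:, 2])

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], [[0, 1], [2, 0]])


class TestUPGMA:
    def test_closest_pair_merges_first(self):
        z = np.array([[10, 9, 2], [9, 10, 2], [2, 2, 10]], dtype=float)
        t = zscore_tree(z, ["A", "B", "C"])
        assert t.merges[0][:2] == (0, 1)

    def test_constant_offdiagonal_same_height(self):
        z = np.full((4, 4), 3.0)
        np.fill_diagonal(z, 9.0)
        t = zscore_tree(z, list("ABCD"))
        heights = {round(h, 9) for _, _, h, _ in t.merges}
        assert len(heights) == 1

    def test_matches_brute_force_average_linkage(self):
        rng = np.random.default_rng(13)
        for n in (4, 5, 6, 7):
            d = _random_distance_matrix(rng, n)
            t = upgma_cluster(DistanceMatrix([f"l{i}" for i in range(n)], d))
            oracle = _brute_force_upgma(d, n)
            for got, exp in zip(t.merges, oracle):
                assert got[:2] == exp[:2]
                assert got[2] == pytest.approx(exp[2])

    def test_asymmetric_z_rejected(self):
        z = np.array([[5, 1.0], [1.1, 5]])
        with pytest.raises(ValueError, match="asymmetric"):
            zscore_tree(z, ["A", "B"])


class TestCutTree:
    @pytest.fixture()
    def planted_tree(self):
        # two well-separated triples
        pts = np.array([0.0, 0.5, 1.0, 100.0, 100.5, 101.0])
        d = np.abs(pts[:, None] - pts[None, :])
        ids = list("ABCDEF")
        return ward_cluster(DistanceMatrix(ids, d))

    def test_k1_and_kn(self, planted_tree):
        assert set(cut_tree(planted_tree, 1).values()) == {0}
        assert len(set(cut_tree(planted_tree, 6).values())) == 6

    def test_recovers_planted_bipartition(self, planted_tree):
        labels = cut_tree(planted_tree, 2)
        assert labels["A"] == labels["B"] == labels["C"]
        assert labels["D"] == labels["E"] == labels["F"]
        assert labels["A"] != labels["D"]

    def test_out_of_range(self, planted_tree):
        with pytest.raises(ValueError):
            cut_tree(planted_tree, 0)
        with pytest.raises(ValueError):
            cut_tree(planted_tree, 7)

    def test_labels_invariant_to_leaf_order(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=8)
        d = np.abs(pts[:, None] - pts[None, :])
        ids = [f"L{i}" for i in range(8)]
        t1 = ward_cluster(DistanceMatrix(ids, d))
        perm = rng.permutation(8)
        t2 = ward_cluster(DistanceMatrix([ids[i] for i in perm], d[np.ix_(perm, perm)]))
        l1, l2 = cut_tree(t1, 3), cut_tree(t2, 3)
        # same partition up to label renaming
        from sklearn.metrics import adjusted_rand_score

        items = sorted(l1)
        assert adjusted_rand_score([l1[i] for i in items], [l2[i] for i in items]) == 1.0


class TestNewick:
    def test_two_leaves(self):
        t = Dendrogram(["A", "B"], [(0, 1, 1.0, 2)])
        assert to_newick(t) == "(A:1,B:1);"

    def test_three_leaf_internal_branch_length(self):
        d = np.array([[0, 1, 5], [1, 0, 4], [5, 4, 0]], dtype=float)
        t = ward_cluster(DistanceMatrix(["a", "b", "c"], d))
        nwk = to_newick(t)
        # internal branch = sqrt(27) - 1
        import re

        lengths = sorted(float(x) for x in re.findall(r":([0-9.]+)", nwk))
        assert any(abs(v - (math.sqrt(27) - 1)) < 1e-5 for v in lengths)

    def test_round_trip_topology(self):
        import dendropy

        rng = np.random.default_rng(11)
        d = _random_distance_matrix(rng, 9)
        ids = [f"leaf{i}" for i in range(9)]
        t = ward_cluster(DistanceMatrix(ids, d))
        tree = dendropy.Tree.get(data=to_newick(t), schema="newick")
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(ids)
        # bipartitions of the parsed tree match the merge tree's clusters
        n = len(ids)
        clusters = {}
        for step, (a, b, _h, _s) in enumerate(t.merges):
            ca = clusters.get(a, {a} if a < n else None) or clusters[a]
            cb = clusters.get(b, {b} if b < n else None) or clusters[b]
            clusters[n + step] = ca | cb
        expected = {
            frozenset(ids[i] for i in c) for c in clusters.values() if len(c) < n
        }
        got = set()
        for node in tree.preorder_node_iter():
            leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(leaves) < n:
                got.add(leaves)
        assert got == expected
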