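import numpy as np
import pytest

from ksforge.dedup import (
    DsMatrix,
    average_linkage,
    build_ds_matrix,
    correct_all,
    correct_family,
    correct_subfamily,
    cut_k,
    find_subfamilies,
    Subfamily,
)
from ksforge.mcl import GeneFamily
from ksforge.ng86 import PairwiseDs
from .oracles import brute_average_linkage, brute_cut


def _pair(a, b, ds, saturated=False):
    return PairwiseDs(a, b, 100, 200, 10, 10, 0.1, ds, 0.05, 300, saturated)


def _matrix(ids, entries, fill=10.0):
    """entries: dict of (i, j) -> ds; missing pairs undefined."""
    n = len(ids)
    d = np.full((n, n), fill)
    defined = np.zeros((n, n), bool)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(defined, True)
    for (i, j), v in entries.items():
        d[i, j] = d[j, i] = v
        defined[i, j] = defined[j, i] = True
    return DsMatrix("F1", tuple(ids), d, defined, fill)


THREE = _matrix(["g1", "g2", "g3"], {(0, 1): 0.1, (0, 2): 1.0, (1, 2): 1.2})


class TestBuildMatrix:
    def test_two_member_family(self):
        fam = GeneFamily("F1", ("a", "b"))
        m = build_ds_matrix(fam, [_pair("a", "b", 0.42)])
        assert m.d[0, 1] == 0.42 and m.defined[0, 1]

    def test_saturated_pair_filled(self):
        fam = GeneFamily("F1", ("a", "b"))
        m = build_ds_matrix(fam, [_pair("a", "b", float("nan"), saturated=True)])
        assert m.d[0, 1] == 10.0 and not m.defined[0, 1]

    def test_complete_family_all_defined(self):
        ids = ("a", "b", "c", "d")
        fam = GeneFamily("F1", ids)
        pairs = [
            _pair(ids[i], ids[j], 0.1 * (i + j))
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        m = build_ds_matrix(fam, pairs)
        assert m.defined.all()

    def test_foreign_pair_rejected(self):
        fam = GeneFamily("F1", ("a", "b"))
        with pytest.raises(ValueError):
            build_ds_matrix(fam, [_pair("a", "zzz", 0.4)])


class TestLinkage:
    def test_hand_worked_example(self):
        dg = average_linkage(THREE)
        assert dg.merges[0].members == ("g1", "g2")
        assert dg.merges[0].height == pytest.approx(0.1)
        assert dg.merges[1].height == pytest.approx(1.1)  # mean(1.0, 1.2)

    def test_two_member(self):
        m = _matrix(["a", "b"], {(0, 1): 0.42})
        dg = average_linkage(m)
        assert len(dg.merges) == 1 and dg.merges[0].height == pytest.approx(0.42)

    def test_equal_distances_tie_order(self):
        m = _matrix(["a", "b", "c"], {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5})
        dg = average_linkage(m)
        assert dg.merges[0].members == ("a", "b")  # smallest lexicographic pair
        assert all(mg.height == pytest.approx(0.5) for mg in dg.merges)

    def test_heights_monotone(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            ids = [f"g{i}" for i in range(n)]
            entries = {
                (i, j): float(rng.uniform(0.01, 3))
                for i in range(n)
                for j in range(i + 1, n)
            }
            dg = average_linkage(_matrix(ids, entries))
            heights = [mg.height for mg in dg.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            ids = [f"g{i}" for i in range(n)]
            entries = {
                (i, j): float(rng.uniform(0.01, 3))
                for i in range(n)
                for j in range(i + 1, n)
            }
            m = _matrix(ids, entries)
            dg = average_linkage(m)
            oracle = brute_average_linkage(m.d, list(ids))
            for mine, (members, height) in zip(dg.merges, oracle):
                assert mine.members == members
                assert mine.height == pytest.approx(height, abs=1e-12)
            for k in range(1, n + 1):
                assert cut_k(dg, k) == brute_cut(oracle, list(ids), k)

    def test_matches_scipy_on_distinct_distances(self, rng):
        from scipy.cluster.hierarchy import average, cut_tree
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = int(rng.integers(3, 7))
            ids = [f"g{i}" for i in range(n)]
            vals = rng.permutation(np.linspace(0.1, 2.0, n * (n - 1) // 2))
            entries = {}
            k = 0
            for i in range(n):
                for j in range(i + 1, n):
                    entries[(i, j)] = float(vals[k])
                    k += 1
            m = _matrix(ids, entries)
            dg = average_linkage(m)
            Z = average(squareform(m.d))
            assert [mg.height for mg in dg.merges] == pytest.approx(
                list(Z[:, 2]), abs=1e-10
            )
            for k_clusters in range(1, n + 1):
                labels = cut_tree(Z, n_clusters=k_clusters).ravel()
                scipy_parts = sorted(
                    tuple(sorted(ids[i] for i in range(n) if labels[i] == lab))
                    for lab in set(labels)
                )
                assert cut_k(dg, k_clusters) == scipy_parts


class TestCut:
    def test_cut_examples(self):
        dg = average_linkage(THREE)
        assert cut_k(dg, 1) == [("g1", "g2", "g3")]
        assert cut_k(dg, 2) == [("g1", "g2"), ("g3",)]
        assert cut_k(dg, 3) == [("g1",), ("g2",), ("g3",)]

    def test_out_of_range(self):
        dg = average_linkage(THREE)
        with pytest.raises(ValueError):
            cut_k(dg, 0)
        with pytest.raises(ValueError):
            cut_k(dg, 4)


class TestSubfamilies:
    def test_all_below_threshold_one_subfamily(self):
        subs = find_subfamilies(THREE)
        assert len(subs) == 1 and subs[0].members == ("g1", "g2", "g3")

    def test_fill_entries_split(self):
        m = _matrix(["g1", "g2", "g3", "g4"], {(0, 1): 0.5, (2, 3): 0.6})
        subs = find_subfamilies(m)
        assert sorted(s.members for s in subs) == [("g1", "g2"), ("g3", "g4")]

    def test_singleton(self):
        m = _matrix(["only"], {})
        (sub,) = find_subfamilies(m)
        assert sub.members == ("only",)

    def test_no_defined_ds_above_threshold_inside(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 8))
            ids = [f"g{i}" for i in range(n)]
            entries = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.8:
                        entries[(i, j)] = float(rng.uniform(0.05, 8.0))
            m = _matrix(ids, entries)
            index = {g: i for i, g in enumerate(ids)}
            for sub in find_subfamilies(m):
                for a in sub.members:
                    for b in sub.members:
                        if a < b:
                            i, j = index[a], index[b]
                            assert m.defined[i, j] and m.d[i, j] < 5.0


class TestCorrection:
    def test_worked_example_deepest_split(self):
        sf = Subfamily("F1", ("g1", "g2", "g3"))
        (event,) = correct_subfamily(sf, THREE, mode="deepest_split")
        assert event.ds == pytest.approx(1.1)
        assert event.weight == 2

    def test_worked_example_recursive(self):
        sf = Subfamily("F1", ("g1", "g2", "g3"))
        events = correct_subfamily(sf, THREE, mode="recursive")
        assert sorted((round(e.ds, 6), e.weight) for e in events) == [
            (0.1, 1),
            (1.1, 2),
        ]

    def test_two_member_subfamily(self):
        m = _matrix(["a", "b"], {(0, 1): 0.42})
        (event,) = correct_subfamily(Subfamily("F1", ("a", "b")), m)
        assert event.ds == pytest.approx(0.42) and event.weight == 1

    def test_event_within_cross_pair_range(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            ids = [f"g{i}" for i in range(n)]
            entries = {
                (i, j): float(rng.uniform(0.05, 4.0))
                for i in range(n)
                for j in range(i + 1, n)
            }
            m = _matrix(ids, entries)
            events = correct_subfamily(Subfamily("F1", tuple(ids)), m, mode="recursive")
            lo = min(entries.values())
            hi = max(entries.values())
            for e in events:
                assert lo - 1e-12 <= e.ds <= hi + 1e-12
            assert len(events) <= n - 1

    def test_two_member_families_pass_through(self):
        fams = [GeneFamily("F1", ("a", "b")), GeneFamily("F2", ("c", "d"))]
        pairs = {"F1": [_pair("a", "b", 0.3)], "F2": [_pair("c", "d", 1.7)]}
        events = correct_all(fams, pairs)
        assert [round(e.ds, 6) for e in events] == [0.3, 1.7]

    def test_deterministic_output(self, rng):
        fam = GeneFamily("F1", ("a", "b", "c", "d"))
        pairs = [
            _pair(x, y, float(rng.uniform(0.1, 2)))
            for x, y in [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        ]
        e1 = correct_family(fam, pairs, mode="recursive")
        e2 = correct_family(fam, pairs, mode="recursive")
        assert e1 == e2
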