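import numpy as np
import pytest

from ksforge.seqio import GeneRecord
from ksforge.similarity import (
    ConfigError,
    HitsParseError,
    SimilarityHit,
    build_graph,
    builtin_all_vs_all,
    parse_tabular_hits,
)


def _hit(q, s, evalue, bitscore=100.0):
    return SimilarityHit(q, s, 90.0, 100, evalue, bitscore)


class TestParseTabular:
    LINE = "a\tb\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-50\t200\n"

    def test_basic_line(self, tmp_path):
        p = tmp_path / "hits.m8"
        p.write_text(self.LINE)
        (hit,) = parse_tabular_hits(p)
        assert (hit.query, hit.subject) == ("a", "b")
        assert hit.evalue == 1e-50 and hit.bitscore == 200
        assert hit.pct_identity == 90.0 and hit.aln_len == 100

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "hits.m8"
        p.write_text("a\tb\t90.0\t100\t1e-50\t200\n")
        with pytest.raises(HitsParseError, match="line 1"):
            parse_tabular_hits(p)

    def test_zero_evalue(self, tmp_path):
        p = tmp_path / "hits.m8"
        p.write_text(self.LINE.replace("1e-50", "0.0"))
        assert parse_tabular_hits(p)[0].evalue == 0.0


class TestBuildGraph:
    def test_cutoff_boundary_inclusive(self):
        g = build_graph([_hit("a", "b", 1e-10), _hit("c", "d", 1e-9)])
        assert g.weight("a", "b") == 10.0
        assert g.weight("c", "d") is None

    def test_reciprocal_mean(self):
        g = build_graph([_hit("a", "b", 1e-20), _hit("b", "a", 1e-40)])
        assert g.weight("a", "b") == pytest.approx(30.0)

    def test_zero_evalue_capped(self):
        g = build_graph([_hit("a", "b", 0.0)])
        assert g.weight("a", "b") == 200.0

    def test_self_hits_discarded(self):
        g = build_graph([_hit("a", "a", 1e-50)])
        assert g.edges == {}

    def test_duplicate_lines_invariant(self):
        hits = [_hit("a", "b", 1e-20)]
        g1 = build_graph(hits)
        g2 = build_graph(hits * 3)
        assert g1.edges == g2.edges

    def test_cutoff_monotonicity(self, rng):
        hits = [
            _hit(f"g{i}", f"g{j}", 10.0 ** -rng.integers(5, 40))
            for i in range(6)
            for j in range(6)
            if i != j
        ]
        loose = set(build_graph(hits, evalue_cutoff=1e-5).edges)
        strict = set(build_graph(hits, evalue_cutoff=1e-20).edges)
        assert strict <= loose

    def test_isolated_nodes_from_gene_list(self):
        g = build_graph([_hit("a", "b", 1e-20)], nodes=["a", "b", "lonely"])
        assert "lonely" in g.nodes
        assert all(w > 0 for w in g.edges.values())


class TestBuiltinSearch:
    def _records(self, rng, n=2, length=100):
        from ksforge.simulate import random_cds
        from ksforge.seqio import translate_cds

        out = []
        for i in range(n):
            cds = random_cds(length, rng)
            out.append(GeneRecord(f"g{i}", cds, translate_cds(cds)))
        return out

    def test_exact_copy_reciprocal_equal_scores(self, rng):
        a, b = self._records(rng, 2)
        copy = GeneRecord("copy", a.cds, a.protein)
        hits = builtin_all_vs_all([a, copy, b])
        pairs = {(h.query, h.subject) for h in hits}
        assert ("g0", "copy") in pairs and ("copy", "g0") in pairs
        scores = {h.bitscore for h in hits if {h.query, h.subject} == {"g0", "copy"}}
        assert len(scores) == 1

    def test_no_self_hits(self, rng):
        a, b = self._records(rng, 2)
        copy = GeneRecord("copy", a.cds, a.protein)
        hits = builtin_all_vs_all([a, copy, b])
        assert all(h.query != h.subject for h in hits)

    def test_unrelated_sequences_no_hit(self, rng):
        recs = self._records(rng, 2, length=60)
        hits = [h for h in builtin_all_vs_all(recs) if h.evalue <= 1e-10]
        assert hits == []

    def test_diverged_paralogs_found(self, rng):
        from ksforge.simulate import diverge_pair, random_cds
        from ksforge.seqio import translate_cds

        cds = random_cds(200, rng)
        a, b = diverge_pair(cds, 0.6, rng)
        recs = [
            GeneRecord("pa", a, translate_cds(a)),
            GeneRecord("pb", b, translate_cds(b)),
        ] + self._records(rng, 3, 200)
        g = build_graph(builtin_all_vs_all(recs), evalue_cutoff=1e-10)
        assert g.weight("pa", "pb") is not None

    def test_unknown_matrix(self, rng):
        with pytest.raises(ConfigError):
            builtin_all_vs_all(self._records(rng, 2), matrix="NOSUCH99")

    def test_graph_invariants(self, rng):
        from ksforge.simulate import diverge_pair, random_cds
        from ksforge.seqio import translate_cds

        recs = []
        for i in range(4):
            cds = random_cds(120, rng)
            a, b = diverge_pair(cds, 0.3, rng)
            recs.append(GeneRecord(f"f{i}a", a, translate_cds(a)))
            recs.append(GeneRecord(f"f{i}b", b, translate_cds(b)))
        g = build_graph(builtin_all_vs_all(recs))
        for (a, b), w in g.edges.items():
            assert a < b and 0 < w <= 200.0
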