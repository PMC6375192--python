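import shutil

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ksforge.codon_align import (
    AlignmentValidationError,
    CodonAlignment,
    ProteinAlignment,
    align_family,
    align_family_external,
    backtranslate,
    extract_pairs,
    validate_external_alignment,
)
from ksforge.seqio import translate_cds


class TestAlignFamily:
    def test_identical_proteins_gapless(self):
        pa = align_family([("a", "MKVLL"), ("b", "MKVLL")])
        assert pa.rows == ("MKVLL", "MKVLL")

    def test_single_gap(self):
        pa = align_family([("a", "MKV"), ("b", "MV")])
        assert pa.length == 3
        assert pa.rows[0] == "MKV"
        assert pa.rows[1].replace("-", "") == "MV"
        assert pa.rows[1].count("-") == 1

    def test_degapped_rows_reproduce_inputs(self, rng):
        from ksforge.simulate import diverge_pair, random_cds

        cds = random_cds(60, rng)
        seqs = []
        for i in range(5):
            a, _ = diverge_pair(cds, 0.4, rng)
            seqs.append((f"m{i}", translate_cds(a)))
        pa = align_family(seqs)
        assert pa.length >= max(len(s) for _, s in seqs)
        for (name, seq), row in zip(seqs, pa.rows):
            assert row.replace("-", "") == seq

    def test_member_order_preserved(self):
        pa = align_family([("z", "MKV"), ("a", "MKV"), ("m", "MKV")])
        assert pa.ids == ("z", "a", "m")


class TestExternalAligner:
    def test_validation_error_names_member(self):
        with pytest.raises(AlignmentValidationError, match="b"):
            validate_external_alignment(
                [("a", "MKV"), ("b", "MV")], [("a", "MKV"), ("b", "MKV")]
            )

    @pytest.mark.skipif(shutil.which("mafft") is None, reason="mafft not on PATH")
    def test_mafft_roundtrip(self):
        proteins = [("a", "MKVAAILS"), ("b", "MKVAILS"), ("c", "MKVAAVLS")]
        pa = align_family_external(proteins, ["mafft", "--quiet", "-"])
        for (name, seq), row in zip(proteins, pa.rows):
            assert row.replace("-", "") == seq


class TestBacktranslate:
    def test_gap_becomes_triple_dash(self):
        pa = ProteinAlignment(("a",), ("M-A",))
        ca = backtranslate(pa, {"a": "ATGGCA"})
        assert ca.rows == ("ATG---GCA",)

    def test_gapless_row_is_cds(self):
        pa = ProteinAlignment(("a",), ("MA",))
        ca = backtranslate(pa, {"a": "ATGGCA"})
        assert ca.rows[0] == "ATGGCA"

    def test_length_mismatch_errors(self):
        pa = ProteinAlignment(("a",), ("MAA",))
        with pytest.raises(ValueError):
            backtranslate(pa, {"a": "ATGGCA"})

    @given(st.integers(2, 30), st.integers(0, 5))
    def test_translate_degap_roundtrip(self, n_codons, gaps):
        import numpy as np

        from ksforge.simulate import random_cds

        rng = np.random.default_rng(n_codons * 31 + gaps)
        cds = random_cds(n_codons, rng)
        protein = translate_cds(cds)
        row = list(protein)
        for g in rng.integers(0, len(row) + 1, size=gaps):
            row.insert(int(g), "-")
        pa = ProteinAlignment(("a",), ("".join(row),))
        ca = backtranslate(pa, {"a": cds})
        degapped = ca.rows[0].replace("-", "")
        assert degapped == cds
        assert translate_cds(degapped) == protein


class TestExtractPairs:
    def _ca(self, rows):
        return CodonAlignment(tuple(f"g{i}" for i in range(len(rows))), tuple(rows))

    def test_strict_90bp_boundary(self):
        row = "GCT" * 30  # exactly 90 bp
        assert extract_pairs(self._ca([row, row])) == []
        row = "GCT" * 31  # 93 bp
        (pair,) = extract_pairs(self._ca([row, row]))
        assert pair.stripped_bp == 93

    def test_gap_column_stripped_in_frame(self):
        a = "GCT" * 4 + "AAA" + "GCT" * 27
        b = "GCT" * 4 + "---" + "GCT" * 27
        (pair,) = extract_pairs(self._ca([a, b]))
        assert pair.stripped_bp == 93
        assert all(len(c) == 3 and "-" not in c for c in pair.codons_a + pair.codons_b)

    def test_n_codons_stripped(self):
        a = "GCT" * 31 + "GCN"
        b = "GCT" * 31 + "GCA"
        (pair,) = extract_pairs(self._ca([a, b]))
        assert pair.stripped_bp == 93

    def test_pair_count_bound(self):
        rows = ["GCT" * 40] * 5
        pairs = extract_pairs(self._ca(rows))
        assert len(pairs) == 5 * 4 // 2

    def test_symmetric_in_member_order(self):
        a = "GCT" * 20 + "---" * 5 + "GCA" * 20
        b = "GCT" * 45
        p1 = extract_pairs(self._ca([a, b]))[0]
        p2 = extract_pairs(self._ca([b, a]))[0]
        assert p1.codons_a == p2.codons_b and p1.codons_b == p2.codons_a
        assert p1.stripped_bp % 3 == 0
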