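import numpy as np
import pytest
from scipy.stats import spearmanr

from ksforge.codon_align import StrippedPair
from ksforge.ng86 import ng86_distance
from ksforge.seqio import translate_cds
from ksforge.simulate import (
    SimConfig,
    diverge_pair,
    pair_depth_from_paths,
    random_cds,
    simulate_paranome,
    write_paranome,
)


def _estimate(a: str, b: str) -> float:
    ca = tuple(a[i : i + 3] for i in range(0, len(a), 3))
    cb = tuple(b[i : i + 3] for i in range(0, len(b), 3))
    r = ng86_distance(StrippedPair("a", "b", ca, cb))
    return float("nan") if r.saturated else r.dS


class TestRandomCds:
    def test_length_and_no_stops(self):
        cds = random_cds(2, 1)
        assert len(cds) == 6 and "*" not in translate_cds(cds)
        assert "*" not in translate_cds(random_cds(10_000, 5))

    def test_deterministic(self):
        assert random_cds(100, 7) == random_cds(100, 7)


class TestDivergePair:
    def test_target_zero_identity(self):
        cds = random_cds(100, 3)
        a, b = diverge_pair(cds, 0.0, 3)
        assert a == cds and b == cds

    def test_copies_stay_translatable(self, rng):
        cds = random_cds(200, rng)
        a, b = diverge_pair(cds, 1.0, rng)
        assert "*" not in translate_cds(a) and "*" not in translate_cds(b)

    @pytest.mark.parametrize("target", [0.2, 0.6, 1.2, 2.0])
    def test_calibration_contract(self, target):
        """Mean NG86 estimate within 5% of the requested depth."""
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(200):
            cds = random_cds(300, rng)
            a, b = diverge_pair(cds, target, rng)
            d = _estimate(a, b)
            if np.isfinite(d):
                ests.append(d)
        assert abs(np.mean(ests) - target) / target < 0.05

    def test_monotone_in_target(self):
        rng = np.random.default_rng(13)
        targets = [0.2, 0.6, 1.2, 1.8]
        means = []
        for t in targets:
            ests = []
            for _ in range(60):
                cds = random_cds(300, rng)
                a, b = diverge_pair(cds, t, rng)
                d = _estimate(a, b)
                if np.isfinite(d):
                    ests.append(d)
            means.append(np.mean(ests))
        rho, _ = spearmanr(targets, means)
        assert rho == 1.0


class TestSimulateParanome:
    def test_no_events_all_singletons(self):
        records, truth = simulate_paranome(SimConfig(n_families=20, seed=1))
        assert len(records) == 20 and truth.pair_depths == {}

    def test_full_retention_pairs_at_wgd_depth(self):
        cfg = SimConfig(n_families=15, wgd_depths=[0.6], wgd_retention=1.0, seed=2)
        records, truth = simulate_paranome(cfg)
        assert len(records) == 30
        assert all(d == 0.6 for d in truth.pair_depths.values())
        fams = {}
        for r in records:
            fams.setdefault(r.gene_id.split("_")[0], []).append(r)
        assert all(len(v) == 2 for v in fams.values())

    def test_retention_binomial_bounds(self):
        cfg = SimConfig(n_families=500, wgd_depths=[0.6], wgd_retention=0.4, seed=3)
        records, truth = simulate_paranome(cfg)
        n_dup = sum(1 for _ in truth.pair_depths)
        mean, sd = 500 * 0.4, np.sqrt(500 * 0.4 * 0.6)
        assert mean - 3 * sd < n_dup < mean + 3 * sd

    def test_byte_identical_given_seed(self, tmp_path):
        cfg = SimConfig(n_families=10, wgd_depths=[0.5], wgd_retention=0.5, seed=9)
        for i in (1, 2):
            write_paranome(cfg, tmp_path / f"c{i}.fa", tmp_path / f"p{i}.fa")
        assert (tmp_path / "c1.fa").read_bytes() == (tmp_path / "c2.fa").read_bytes()
        assert (tmp_path / "p1.fa").read_bytes() == (tmp_path / "p2.fa").read_bytes()

    def test_pair_depth_is_most_recent_common_event(self):
        p_a = [("w0", 0, 1.9), ("w1", 0, 0.6)]
        p_b = [("w0", 0, 1.9), ("w1", 1, 0.6)]
        p_c = [("w0", 1, 1.9)]
        assert pair_depth_from_paths(p_a, p_b) == 0.6
        assert pair_depth_from_paths(p_a, p_c) == 1.9

    def test_two_wave_truth_depths(self):
        cfg = SimConfig(
            n_families=60, wgd_depths=[0.6, 1.9], wgd_retention=[0.5, 0.5], seed=4
        )
        _, truth = simulate_paranome(cfg)
        assert set(truth.pair_depths.values()) <= {0.6, 1.9}
        assert {0.6, 1.9} <= set(truth.pair_depths.values())

    def test_estimated_ds_tracks_truth(self):
        cfg = SimConfig(n_families=40, wgd_depths=[0.6], wgd_retention=1.0, seed=5)
        records, truth = simulate_paranome(cfg)
        by_fam = {}
        for r in records:
            by_fam.setdefault(r.gene_id.split("_")[0], []).append(r)
        ests = []
        for fam in by_fam.values():
            ests.append(_estimate(fam[0].cds, fam[1].cds))
        assert abs(np.nanmean(ests) - 0.6) < 0.05
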