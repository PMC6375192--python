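"""Synthetic paranome generator with ground-truth duplication depths.

Each gene family starts from one random ancestral CDS. Whole-genome
duplication (WGD) waves are applied oldest-first, each duplicating every
surviving lineage with a retention probability at the wave's stated dS
depth; optional small-scale duplications (SSDs) hit random lineages at
uniform depths. Gene identifiers encode the lineage path, so the true
divergence depth of any pair is recomputable from ids alone.

Sequence divergence is generated per site, not with a full codon model:
every position that has synonymous single-nucleotide alternatives
evolves as a uniform Markov chain over its frozen synonymous state set,
and a low nonsynonymous component (default dN/dS = 0.2) is applied to
positions with no synonymous alternatives. The chain "time" applied for
a divergence depth d is obtained by numerical inversion: the expected
Nei–Gojobori estimate (including the Jukes–Cantor transform's convexity
and the exclusion of saturated estimates) is computed semi-analytically
as a function of chain time, and solved so that the mean estimated dS
equals the target depth. This is deliberate: the generator's job is to
control true dS as seen by the estimator under test, not to be a
maximally realistic evolutionary model.

Chain times compose additively along the lineage tree, so nested
duplications receive consistent depths: an edge from a split at depth
d1 down to a split at d2 carries chain time g(d1) - g(d2), where g is
half the inverted pair time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .ng86 import SENSE_CODONS, syn_fraction
from .seqio import CODON_TO_AA, STOP_CODONS, GeneRecord, translate_cds, write_fasta

_NT = "ACGT"


@dataclass
class SimConfig:
    n_families: int
    codons_per_gene: int = 300
    wgd_depths: Sequence[float] = ()
    wgd_retention: float | Sequence[float] = 1.0
    ssd_rate: float = 0.0
    ssd_depth_range: tuple[float, float] = (0.1, 2.0)
    dn_ds: float = 0.2
    seed: int = 0

    def retentions(self) -> list[float]:
        if isinstance(self.wgd_retention, (int, float)):
            return [float(self.wgd_retention)] * len(self.wgd_depths)
        rets = [float(r) for r in self.wgd_retention]
        if len(rets) != len(self.wgd_depths):
            raise ValueError("wgd_retention length must match wgd_depths")
        return rets

    def validate(self) -> None:
        if self.n_families < 1 or self.codons_per_gene < 1:
            raise ValueError("n_families and codons_per_gene must be positive")
        if any(d < 0 for d in self.wgd_depths):
            raise ValueError("WGD depths must be non-negative")
        if any(not 0 <= r <= 1 for r in self.retentions()):
            raise ValueError("retention probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    """True pairwise divergence depths and the event list per family."""

    pair_depths: dict[tuple[str, str], float] = field(default_factory=dict)
    events: list[tuple[str, str, float]] = field(default_factory=list)

    def depth(self, gene_a: str, gene_b: str) -> float:
        key = (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)
        return self.pair_depths[key]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#events\nfamily\ttype\tdepth\n")
            for fam, etype, depth in self.events:
                fh.write(f"{fam}\t{etype}\t{depth:.6f}\n")
            fh.write("#pairs\ngene_a\tgene_b\tdepth\n")
            for (a, b), depth in sorted(self.pair_depths.items()):
                fh.write(f"{a}\t{b}\t{depth:.6f}\n")


def random_cds(n_codons: int, rng: np.random.Generator | int) -> str:
    """Uniform random sense codons (no stops); deterministic given the seed."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _position_alternatives(cds: str) -> tuple[list, list, float, float]:
    """Classify every position of a CDS by its substitution options.

    Returns (syn_sites, nonsyn_sites, S_anc, N_anc). ``syn_sites`` holds
    (position, state_set) for positions with >= 1 synonymous non-stop
    alternative, the state set being the ancestor base plus those
    alternatives (frozen for the whole family). ``nonsyn_sites`` holds
    the analogous sets for positions with nonsynonymous alternatives
    only, so the two processes never collide at one position.
    """
    syn_sites = []
    nonsyn_sites = []
    S_anc = 0.0
    for c0 in range(0, len(cds), 3):
        codon = cds[c0 : c0 + 3]
        aa0 = CODON_TO_AA[codon]
        S_anc += syn_fraction(codon)
        for pos in range(3):
            syn_alts = []
            nonsyn_alts = []
            for alt in _NT:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                if CODON_TO_AA[mutant] == aa0:
                    syn_alts.append(alt)
                else:
                    nonsyn_alts.append(alt)
            if syn_alts:
                syn_sites.append((c0 + pos, (codon[pos], *syn_alts)))
            elif nonsyn_alts:
                nonsyn_sites.append((c0 + pos, (codon[pos], *nonsyn_alts)))
    N_anc = 3 * (len(cds) // 3) - S_anc
    return syn_sites, nonsyn_sites, S_anc, N_anc


def _p_differ(n_alts: int, tau: float) -> float:
    """P(two chain endpoints differ) for a uniform chain over n_alts+1 states
    run for total time ``tau`` (time = expected substitutions per site)."""
    k = n_alts + 1
    return (n_alts / k) * -math.expm1(-k * tau / n_alts)


def _jc(p: np.ndarray) -> np.ndarray:
    return -0.75 * np.log1p(-(4.0 / 3.0) * np.clip(p, 0.0, 0.749999))


class FamilyModel:
    """Per-family calibration and sequence-evolution machinery."""

    def __init__(self, anc_cds: str, dn_ds: float = 0.2):
        self.anc = anc_cds
        self.dn_ds = dn_ds
        syn_sites, nonsyn_sites, self.S_anc, self.N_anc = _position_alternatives(anc_cds)
        self.syn_by_class: dict[int, tuple[np.ndarray, list]] = {}
        self.nonsyn_by_class: dict[int, tuple[np.ndarray, list]] = {}
        for sites, store in ((syn_sites, self.syn_by_class), (nonsyn_sites, self.nonsyn_by_class)):
            by_a: dict[int, list] = {}
            for pos, states in sites:
                by_a.setdefault(len(states) - 1, []).append((pos, states))
            for a, entries in by_a.items():
                store[a] = (
                    np.array([e[0] for e in entries], dtype=np.int64),
                    [e[1] for e in entries],
                )
        # first-order correction of the expected synonymous site count:
        # sum over single-position variants of the change in whole-codon
        # synonymous fraction, grouped by site class
        self._s_delta: dict[int, float] = {}
        for a, (positions, state_sets) in self.syn_by_class.items():
            delta = 0.0
            for pos, states in zip(positions, state_sets):
                c0 = 3 * (pos // 3)
                codon = anc_cds[c0 : c0 + 3]
                base = syn_fraction(codon)
                off = pos - c0
                for alt in states[1:]:
                    mutant = codon[:off] + alt + codon[off + 1 :]
                    delta += syn_fraction(mutant) - base
            self._s_delta[a] = delta
        self._tau_syn_cache: dict[float, float] = {}
        self._tau_nonsyn_cache: dict[float, float] = {}

    # --- calibration -----------------------------------------------------

    def _expected_S(self, tau: float) -> float:
        s = self.S_anc
        for a, delta in self._s_delta.items():
            k = a + 1
            p_other = (1.0 / k) * -math.expm1(-k * tau / a)  # per specific alt state
            s += p_other * delta
        return s

    def _ps_moments(self, tau: float) -> tuple[float, float]:
        e_sd = 0.0
        v_sd = 0.0
        for a, (positions, _) in self.syn_by_class.items():
            p = _p_differ(a, tau)
            n = len(positions)
            e_sd += n * p
            v_sd += n * p * (1.0 - p)
        s = self._expected_S(tau)
        return e_sd / s, v_sd / (s * s)

    def _expected_estimate(self, tau: float) -> float:
        """Mean NG86+JC dS over non-saturated replicates at chain time tau.

        Approximates pS as Normal with the moments above, truncates at
        the saturation boundary (saturated replicates are excluded from
        the contract's mean), and integrates the Jukes–Cantor transform
        numerically — the transform's convexity makes the mean estimate
        exceed JC(E[pS]) appreciably near saturation, so plain pS-level
        inversion would overshoot the mean contract there.
        """
        mean, var = self._ps_moments(tau)
        sd = math.sqrt(max(var, 1e-12))
        lo = max(0.0, mean - 6 * sd)
        hi = min(0.749999, mean + 6 * sd)
        if hi <= lo:
            return float(_jc(np.array([min(mean, 0.749999)]))[0])
        p = np.linspace(lo, hi, 257)
        w = np.exp(-0.5 * ((p - mean) / sd) ** 2)
        mass = np.trapezoid(w, p)
        if mass <= 0:
            return float(_jc(np.array([mean]))[0])
        return float(np.trapezoid(_jc(p) * w, p) / mass)

    def analytic_pair_time(self, depth: float) -> float:
        """Chain time whose expected NG86 dS estimate equals ``depth``."""
        if depth <= 0:
            return 0.0
        hi = 30.0
        if self._expected_estimate(hi) <= depth:
            return hi  # depth beyond reachable saturation; clamp
        return brentq(lambda t: self._expected_estimate(t) - depth, 1e-9, hi, xtol=1e-6)

    def pair_time_syn(self, depth: float) -> float:
        """Calibrated chain time for a pair at divergence depth ``depth``.

        The semi-analytic inversion treats synonymous sites as
        independent; within-codon interactions (a second change can turn
        a synonymous difference nonsynonymous in context) make the
        realized estimate fall short at high depth. A cached Monte-Carlo
        refinement factor (see :func:`_calibration_factor`) absorbs that
        residual.
        """
        if depth <= 0:
            return 0.0
        cached = self._tau_syn_cache.get(depth)
        if cached is not None:
            return cached
        n_codons = len(self.anc) // 3
        tau = self.analytic_pair_time(depth) * _calibration_factor(
            n_codons, self.dn_ds, depth
        )
        self._tau_syn_cache[depth] = tau
        return tau

    def pair_time_nonsyn(self, depth: float) -> float:
        if depth <= 0 or self.dn_ds <= 0 or not self.nonsyn_by_class:
            return 0.0
        cached = self._tau_nonsyn_cache.get(depth)
        if cached is not None:
            return cached
        target_pn = 0.75 * -math.expm1(-4.0 * self.dn_ds * depth / 3.0)

        def f(tau: float) -> float:
            e_nd = sum(
                len(pos) * _p_differ(a, tau) for a, (pos, _) in self.nonsyn_by_class.items()
            )
            return e_nd / self.N_anc - target_pn

        hi = 30.0
        tau = hi if f(hi) <= 0 else brentq(f, 1e-12, hi, xtol=1e-8)
        self._tau_nonsyn_cache[depth] = tau
        return tau

    # --- evolution -------------------------------------------------------

    def mutate(self, seq: list[str], tau_syn: float, tau_nonsyn: float,
               rng: np.random.Generator) -> list[str]:
        """Evolve a sequence (list of bases) for the given chain times."""
        out = list(seq)
        touched: set[int] = set()
        for tau, table in ((tau_syn, self.syn_by_class), (tau_nonsyn, self.nonsyn_by_class)):
            if tau <= 0:
                continue
            for a, (positions, state_sets) in sorted(table.items()):
                k = a + 1
                p_stay = 1.0 / k + (a / k) * math.exp(-k * tau / a)
                u = rng.random(len(positions))
                choice = rng.integers(0, a, size=len(positions))
                for i in np.flatnonzero(u >= p_stay):
                    states = state_sets[i]
                    cur = out[positions[i]]
                    alts = [s for s in states if s != cur]
                    out[positions[i]] = alts[choice[i] % len(alts)]
                    touched.add(positions[i] // 3)
        # two individually safe changes within one codon can combine into a
        # stop; such codons (rare) revert to their pre-mutation state
        for c in touched:
            if "".join(out[3 * c : 3 * c + 3]) in STOP_CODONS:
                out[3 * c : 3 * c + 3] = seq[3 * c : 3 * c + 3]
        return out


_CAL_CACHE: dict[tuple[int, float, float], float] = {}


def _calibration_factor(
    n_codons: int,
    dn_ds: float,
    depth: float,
    n_reps: int = 192,
    rel_tol: float = 0.01,
    max_iter: int = 6,
) -> float:
    """Monte-Carlo refinement of the chain-time inversion.

    Simulates replicate pairs on fresh random ancestors (fixed internal
    seed derived from the cache key, so results are deterministic and
    reusable across calls), measures the mean NG86 estimate, and adjusts
    a multiplicative factor on the analytic chain time until the mean
    matches the target depth. The update maps the observed mean back
    through the analytic expectation curve, i.e. a model-based Newton
    step on the time axis.
    """
    key = (n_codons, round(dn_ds, 6), round(depth, 6))
    cached = _CAL_CACHE.get(key)
    if cached is not None:
        return cached
    if depth <= 0:
        _CAL_CACHE[key] = 1.0
        return 1.0
    from .codon_align import StrippedPair
    from .ng86 import ng86_distance

    cal_seed = (hash(key) & 0x7FFFFFFF) ^ 0x5EED
    rng = np.random.default_rng(cal_seed)
    ancestors = [random_cds(n_codons, rng) for _ in range(n_reps)]
    models = [FamilyModel(anc, dn_ds=dn_ds) for anc in ancestors]
    base_tau = [m.analytic_pair_time(depth) for m in models]
    base_tau_n = [m.pair_time_nonsyn(depth) for m in models]
    ref = models[0]

    tau_want = ref.analytic_pair_time(depth)
    factor = 1.0
    for _ in range(max_iter):
        ests = []
        for m, tau, tau_n in zip(models, base_tau, base_tau_n):
            a = m.mutate(list(m.anc), factor * tau / 2.0, tau_n / 2.0, rng)
            b = m.mutate(list(m.anc), factor * tau / 2.0, tau_n / 2.0, rng)
            ca = tuple("".join(a[i : i + 3]) for i in range(0, len(a), 3))
            cb = tuple("".join(b[i : i + 3]) for i in range(0, len(b), 3))
            r = ng86_distance(StrippedPair("a", "b", ca, cb))
            if not r.saturated:
                ests.append(r.dS)
        if not ests:
            break
        mean_est = float(np.mean(ests))
        if abs(mean_est - depth) / depth < rel_tol:
            break
        # map the observed mean back through the expectation curve and
        # take a multiplicative Newton step on the time axis
        tau_obs = ref.analytic_pair_time(min(mean_est, 8.0))
        if tau_obs <= 0:
            break
        factor *= min(max(tau_want / tau_obs, 0.5), 2.0)
    _CAL_CACHE[key] = factor
    return factor


def diverge_pair(
    cds: str,
    target_ds: float,
    rng: np.random.Generator | int,
    dn_ds: float = 0.2,
) -> tuple[str, str]:
    """Evolve two copies of a CDS so their expected NG86 dS is ``target_ds``.

    Each copy is evolved independently for half the inverted chain time;
    chain times are additive, so the pair separation equals the full
    calibrated time.
    """
    if target_ds < 0:
        raise ValueError("target_ds must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    model = FamilyModel(cds, dn_ds=dn_ds)
    half_s = model.pair_time_syn(target_ds) / 2.0
    half_n = model.pair_time_nonsyn(target_ds) / 2.0
    a = model.mutate(list(cds), half_s, half_n, rng)
    b = model.mutate(list(cds), half_s, half_n, rng)
    return "".join(a), "".join(b)


def _build_lineages(
    events: Sequence[tuple[str, float]],
    retentions: Sequence[float],
    rng: np.random.Generator,
) -> list[list[tuple[str, int, float]]]:
    """Apply duplication events oldest-first to a single root lineage.

    Each lineage is a path: a list of (event_label, side, depth) for the
    splits it went through. WGD events duplicate every surviving lineage
    with their retention probability; SSD events duplicate one uniformly
    chosen lineage.
    """
    lineages: list[list[tuple[str, int, float]]] = [[]]
    for (label, depth), retention in zip(events, retentions):
        if label.startswith("w"):
            nxt = []
            for lin in lineages:
                if rng.random() < retention:
                    nxt.append(lin + [(label, 0, depth)])
                    nxt.append(lin + [(label, 1, depth)])
                else:
                    nxt.append(lin)
            lineages = nxt
        else:
            k = int(rng.integers(0, len(lineages)))
            lin = lineages.pop(k)
            lineages.append(lin + [(label, 0, depth)])
            lineages.append(lin + [(label, 1, depth)])
    return lineages


def _leaf_id(family: str, path: list[tuple[str, int, float]]) -> str:
    if not path:
        return f"{family}_r"
    return family + "_" + "-".join(f"{label}{'ab'[side]}" for label, side, _ in path)


def _emit_leaves(
    model: FamilyModel,
    group: list[tuple[int, list[tuple[str, int, float]]]],
    pos: int,
    top_depth: float | None,
    seq: list[str],
    rng: np.random.Generator,
    out: dict[int, str],
) -> None:
    """Recursively evolve down the lineage tree and record leaf sequences."""
    if len(group) == 1 and len(group[0][1]) == pos:
        leaf_idx = group[0][0]
        if top_depth is not None:
            seq = model.mutate(
                seq,
                model.pair_time_syn(top_depth) / 2.0,
                model.pair_time_nonsyn(top_depth) / 2.0,
                rng,
            )
        out[leaf_idx] = "".join(seq)
        return
    label, _, d_next = group[0][1][pos]
    if top_depth is not None:
        tau_s = (model.pair_time_syn(top_depth) - model.pair_time_syn(d_next)) / 2.0
        tau_n = (model.pair_time_nonsyn(top_depth) - model.pair_time_nonsyn(d_next)) / 2.0
        seq = model.mutate(seq, max(tau_s, 0.0), max(tau_n, 0.0), rng)
    sides: dict[int, list] = {0: [], 1: []}
    for leaf_idx, path in group:
        sides[path[pos][1]].append((leaf_idx, path))
    for side in (0, 1):
        if sides[side]:
            _emit_leaves(model, sides[side], pos + 1, d_next, list(seq), rng, out)


def simulate_family(
    family_id: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: GroundTruth,
) -> list[GeneRecord]:
    wgds = sorted(
        zip((f"w{i}" for i in range(len(cfg.wgd_depths))), cfg.wgd_depths, cfg.retentions()),
        key=lambda t: -t[1],
    )
    n_ssd = rng.poisson(cfg.ssd_rate) if cfg.ssd_rate > 0 else 0
    ssds = [
        (f"s{j}", float(rng.uniform(*cfg.ssd_depth_range)), 1.0) for j in range(n_ssd)
    ]
    all_events = sorted(wgds + ssds, key=lambda t: -t[1])
    lineages = _build_lineages(
        [(label, depth) for label, depth, _ in all_events],
        [ret for _, _, ret in all_events],
        rng,
    )
    anc = random_cds(cfg.codons_per_gene, rng)
    model = FamilyModel(anc, dn_ds=cfg.dn_ds)
    seqs: dict[int, str] = {}
    group = list(enumerate(lineages))
    _emit_leaves(model, group, 0, None, list(anc), rng, seqs)
    records = []
    for idx, path in enumerate(lineages):
        gid = _leaf_id(family_id, path)
        cds = seqs[idx]
        records.append(GeneRecord(gid, cds, translate_cds(cds)))
    # ground truth: events actually realized, and per-pair depths
    realized = {label for lin in lineages for label, _, _ in lin}
    for label, depth, _ in all_events:
        if label in realized:
            truth.events.append((family_id, "WGD" if label.startswith("w") else "SSD", depth))
    for i in range(len(lineages)):
        for j in range(i + 1, len(lineages)):
            truth.pair_depths[
                tuple(
                    sorted((_leaf_id(family_id, lineages[i]), _leaf_id(family_id, lineages[j])))
                )
            ] = pair_depth_from_paths(lineages[i], lineages[j])
    return records


def pair_depth_from_paths(path_a, path_b) -> float:
    """Depth of the most recent common duplication of two lineages."""
    for (la, sa, da), (lb, sb, db) in zip(path_a, path_b):
        if la != lb or sa != sb:
            return float(da)
    raise ValueError("lineage paths do not diverge")


def pair_depth_from_ids(gene_a: str, gene_b: str, truth: GroundTruth) -> float:
    return truth.depth(gene_a, gene_b)


def simulate_paranome(cfg: SimConfig) -> tuple[list[GeneRecord], GroundTruth]:
    """Generate a full synthetic paranome.

    Deterministic: the same config (including seed) yields byte-identical
    sequences and ids.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_families)))
    truth = GroundTruth()
    records: list[GeneRecord] = []
    for i in range(1, cfg.n_families + 1):
        records.extend(simulate_family(f"SF{i:0{width}d}", cfg, rng, truth))
    return records, truth


def write_paranome(
    cfg: SimConfig,
    cds_path: str | Path,
    pep_path: str | Path,
    truth_path: str | Path | None = None,
) -> tuple[list[GeneRecord], GroundTruth]:
    records, truth = simulate_paranome(cfg)
    write_fasta(((r.gene_id, r.cds) for r in records), cds_path)
    write_fasta(((r.gene_id, r.protein) for r in records), pep_path)
    if truth_path is not None:
        truth.to_tsv(truth_path)
    return records, truth
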