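"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's lookup tables and clustering code:
the genetic code comes from Biopython's translator, site counting and
pathway enumeration are recomputed from first principles per call, and
the linkage oracle re-derives cluster means from scratch at every step.
"""

from __future__ import annotations

import functools
import itertools
import math

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
NUCS = "ACGT"


@functools.lru_cache(maxsize=None)
def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


@functools.lru_cache(maxsize=None)
def brute_syn_fraction(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        syn = denom = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOPS:
                continue
            denom += 1
            if aa_of(mut) == aa_of(codon):
                syn += 1
        if denom:
            total += syn / denom
    return total


@functools.lru_cache(maxsize=None)
def brute_codon_diff(a: str, b: str) -> tuple[float, float]:
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in itertools.permutations(positions):
        cur = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                nd += 1
            elif cur in STOPS:
                nd += 1
            elif aa_of(nxt) == aa_of(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if blocked else clean).append((sd, nd))
    use = clean if clean else dirty
    return (
        sum(x[0] for x in use) / len(use),
        sum(x[1] for x in use) / len(use),
    )


def brute_ng86(codons_a, codons_b):
    """Returns (S, N, Sd, Nd, dS) with dS = nan when saturated."""
    L = len(codons_a)
    S = 0.5 * (
        sum(brute_syn_fraction(c) for c in codons_a)
        + sum(brute_syn_fraction(c) for c in codons_b)
    )
    N = 3 * L - S
    Sd = Nd = 0.0
    for x, y in zip(codons_a, codons_b):
        sd, nd = brute_codon_diff(x, y)
        Sd += sd
        Nd += nd
    if S <= 0:
        return S, N, Sd, Nd, math.nan
    pS = Sd / S
    dS = math.nan if pS >= 0.75 else -0.75 * math.log(1 - 4 * pS / 3)
    return S, N, Sd, Nd, dS


def brute_average_linkage(d: np.ndarray, ids: list[str]):
    """Naive agglomeration; returns the merge list [(members, height), ...]."""
    clusters = [[i] for i in ids]
    index = {g: k for k, g in enumerate(ids)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                vals = [d[index[x], index[y]] for x in clusters[a] for y in clusters[b]]
                mean = sum(vals) / len(vals)
                rep = tuple(sorted((min(clusters[a]), min(clusters[b]))))
                if best is None or (mean, rep) < best[:2]:
                    best = (mean, rep, a, b)
        mean, _, a, b = best
        merged = sorted(clusters[a] + clusters[b])
        merges.append((tuple(merged), mean))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def brute_cut(merges, ids, k: int):
    """Partition after replaying the first n-k merges."""
    parent = {g: g for g in ids}

    def find(g):
        while parent[g] != g:
            g = parent[g]
        return g

    for members, _ in merges[: len(ids) - k]:
        roots = sorted({find(m) for m in members})
        for r in roots[1:]:
            parent[r] = roots[0]
    groups: dict[str, list[str]] = {}
    for g in ids:
        groups.setdefault(find(g), []).append(g)
    return sorted((tuple(sorted(v)) for v in groups.values()), key=lambda c: c[0])
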