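"""Nei–Gojobori (1986) pairwise synonymous distance with Jukes–Cantor correction.

The NG86 method counts, for each codon, the fraction of its three sites
that are synonymous (a site's fraction is the share of the possible
single-nucleotide changes at that position which preserve the amino acid,
with changes to stop codons excluded from both numerator and denominator).
Differences between two codons are resolved by enumerating every ordering
of the single-nucleotide steps between them, discarding orderings that
pass through a stop codon, and averaging the synonymous/nonsynonymous step
counts over the remaining orderings. The proportion of synonymous
differences per synonymous site, pS = Sd/S, is then corrected for multiple
hits with the Jukes–Cantor formula

    dS = -(3/4) * ln(1 - (4/3) * pS),

which is undefined (saturated) once pS >= 3/4.

All 64x64 codon-pair difference counts and per-codon site fractions are
precomputed at import, so distances over long alignments reduce to table
lookups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .seqio import CODON_TO_AA, STOP_CODONS

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}

ALL_CODONS = [a + b + c for a in _NT for b in _NT for c in _NT]
CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]


def _aa(codon: str) -> str | None:
    """Amino acid of a codon, or None for a stop codon."""
    return CODON_TO_AA.get(codon)


def syn_fraction(codon: str) -> float:
    """Fractional number of synonymous sites in a codon (range [0, 3]).

    Per position, the fraction of the three possible single-nucleotide
    changes that are synonymous, among the changes that do not create a
    stop codon.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if codon not in CODON_INDEX:
        raise ValueError(f"invalid codon {codon!r}")
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        tot = 0
        for alt in _NT:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue  # excluded from numerator and denominator
            tot += 1
            if _aa(mutant) == aa0:
                syn += 1
        if tot:
            s += syn / tot
    return s


def codon_diff(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    Enumerates every ordering of the single-nucleotide steps from
    ``codon_a`` to ``codon_b``; orderings that pass through a stop codon
    are discarded. If every ordering is blocked, all orderings are used
    with stop-creating steps counted as nonsynonymous.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c!r} not allowed")
        if c not in CODON_INDEX:
            raise ValueError(f"invalid codon {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                if not allow_stops:
                    return None
                nd += 1  # stop-creating step counted as nonsynonymous
            elif _aa(cur) is None or _aa(nxt) is None:
                nd += 1  # step out of / into a stop in fallback mode
            elif _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return (sd, nd)

    valid = [r for order in permutations(diff_pos) if (r := walk(order, False)) is not None]
    if not valid:
        valid = [walk(order, True) for order in permutations(diff_pos)]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return (sd, nd)


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    syn = np.full(64, np.nan)
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for i, ci in enumerate(ALL_CODONS):
        if ci in STOP_CODONS:
            continue
        syn[i] = syn_fraction(ci)
        for j, cj in enumerate(ALL_CODONS):
            if cj in STOP_CODONS:
                continue
            sd[i, j], nd[i, j] = codon_diff(ci, cj)
    return syn, sd, nd


SYN_SITES, SD_TABLE, ND_TABLE = _build_tables()


def encode_codons(codons) -> np.ndarray:
    """Encode an iterable of codon strings (A/C/G/T only) as table indices."""
    idx = np.empty(len(codons), dtype=np.int64)
    for k, codon in enumerate(codons):
        try:
            idx[k] = (
                16 * _NT_INDEX[codon[0]] + 4 * _NT_INDEX[codon[1]] + _NT_INDEX[codon[2]]
            )
        except KeyError:
            raise ValueError(f"cannot encode codon {codon!r}") from None
    return idx


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p); nan at p >= 3/4."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class PairwiseDs:
    """NG86 statistics for one paralog pair.

    ``saturated`` is set when pS >= 3/4 (or S == 0), in which case ``dS``
    is nan. ``dN`` is nan analogously when pN >= 3/4.
    """

    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    dS: float
    dN: float
    stripped_bp: int
    saturated: bool


def ng86_distance(pair) -> PairwiseDs:
    """Compute NG86 dS/dN for a gap-stripped codon pair.

    ``pair`` is a :class:`~ksforge.codon_align.StrippedPair`: two
    equal-length codon lists free of gaps, Ns and stop codons.
    """
    ia = encode_codons(pair.codons_a)
    ib = encode_codons(pair.codons_b)
    if len(ia) != len(ib):
        raise ValueError("codon lists differ in length")
    L = len(ia)
    sa = SYN_SITES[ia]
    sb = SYN_SITES[ib]
    if np.isnan(sa).any() or np.isnan(sb).any():
        raise ValueError("stop codon in stripped pair")
    S = 0.5 * (sa.sum() + sb.sum())
    N = 3.0 * L - S
    Sd = float(SD_TABLE[ia, ib].sum())
    Nd = float(ND_TABLE[ia, ib].sum())

    if S <= 0.0:
        pS, dS, saturated = math.inf, math.nan, True
    else:
        pS = Sd / S
        dS = jukes_cantor(pS)
        saturated = pS >= 0.75
    dN = jukes_cantor(Nd / N) if N > 0 else math.nan
    return PairwiseDs(
        gene_a=pair.gene_a,
        gene_b=pair.gene_b,
        S=float(S),
        N=float(N),
        Sd=Sd,
        Nd=Nd,
        pS=float(pS),
        dS=float(dS),
        dN=float(dN),
        stripped_bp=3 * L,
        saturated=bool(saturated),
    )
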