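"""Protein alignment per gene family, codon back-translation and pair extraction.

Each multi-member gene family is aligned at the protein level, the
alignment is back-translated onto the CDS (every aligned residue replaced
by its source codon, gaps becoming ``---``), and gap-stripped codon pairs
are extracted for dS estimation. Pairs whose gap-stripped length is not
strictly greater than ``min_bp`` nucleotides are discarded.

The built-in aligner is a standard progressive scheme: a 3-mer cosine
distance matrix, an average-linkage guide tree, and profile–profile
Needleman–Wunsch/Gotoh with BLOSUM62 and affine gaps (open 10, extend
0.5). It is intended for desk-scale work and testing; at genome scale an
external aligner (e.g. MAFFT) can be plugged in through
:func:`align_family_external` — the contract is aligned FASTA on stdout
given FASTA on stdin.
"""

from __future__ import annotations

import subprocess
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import translate_cds

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}
_SCORE = np.array(
    [[_BLOSUM[a, b] for b in _ALPHABET] for a in _ALPHABET], dtype=np.float64
)
_NSYM = len(_ALPHABET)


class AlignmentValidationError(ValueError):
    """An externally supplied alignment does not reproduce its inputs."""


@dataclass(frozen=True)
class ProteinAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentValidationError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class CodonAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class StrippedPair:
    """A gap/N/stop-stripped codon pair ready for NG86."""

    gene_a: str
    gene_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    @property
    def stripped_bp(self) -> int:
        return 3 * len(self.codons_a)


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Column frequency profile; gaps carry zero weight in scoring."""
    L = len(rows[0])
    prof = np.zeros((L, _NSYM), dtype=np.float64)
    for row in rows:
        for j, aa in enumerate(row):
            if aa != "-":
                prof[j, _AA_INDEX.get(aa, _AA_INDEX["X"])] += 1.0
    return prof / len(rows)


@njit(cache=True)
def _gotoh(C, gap_open, gap_extend):  # pragma: no cover - exercised via wrapper
    """Affine-gap global alignment over a precomputed column-score matrix.

    Returns the traceback as an array of ops (0=match, 1=gap in B, 2=gap
    in A), rightmost-aligned in the output buffer.
    """
    n, m = C.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A row)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B column)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
        ptrX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
        ptrY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = C[i - 1, j - 1]
            bm, bx, by = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            if bm >= bx and bm >= by:
                M[i, j] = bm + s
                ptrM[i, j] = 0
            elif bx >= by:
                M[i, j] = bx + s
                ptrM[i, j] = 1
            else:
                M[i, j] = by + s
                ptrM[i, j] = 2
            om = M[i - 1, j] - gap_open
            ox = X[i - 1, j] - gap_extend
            if om >= ox:
                X[i, j] = om
                ptrX[i, j] = 0
            else:
                X[i, j] = ox
                ptrX[i, j] = 1
            om = M[i, j - 1] - gap_open
            oy = Y[i, j - 1] - gap_extend
            if om >= oy:
                Y[i, j] = om
                ptrY[i, j] = 0
            else:
                Y[i, j] = oy
                ptrY[i, j] = 2
    # traceback
    ops = np.empty(n + m, dtype=np.uint8)
    k = n + m
    i, j = n, m
    if M[i, j] >= X[i, j] and M[i, j] >= Y[i, j]:
        state = 0
    elif X[i, j] >= Y[i, j]:
        state = 1
    else:
        state = 2
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0
            state = ptrM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = ptrX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = ptrY[i, j]
            j -= 1
    return ops[k:]


def _align_profiles(rows_a: Sequence[str], rows_b: Sequence[str]) -> tuple[list[str], list[str]]:
    pa = _profile(rows_a)
    pb = _profile(rows_b)
    C = pa @ _SCORE @ pb.T
    ops = _gotoh(C, GAP_OPEN, GAP_EXTEND)
    la = len(rows_a[0])
    out_a = []
    out_b = []
    i = j = 0
    cols_a: list[int] = []  # source column or -1 for gap
    cols_b: list[int] = []
    for op in ops:
        if op == 0:
            cols_a.append(i)
            cols_b.append(j)
            i += 1
            j += 1
        elif op == 1:
            cols_a.append(i)
            cols_b.append(-1)
            i += 1
        else:
            cols_a.append(-1)
            cols_b.append(j)
            j += 1
    assert i == la and j == len(rows_b[0])
    for row in rows_a:
        out_a.append("".join(row[c] if c >= 0 else "-" for c in cols_a))
    for row in rows_b:
        out_b.append("".join(row[c] if c >= 0 else "-" for c in cols_b))
    return out_a, out_b


def _kmer_cosine_distances(proteins: Sequence[str], k: int = 3) -> np.ndarray:
    counts = [Counter(p[i : i + k] for i in range(max(len(p) - k + 1, 1))) for p in proteins]
    n = len(proteins)
    d = np.zeros((n, n))
    norms = [np.sqrt(sum(v * v for v in c.values())) or 1.0 for c in counts]
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(counts[i]) & set(counts[j])
            dot = sum(counts[i][x] * counts[j][x] for x in shared)
            d[i, j] = d[j, i] = 1.0 - dot / (norms[i] * norms[j])
    return d


def _upgma_order(d: np.ndarray) -> list:
    """Average-linkage guide tree, returned as a nested merge structure."""
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    trees: dict[int, object] = {i: i for i in range(n)}
    nxt = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                mean = float(
                    np.mean([d[x, y] for x in clusters[a] for y in clusters[b]])
                )
                key = (mean, min(clusters[a]), min(clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        trees[nxt] = (trees.pop(a), trees.pop(b))
        nxt += 1
    return trees[nxt - 1]


def align_family(proteins: Sequence[tuple[str, str]]) -> ProteinAlignment:
    """Progressively align a family's proteins (built-in aligner)."""
    if len(proteins) < 2:
        raise ValueError("align_family needs at least 2 members")
    ids = [p[0] for p in proteins]
    seqs = [p[1] for p in proteins]
    if len(proteins) == 2:
        ra, rb = _align_profiles([seqs[0]], [seqs[1]])
        return ProteinAlignment(tuple(ids), (ra[0], rb[0]))
    d = _kmer_cosine_distances(seqs)
    tree = _upgma_order(d)

    def build(node) -> tuple[list[int], list[str]]:
        if isinstance(node, int):
            return [node], [seqs[node]]
        left_ids, left_rows = build(node[0])
        right_ids, right_rows = build(node[1])
        ra, rb = _align_profiles(left_rows, right_rows)
        return left_ids + right_ids, ra + rb

    member_order, rows = build(tree)
    # restore input member order
    pos = {m: i for i, m in enumerate(member_order)}
    rows = [rows[pos[i]] for i in range(len(ids))]
    return ProteinAlignment(tuple(ids), tuple(rows))


def align_family_external(
    proteins: Sequence[tuple[str, str]],
    command: Sequence[str] | str,
) -> ProteinAlignment:
    """Align via an external tool reading FASTA on stdin, writing aligned FASTA.

    The result is validated: each degapped row must equal its input
    protein, otherwise :class:`AlignmentValidationError` names the member.
    """
    fasta = "".join(f">{name}\n{seq}\n" for name, seq in proteins)
    if isinstance(command, str):
        command = command.split()
    proc = subprocess.run(
        list(command), input=fasta, capture_output=True, text=True, check=True
    )
    entries: list[tuple[str, str]] = []
    name = None
    buf: list[str] = []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if name is not None:
                entries.append((name, "".join(buf)))
            name = line[1:].split()[0]
            buf = []
        elif name is not None:
            buf.append(line.strip())
    if name is not None:
        entries.append((name, "".join(buf)))
    return validate_external_alignment(proteins, entries)


def validate_external_alignment(
    proteins: Sequence[tuple[str, str]],
    aligned: Sequence[tuple[str, str]],
) -> ProteinAlignment:
    aligned_map = {n: s.upper() for n, s in aligned}
    rows = []
    for name, seq in proteins:
        if name not in aligned_map:
            raise AlignmentValidationError(f"member {name} missing from alignment")
        row = aligned_map[name]
        if row.replace("-", "") != seq.upper():
            raise AlignmentValidationError(
                f"degapped alignment row for member {name} does not match its protein"
            )
        rows.append(row)
    return ProteinAlignment(tuple(n for n, _ in proteins), tuple(rows))


def backtranslate(pa: ProteinAlignment, cds_map: Mapping[str, str]) -> CodonAlignment:
    """Replace each aligned residue by its source codon; '-' becomes '---'."""
    rows = []
    for name, row in zip(pa.ids, pa.rows):
        cds = cds_map[name]
        if len(cds) != 3 * len(row.replace("-", "")):
            raise ValueError(f"{name}: CDS length inconsistent with protein row")
        out = []
        k = 0
        for aa in row:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(out))
    return CodonAlignment(pa.ids, tuple(rows))


def extract_pairs(ca: CodonAlignment, min_bp: int = 90) -> list[StrippedPair]:
    """All member pairs with per-pair gap/N/stop codon columns removed.

    A pair is kept only if its stripped length is strictly greater than
    ``min_bp`` nucleotides. Stripping is pairwise: a column is removed for
    a pair when either of the two rows has a gap, an ambiguous base, or a
    stop codon in that column.
    """
    from .seqio import STOP_CODONS

    n = len(ca.ids)
    codon_rows = [
        [row[3 * k : 3 * k + 3] for k in range(len(row) // 3)] for row in ca.rows
    ]
    pairs: list[StrippedPair] = []
    for i in range(n):
        for j in range(i + 1, n):
            ca_i: list[str] = []
            ca_j: list[str] = []
            for x, y in zip(codon_rows[i], codon_rows[j]):
                if "-" in x or "-" in y or "N" in x or "N" in y:
                    continue
                if x in STOP_CODONS or y in STOP_CODONS:
                    continue
                ca_i.append(x)
                ca_j.append(y)
            if 3 * len(ca_i) > min_bp:
                pairs.append(
                    StrippedPair(ca.ids[i], ca.ids[j], tuple(ca_i), tuple(ca_j))
                )
    return pairs


def family_codon_alignment(
    members: Sequence[str],
    records: Mapping[str, object],
    aligner: Callable[[Sequence[tuple[str, str]]], ProteinAlignment] | None = None,
) -> CodonAlignment:
    """Convenience: protein-align a family and back-translate it."""
    proteins = [(m, records[m].protein) for m in members]
    pa = (aligner or align_family)(proteins)
    cds_map = {m: records[m].cds for m in members}
    ca = backtranslate(pa, cds_map)
    for name, row in zip(ca.ids, ca.rows):
        degapped = row.replace("-", "")
        if translate_cds(degapped) != records[name].protein:
            raise AlignmentValidationError(f"round-trip failure for {name}")
    return ca
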