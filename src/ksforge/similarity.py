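"""All-vs-all protein similarity: built-in search, tabular parsing, graph building.

Two routes produce the same downstream object, a symmetric weighted
similarity graph over gene identifiers:

* ``builtin_all_vs_all`` — a self-contained Smith–Waterman search with
  BLOSUM62 and Karlin–Altschul E-values, seeded by shared 4-mers so that
  only plausibly related pairs are aligned. Suited to desk-scale inputs
  and testing.
* ``parse_tabular_hits`` — reads an externally produced all-vs-all table
  in the standard 12-column tabular dialect (BLAST ``-outfmt 6`` /
  MMseqs2 ``m8``), which is the recommended route at genome scale.

``build_graph`` then keeps hits with E-value <= cutoff (default 1e-10),
drops self-hits, converts E-values to edge weights ``-log10(E)`` capped
at ``weight_cap`` (E = 0 maps to the cap), and averages the weights of
reciprocal hits.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import GeneRecord, open_text

# Fixed ungapped BLOSUM62 Karlin-Altschul parameters; a documented
# approximation (no lookup by gap penalties).
KA_LAMBDA = 0.267
KA_K = 0.041


class ConfigError(ValueError):
    pass


class HitsParseError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    pct_identity: float
    aln_len: int
    evalue: float
    bitscore: float


class SimilarityGraph:
    """Undirected weighted graph over gene ids (no self-loops)."""

    def __init__(self) -> None:
        self.nodes: set[str] = set()
        self.edges: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_node(self, node: str) -> None:
        self.nodes.add(node)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise ValueError("self-loops not allowed")
        if weight <= 0:
            raise ValueError("weights must be strictly positive")
        self.nodes.update((a, b))
        self.edges[self._key(a, b)] = weight

    def weight(self, a: str, b: str) -> float | None:
        return self.edges.get(self._key(a, b))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def connected_components(self) -> list[list[str]]:
        """Components, each sorted by id, ordered by smallest member id."""
        comps = [sorted(c) for c in nx.connected_components(self.to_networkx())]
        return sorted(comps, key=lambda c: c[0])


def builtin_all_vs_all(
    records: Sequence[GeneRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    evalue_max: float = 1e-3,
    seed_k: int = 4,
    min_shared_kmers: int = 5,
    max_kmer_occupancy: int = 200,
) -> list[SimilarityHit]:
    """Smith–Waterman all-vs-all with Karlin–Altschul E-values.

    Candidate pairs are seeded by shared ``seed_k``-mers (at least
    ``min_shared_kmers`` distinct shared words); unrelated random
    sequences essentially never share that many words, and any pair that
    could reach the downstream 1e-10 E-value cutoff vastly exceeds it.
    K-mers occurring in more than ``max_kmer_occupancy`` sequences are
    treated as low-complexity and ignored for seeding. For every
    surviving ordered pair, E = K * m * n * exp(-lambda * S) with S the
    raw local alignment score; hits with E > ``evalue_max`` are omitted,
    as are self-hits.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    try:
        submat = substitution_matrices.load(matrix)
    except Exception as exc:
        raise ConfigError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=submat,
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )

    kmer_index: dict[str, list[int]] = defaultdict(list)
    for idx, rec in enumerate(records):
        seq = rec.protein
        for w in {seq[i : i + seed_k] for i in range(max(len(seq) - seed_k + 1, 1))}:
            kmer_index[w].append(idx)
    shared: Counter[tuple[int, int]] = Counter()
    for members in kmer_index.values():
        if len(members) < 2 or len(members) > max_kmer_occupancy:
            continue
        for a, b in itertools.combinations(members, 2):
            shared[(a, b)] += 1
    candidates = [pair for pair, c in shared.items() if c >= min_shared_kmers]

    hits: list[SimilarityHit] = []
    for a, b in sorted(candidates):
        ra, rb = records[a], records[b]
        score = aligner.score(ra.protein, rb.protein)
        m, n = len(ra.protein), len(rb.protein)
        evalue = KA_K * m * n * math.exp(-KA_LAMBDA * score)
        if evalue > evalue_max:
            continue
        aln = aligner.align(ra.protein, rb.protein)[0]
        counts = aln.counts()
        aligned_cols = counts.identities + counts.mismatches
        pct = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
        bitscore = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)
        hits.append(SimilarityHit(ra.gene_id, rb.gene_id, pct, aln.length, evalue, bitscore))
        hits.append(SimilarityHit(rb.gene_id, ra.gene_id, pct, aln.length, evalue, bitscore))
    return hits


def parse_tabular_hits(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column BLAST outfmt-6 / MMseqs2 m8 hits file.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Columns beyond the twelfth are ignored;
    fewer than twelve is a parse error naming the line.
    """
    hits: list[SimilarityHit] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise HitsParseError(
                    f"{path}: expected 12 tab-separated columns, got {len(cols)} "
                    f"at line {lineno}"
                )
            try:
                hits.append(
                    SimilarityHit(
                        query=cols[0],
                        subject=cols[1],
                        pct_identity=float(cols[2]),
                        aln_len=int(cols[3]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise HitsParseError(f"{path}: bad field at line {lineno}: {exc}") from exc
    return hits


def build_graph(
    hits: Iterable[SimilarityHit],
    evalue_cutoff: float = 1e-10,
    weight_cap: float = 200.0,
    nodes: Iterable[str] | None = None,
) -> SimilarityGraph:
    """Filter hits and build the symmetric weighted similarity graph.

    Hits with ``evalue > evalue_cutoff`` (strictly above; the boundary is
    kept) and self-hits are discarded. Edge weight is ``-log10(evalue)``
    with E = 0 mapped to ``weight_cap``; all weights are capped there.
    Multiple hits for the same ordered pair keep the best (largest)
    weight; reciprocal hits are merged by the arithmetic mean of the two
    directional weights. ``nodes`` optionally supplies the full gene set
    so genes without retained hits appear as isolated nodes.
    """
    directional: dict[tuple[str, str], float] = {}
    graph = SimilarityGraph()
    if nodes is not None:
        for nid in nodes:
            graph.add_node(nid)
    for hit in hits:
        graph.nodes.update((hit.query, hit.subject))
        if hit.query == hit.subject:
            continue
        if hit.evalue > evalue_cutoff:
            continue
        if hit.evalue <= 0.0:
            w = weight_cap
        else:
            w = min(-math.log10(hit.evalue), weight_cap)
        key = (hit.query, hit.subject)
        if w > directional.get(key, 0.0):
            directional[key] = w
    done = set()
    for (q, s), w in directional.items():
        key = SimilarityGraph._key(q, s)
        if key in done:
            continue
        done.add(key)
        back = directional.get((s, q))
        weight = (w + back) / 2.0 if back is not None else w
        graph.add_edge(q, s, weight)
    return graph
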