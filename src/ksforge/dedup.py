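"""Redundancy correction: from n(n-1)/2 pairwise dS values to duplication events.

A family of n genes that arose through n-1 retained duplications yields
n(n-1)/2 pairwise dS values, so old duplications are massively
over-counted in the raw pair distribution. The correction implemented
here collapses that redundancy:

1. The pairwise dS values are used as a dissimilarity matrix
   (unmeasurable pairs — saturated, filtered, or absent — are filled
   with a value above the subfamily threshold so they can never be
   forced into one subfamily).
2. An average-linkage (UPGMA-style) tentative tree is built and cut into
   k = 1..n clusters; the smallest k whose clusters each contain only
   measured within-cluster dS values below ``ds_max`` (default 5)
   defines the subfamilies — each subfamily keeps as many genes as
   possible.
3. Each subfamily of m >= 3 genes is re-clustered and cut into exactly
   two child clades; the mean of the measured between-clade dS values,
   weighted by the number of such combinations, represents the
   subfamily's deepest duplication event. Two-gene subfamilies
   contribute their single pairwise dS directly.

``mode="deepest_split"`` (default) emits one event per subfamily;
``mode="recursive"`` additionally descends into each child clade,
emitting one event per internal split (at most m-1 events), which
preserves shallow duplications nested inside old subfamilies.

Tie-breaking in agglomeration and cutting is lexicographic on member
ids, so the whole stage is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .mcl import GeneFamily
from .ng86 import PairwiseDs

logger = logging.getLogger(__name__)

DEFAULT_FILL = 10.0
DEFAULT_DS_MAX = 5.0

Mode = Literal["deepest_split", "recursive"]


@dataclass
class DsMatrix:
    family_id: str
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal; fill value where undefined
    defined: np.ndarray  # bool mask; True where a usable dS was measured
    fill_value: float = DEFAULT_FILL

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, members: Sequence[str]) -> "DsMatrix":
        idx = [self.ids.index(m) for m in members]
        return DsMatrix(
            self.family_id,
            tuple(members),
            self.d[np.ix_(idx, idx)],
            self.defined[np.ix_(idx, idx)],
            self.fill_value,
        )


@dataclass(frozen=True)
class Merge:
    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass(frozen=True)
class Dendrogram:
    ids: tuple[str, ...]
    merges: tuple[Merge, ...]


@dataclass(frozen=True)
class Subfamily:
    family_id: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class DuplicationEvent:
    family_id: str
    subfamily: int
    ds: float
    weight: int
    n_members: int


def build_ds_matrix(
    family: GeneFamily,
    pairs: Iterable[PairwiseDs],
    fill_value: float = DEFAULT_FILL,
) -> DsMatrix:
    """Assemble the family's dS dissimilarity matrix.

    Saturated pairs, pairs lost to the alignment-length filter, and
    member pairs with no measurement at all take ``fill_value`` and are
    flagged undefined.
    """
    ids = tuple(family.members)
    index = {m: i for i, m in enumerate(ids)}
    n = len(ids)
    d = np.full((n, n), fill_value, dtype=float)
    defined = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(defined, True)
    for p in pairs:
        if p.gene_a not in index or p.gene_b not in index:
            raise ValueError(f"pair {p.gene_a}/{p.gene_b} not in family {family.family_id}")
        i, j = index[p.gene_a], index[p.gene_b]
        if p.saturated or not np.isfinite(p.dS):
            continue
        d[i, j] = d[j, i] = p.dS
        defined[i, j] = defined[j, i] = True
    return DsMatrix(family.family_id, ids, d, defined, fill_value)


def average_linkage(m: DsMatrix) -> Dendrogram:
    """UPGMA-style agglomeration on the (filled) dS matrix.

    At each step the two clusters with the smallest mean inter-cluster
    dissimilarity merge at that mean; ties are broken by the smallest
    lexicographic pair of cluster representatives (each cluster
    represented by its smallest member id).
    """
    if m.n < 2:
        raise ValueError("average_linkage needs n >= 2")
    clusters: list[tuple[str, ...]] = [(i,) for i in m.ids]
    index = {gid: k for k, gid in enumerate(m.ids)}
    merges: list[Merge] = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ia = [index[g] for g in clusters[a]]
                ib = [index[g] for g in clusters[b]]
                mean = float(m.d[np.ix_(ia, ib)].mean())
                rep = tuple(sorted((min(clusters[a]), min(clusters[b]))))
                key = (mean, rep)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (height, _), a, b = best
        left, right = clusters[a], clusters[b]
        if min(right) < min(left):
            left, right = right, left
        merges.append(Merge(left, right, height))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(tuple(sorted(left + right)))
    return Dendrogram(m.ids, tuple(merges))


def cut_k(dg: Dendrogram, k: int) -> list[tuple[str, ...]]:
    """Partition into k clusters by undoing the k-1 highest merges.

    Average linkage is monotone (heights are non-decreasing in merge
    order), and height ties are resolved toward undoing later merges
    first, so cutting is equivalent to replaying only the first n-k
    merges. Clusters are returned sorted by smallest member id.
    """
    n = len(dg.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent: dict[str, str] = {g: g for g in dg.ids}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for merge in dg.merges[: n - k]:
        ra, rb = find(merge.left[0]), find(merge.right[0])
        parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for g in dg.ids:
        groups.setdefault(find(g), []).append(g)
    return sorted((tuple(sorted(v)) for v in groups.values()), key=lambda c: c[0])


def find_subfamilies(
    m: DsMatrix,
    dg: Dendrogram | None = None,
    ds_max: float = DEFAULT_DS_MAX,
) -> list[Subfamily]:
    """Split a family into subfamilies with all within dS below ``ds_max``.

    Scans the k = 1..n cluster series and returns the partition at the
    smallest k for which every cluster contains only defined
    within-cluster dS values strictly below ``ds_max`` (so each
    subfamily keeps as many genes as possible). k = n always satisfies
    the condition vacuously.
    """
    if m.n == 1:
        return [Subfamily(m.family_id, m.ids)]
    if dg is None:
        dg = average_linkage(m)
    index = {g: i for i, g in enumerate(m.ids)}
    for k in range(1, m.n + 1):
        parts = cut_k(dg, k)
        ok = True
        for part in parts:
            idx = [index[g] for g in part]
            sub_d = m.d[np.ix_(idx, idx)]
            sub_def = m.defined[np.ix_(idx, idx)]
            off = ~np.eye(len(idx), dtype=bool)
            if (~sub_def[off]).any() or (sub_d[off] >= ds_max).any():
                ok = False
                break
        if ok:
            return [Subfamily(m.family_id, p) for p in parts]
    raise AssertionError("unreachable: k = n is always valid")


def _split_events(
    members: tuple[str, ...],
    m: DsMatrix,
    recursive: bool,
) -> list[tuple[float, int, int]]:
    """Events (ds, weight, clade size) from the two-clade split of ``members``."""
    if len(members) < 2:
        return []
    if len(members) == 2:
        i, j = m.ids.index(members[0]), m.ids.index(members[1])
        if not m.defined[i, j]:
            logger.warning(
                "family %s: pair %s/%s has no measurable dS; event skipped",
                m.family_id,
                members[0],
                members[1],
            )
            return []
        return [(float(m.d[i, j]), 1, 2)]
    sub = m.submatrix(members)
    dg = average_linkage(sub)
    clade_a, clade_b = cut_k(dg, 2)
    ia = [m.ids.index(g) for g in clade_a]
    ib = [m.ids.index(g) for g in clade_b]
    cross_d = m.d[np.ix_(ia, ib)]
    cross_def = m.defined[np.ix_(ia, ib)]
    events: list[tuple[float, int, int]] = []
    n_def = int(cross_def.sum())
    if n_def == 0:
        logger.warning(
            "family %s: all between-clade dS undefined for a %d-gene subfamily; "
            "event skipped",
            m.family_id,
            len(members),
        )
    else:
        events.append((float(cross_d[cross_def].mean()), n_def, len(members)))
    if recursive:
        events.extend(_split_events(clade_a, m, True))
        events.extend(_split_events(clade_b, m, True))
    return events


def correct_subfamily(
    sf: Subfamily,
    m: DsMatrix,
    mode: Mode = "deepest_split",
    subfamily_index: int = 0,
) -> list[DuplicationEvent]:
    """Collapse one subfamily into duplication-event dS values.

    Singletons yield nothing; a two-gene subfamily yields its single
    pairwise dS with weight 1; larger subfamilies are re-clustered, cut
    into two child clades, and represented by the combination-weighted
    mean of the between-clade dS values. ``recursive`` mode also
    descends into each clade.
    """
    events = _split_events(tuple(sf.members), m, recursive=(mode == "recursive"))
    return [
        DuplicationEvent(sf.family_id, subfamily_index, ds, weight, size)
        for ds, weight, size in events
    ]


def correct_family(
    family: GeneFamily,
    pairs: Iterable[PairwiseDs],
    mode: Mode = "deepest_split",
    ds_max: float = DEFAULT_DS_MAX,
    fill_value: float = DEFAULT_FILL,
) -> list[DuplicationEvent]:
    """Full correction for one family: matrix, subfamilies, events."""
    if family.size == 1:
        return []
    m = build_ds_matrix(family, pairs, fill_value=fill_value)
    subfamilies = find_subfamilies(m, ds_max=ds_max)
    events: list[DuplicationEvent] = []
    for k, sf in enumerate(subfamilies):
        events.extend(correct_subfamily(sf, m, mode=mode, subfamily_index=k))
    return events


def correct_all(
    families: Sequence[GeneFamily],
    pairs_by_family: Mapping[str, Sequence[PairwiseDs]],
    mode: Mode = "deepest_split",
    ds_max: float = DEFAULT_DS_MAX,
    fill_value: float = DEFAULT_FILL,
) -> list[DuplicationEvent]:
    """Concatenate corrected events over all families, in deterministic order."""
    events: list[DuplicationEvent] = []
    for family in sorted(families, key=lambda f: f.family_id):
        events.extend(
            correct_family(
                family,
                pairs_by_family.get(family.family_id, ()),
                mode=mode,
                ds_max=ds_max,
                fill_value=fill_value,
            )
        )
    return events


def write_events(events: Sequence[DuplicationEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tsubfamily\tds\tweight\tmember_count\n")
        for e in events:
            fh.write(f"{e.family_id}\t{e.subfamily}\t{e.ds:.6f}\t{e.weight}\t{e.n_members}\n")


def write_ds_values(events: Sequence[DuplicationEvent], path) -> None:
    """Flat one-column list of corrected dS values (the primary output)."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(f"{e.ds:.6f}\n")
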