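"""Markov clustering of the similarity graph into gene families.

MCL alternates expansion (matrix power) and inflation (entrywise power
followed by column renormalization) of a column-stochastic matrix until
the flow stabilizes; clusters are read off from the attractor rows. The
matrix is processed densely but one connected component at a time, which
keeps memory bounded by the largest component rather than the whole
graph. Self-loops are added with weight equal to the node's maximum
incident edge weight (standard practice to damp oscillation).

Determinism: identical graph + parameters yield identical families.
Family ids are assigned in decreasing size order, ties broken by the
smallest member id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .similarity import ConfigError, SimilarityGraph


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def _cluster_component(
    nodes: list[str],
    graph: SimilarityGraph,
    inflation: float,
    expansion: int,
    prune_threshold: float,
    max_iter: int,
    convergence_tol: float,
) -> list[list[str]]:
    n = len(nodes)
    if n == 1:
        return [nodes]
    index = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for i, a in enumerate(nodes):
        for j in range(i + 1, n):
            w = graph.weight(a, nodes[j])
            if w is not None:
                W[i, j] = W[j, i] = w
    loop = W.max(axis=0)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(W, loop)
    M = W / W.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        dead = colsum[0] <= 0.0
        if dead.any():
            # a fully pruned column restarts as a self-loop
            M[:, dead] = 0.0
            M[np.flatnonzero(dead), np.flatnonzero(dead)] = 1.0
            colsum = M.sum(axis=0, keepdims=True)
        M = M / colsum
        if prev.shape == M.shape and np.max(np.abs(M - prev)) < convergence_tol:
            break
    else:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations on a component "
            f"of {n} nodes; clusters read from the current matrix",
            RuntimeWarning,
            stacklevel=3,
        )

    eps = 1e-6
    attractors = [i for i in range(n) if M[i, i] > eps]
    if not attractors:
        attractors = [int(np.argmax(np.diag(M)))]
    # merge attractors that attract one another into attractor systems
    parent = {i: i for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in attractors:
        for j in attractors:
            if i < j and (M[i, j] > eps or M[j, i] > eps):
                parent[find(i)] = find(j)
    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)
    groups = sorted(systems.values(), key=lambda g: nodes[min(g)])

    clusters: dict[int, list[str]] = {k: [] for k in range(len(groups))}
    for j in range(n):
        attraction = [sum(M[i, j] for i in g) for g in groups]
        best = max(attraction)
        # ties resolved toward the group with the smallest member id
        k = min(
            (ki for ki, a in enumerate(attraction) if a >= best - 1e-15),
            key=lambda ki: nodes[min(groups[ki])],
        )
        clusters[k].append(nodes[j])
    return [sorted(c) for c in clusters.values() if c]


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    convergence_tol: float = 1e-8,
) -> list[GeneFamily]:
    """Cluster a similarity graph into gene families.

    Raises :class:`ConfigError` for inflation <= 1. Isolated nodes become
    singleton families.
    """
    if inflation <= 1.0:
        raise ConfigError("MCL inflation must be > 1")
    if not graph.nodes:
        raise ValueError("empty graph")
    all_clusters: list[list[str]] = []
    for comp in graph.connected_components():
        all_clusters.extend(
            _cluster_component(
                comp, graph, inflation, expansion, prune_threshold, max_iter, convergence_tol
            )
        )
    all_clusters.sort(key=lambda c: (-len(c), c[0]))
    width = max(6, len(str(len(all_clusters))))
    return [
        GeneFamily(f"F{i:0{width}d}", tuple(c)) for i, c in enumerate(all_clusters, start=1)
    ]


def write_families(families, path) -> None:
    """One line per family: family_id TAB tab-separated member ids."""
    with open(path, "w") as fh:
        for fam in families:
            fh.write(fam.family_id + "\t" + "\t".join(fam.members) + "\n")


def read_families(path) -> list[GeneFamily]:
    families = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                families.append(GeneFamily(parts[0], tuple(parts[1:])))
    return families
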