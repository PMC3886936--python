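"""Markov clustering of the homology graph into homologous groups.

Edges are weighted by -log10 of the similarity e-value (averaged over the
two search directions, capped), the classic input weighting for
OrthoMCL-style group construction. The MCL iteration itself is the standard
expansion/inflation alternation with an inflation index of 1.5 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .homology import SimilarityHit

WEIGHT_CAP = 200.0


def build_graph(
    hits: Iterable[SimilarityHit],
    e_cutoff: float = 1e-5,
    strain_of_gene: dict[str, str] | None = None,
    nodes: Iterable[str] | None = None,
) -> nx.Graph:
    """Undirected homology graph from directed similarity hits.

    An edge exists iff at least one direction passes the e-value cutoff; its
    weight is the mean -log10(E) over the available directions, with each
    direction capped at 200 (E = 0 maps to the cap).
    """
    evals: dict[tuple[str, str], float] = {}  # best (smallest) E per direction
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        if key not in evals or h.e_value < evals[key]:
            evals[key] = h.e_value

    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)  # isolated genes become singleton clusters
    pairs = {frozenset(k) for k in evals}
    for pair in pairs:
        q, s = sorted(pair)
        e_fwd = evals.get((q, s))
        e_rev = evals.get((s, q))
        if not any(e is not None and e <= e_cutoff for e in (e_fwd, e_rev)):
            continue
        ws = [
            WEIGHT_CAP if e == 0 else min(-math.log10(e), WEIGHT_CAP)
            for e in (e_fwd, e_rev)
            if e is not None
        ]
        graph.add_edge(q, s, weight=sum(ws) / len(ws))
    if strain_of_gene:
        for node in graph.nodes:
            graph.nodes[node]["strain"] = strain_of_gene.get(node)
    return graph


@dataclass(frozen=True)
class MclParams:
    inflation: float = 1.5
    expansion_power: int = 2
    prune_threshold: float = 1e-8
    max_iterations: int = 200
    convergence_tol: float = 1e-10

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence tolerance must be positive")


class MclConvergenceError(RuntimeError):
    def __init__(self, message: str, partial: "ClusterSet"):
        super().__init__(message)
        self.partial = partial


@dataclass
class ClusterSet:
    """A partition of gene ids into homologous groups (singletons included)."""

    clusters: list[frozenset[str]]
    include_singletons: bool = True

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def cluster_of(self) -> dict[str, int]:
        return {g: i for i, c in enumerate(self.clusters) for g in c}

    def single_copy(self, strain_of_gene: dict[str, str], n_strains: int) -> list[frozenset[str]]:
        """Clusters with exactly one gene in each of the n strains."""
        out = []
        for c in self.clusters:
            strains = [strain_of_gene[g] for g in c]
            if len(c) == n_strains and len(set(strains)) == n_strains:
                out.append(c)
        return out

    def write_tsv(self, path: str | Path, strain_of_gene: dict[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_id\tgene_id\tstrain\n")
            for i, c in enumerate(self.clusters):
                for g in sorted(c):
                    strain = (strain_of_gene or {}).get(g, "")
                    fh.write(f"cluster{i:05d}\t{g}\t{strain}\n")


def _read_clusters(matrix: np.ndarray, nodes: Sequence[str], thresh: float) -> list[frozenset[str]]:
    """Interpret a (near-)idempotent MCL matrix as attractor basins.

    A node attracted to multiple attractor systems joins the cluster of the
    lexicographically smallest attractor id.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if matrix[i, i] > thresh]
    # attractor systems: attractors connected through mutual mass
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    att_set = set(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (matrix[i, j] > thresh or matrix[j, i] > thresh):
                union(i, j)

    cluster_key: dict[int, str] = {}  # attractor root -> smallest attractor node name
    members: dict[int, set[int]] = {}
    for i in attractors:
        members.setdefault(find(i), set()).add(i)
    for root, atts in members.items():
        cluster_key[root] = min(nodes[i] for i in atts)

    assignment: dict[int, int] = {}
    for j in range(n):
        pulls = [i for i in attractors if matrix[i, j] > thresh]
        if not pulls:
            assignment[j] = -1 - j  # numerically orphaned: own singleton
        else:
            best = min(pulls, key=lambda i: nodes[min(members[find(i)], key=lambda k: nodes[k])])
            assignment[j] = find(best)

    grouped: dict[int, set[str]] = {}
    for j, key in assignment.items():
        grouped.setdefault(key, set()).add(nodes[j])
    return [frozenset(s) for s in grouped.values()]


def mcl(graph: nx.Graph, params: MclParams | None = None) -> ClusterSet:
    """Markov clustering of a weighted undirected graph.

    Self-loops are set to each node's maximum incident edge weight (1 for
    isolated nodes), columns are normalized to stochastic, and expansion
    (matrix power) alternates with inflation (element-wise power plus
    renormalization) with pruning until the matrix stops changing.
    """
    params = params or MclParams()
    nodes = sorted(graph.nodes)
    if not nodes:
        return ClusterSet([])
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError("edge weights must be positive")
        M[idx[u], idx[v]] = w
        M[idx[v], idx[u]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M /= M.sum(axis=0, keepdims=True)

    for _ in range(params.max_iterations):
        expanded = np.linalg.matrix_power(M, params.expansion_power)
        inflated = expanded**params.inflation
        inflated[inflated < params.prune_threshold] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.max(np.abs(inflated - M)) < params.convergence_tol:
            M = inflated
            break
        M = inflated
    else:
        raise MclConvergenceError(
            f"MCL did not converge in {params.max_iterations} iterations",
            ClusterSet(_read_clusters(M, nodes, params.prune_threshold)),
        )
    return ClusterSet(_read_clusters(M, nodes, params.prune_threshold))


@dataclass
class PresencePartition:
    """Strain-presence categories of homologous groups."""

    n_strains: int
    counts_per_cluster: list[int]
    histogram: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.histogram.values())

    @property
    def mosaic_count(self) -> int:
        """Groups present in >=2 but not all strains."""
        return sum(v for k, v in self.histogram.items() if 2 <= k <= self.n_strains - 1)

    @property
    def mosaic_pct(self) -> float:
        return 0.0 if self.total == 0 else 100.0 * self.mosaic_count / self.total


def presence_partition(
    clusters: ClusterSet, strain_of_gene: dict[str, str], n_strains: int | None = None
) -> PresencePartition:
    counts = []
    for c in clusters:
        strains = set()
        for g in c:
            if g not in strain_of_gene:
                raise ValueError(f"gene {g} has no strain label")
            strains.add(strain_of_gene[g])
        counts.append(len(strains))
    n = n_strains or (max(len(set(strain_of_gene.values())), 1))
    hist = {k: 0 for k in range(1, n + 1)}
    for c in counts:
        hist[c] += 1
    return PresencePartition(n, counts, hist)


def paralog_size_profile(
    clusters: ClusterSet, strain_of_gene: dict[str, str], strain: str, top_k: int = 15
) -> dict:
    """Within-cluster gene counts of one strain: the paralog-size profile."""
    sizes = []
    for c in clusters:
        k = sum(1 for g in c if strain_of_gene.get(g) == strain)
        if k:
            sizes.append(k)
    sizes.sort(reverse=True)
    return {
        "strain": strain,
        "sizes": sizes,
        "top": sizes[:top_k],
        "max": sizes[0] if sizes else 0,
        "median": float(np.median(sizes)) if sizes else 0.0,
    }


def write_abc(graph: nx.Graph, path: str | Path) -> None:
    """Edge list in the `.abc` (node node weight) convention."""
    with open(path, "w") as fh:
        for u, v, data in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.4f}\n")
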