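"""Pairwise distance matrices and minimum spanning haplotype networks.

Haplotypes within a haplogroup are related by few mutational steps, so a
minimum spanning tree over the distinct haplotypes — with all
equally-short alternative edges retained, giving a *network* rather than
a strict tree — summarises their genealogical structure.  Node size
records how many individuals carry each haplotype and nodes carry a
per-population composition, so founder clusters (large central nodes with
one-step satellites) are visible directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import HaplotypeDataset

__all__ = [
    "DistanceMatrix",
    "HaplotypeNode",
    "MSNGraph",
    "pairwise_distances",
    "collapse_haplotypes",
    "minimum_spanning_network",
    "build_msn",
    "mean_within_distance",
    "write_graphml",
]

_METRICS = ("hamming", "stepwise")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric integer distance matrix over samples or haplotype nodes."""

    ids: tuple[str, ...]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.array_equal(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)


def _distances(x: np.ndarray, metric: str) -> np.ndarray:
    """Condensed integer distances between rows of a repeat matrix."""
    if metric == "hamming":
        return np.rint(pdist(x, "hamming") * x.shape[1]).astype(np.int64)
    if metric == "stepwise":
        return np.rint(pdist(x, "cityblock")).astype(np.int64)
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")


def pairwise_distances(
    stratum: HaplotypeDataset, metric: str = "hamming"
) -> DistanceMatrix:
    """All-vs-all distances between individuals.

    ``hamming`` counts loci with differing repeat counts; ``stepwise``
    sums absolute repeat differences (mutational steps under the SMM).
    """
    if stratum.n < 2:
        raise ValueError("pairwise distances require at least 2 individuals")
    x = stratum.repeat_matrix()
    d = squareform(_distances(x, metric))
    return DistanceMatrix(tuple(stratum.df["sample_id"]), d, metric)


@dataclass(frozen=True)
class HaplotypeNode:
    """One distinct haplotype with its carrier counts."""

    haplotype: tuple[int, ...]
    size: int
    population_counts: tuple[tuple[str, int], ...]

    @property
    def populations(self) -> dict[str, int]:
        return dict(self.population_counts)


def collapse_haplotypes(stratum: HaplotypeDataset) -> list[HaplotypeNode]:
    """Collapse individuals onto distinct haplotypes (network nodes).

    Nodes are ordered by decreasing size, then lexicographically by
    haplotype, so output is deterministic.
    """
    if stratum.n == 0:
        raise ValueError("empty stratum")
    pops = stratum.df["population"].tolist()
    comp: dict[tuple[int, ...], Counter] = {}
    for hap, pop in zip(stratum.haplotypes(), pops):
        comp.setdefault(hap, Counter())[pop] += 1
    nodes = [
        HaplotypeNode(
            haplotype=hap,
            size=sum(cnt.values()),
            population_counts=tuple(sorted(cnt.items())),
        )
        for hap, cnt in comp.items()
    ]
    nodes.sort(key=lambda nd: (-nd.size, nd.haplotype))
    return nodes


@dataclass
class MSNGraph:
    """Minimum spanning network over collapsed haplotypes.

    ``edges`` holds (i, j, distance, in_mst) with i < j; the in_mst=True
    subset is one minimum spanning tree, the remaining edges are
    equal-length alternatives retained at the acceptance step.
    ``graph`` mirrors the same structure as a networkx Graph for export
    and layout.
    """

    nodes: list[HaplotypeNode]
    edges: list[tuple[int, int, int, bool]]
    metric: str
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)

    @property
    def mst_weight(self) -> int:
        return sum(w for _, _, w, flag in self.edges if flag)

    @property
    def n_individuals(self) -> int:
        return sum(nd.size for nd in self.nodes)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def minimum_spanning_network(
    nodes: Sequence[HaplotypeNode],
    d: DistanceMatrix,
    *,
    retain_ties: bool = True,
    metric: str | None = None,
) -> MSNGraph:
    """Kruskal MST over haplotype nodes, optionally keeping tied edges.

    Edges are processed in weight classes.  Within a class, any edge that
    joins two components *as they stood when the class opened* is
    retained; of those, the ones that still join distinct components when
    reached are flagged as MST edges.  With ``retain_ties=False`` only
    the MST edges are kept (a strict tree).
    """
    nodes = list(nodes)
    k = len(nodes)
    if k != d.n:
        raise ValueError("node list and distance matrix disagree")
    metric = metric or d.metric
    g = nx.Graph()
    for i, nd in enumerate(nodes):
        g.add_node(i, size=nd.size, haplotype="-".join(map(str, nd.haplotype)),
                   **{f"n_{pop}": cnt for pop, cnt in nd.population_counts})
    edges_out: list[tuple[int, int, int, bool]] = []
    if k >= 2:
        all_edges = sorted(
            ((int(d.d[i, j]), i, j) for i in range(k) for j in range(i + 1, k)),
            key=lambda e: e[0],
        )
        uf = _UnionFind(k)
        pos = 0
        while pos < len(all_edges):
            w = all_edges[pos][0]
            group = []
            while pos < len(all_edges) and all_edges[pos][0] == w:
                group.append(all_edges[pos])
                pos += 1
            # component structure at the opening of this weight class
            snapshot = [uf.find(i) for i in range(k)]
            for _, i, j in group:
                if snapshot[i] == snapshot[j]:
                    continue  # joins nothing even at class opening
                in_mst = uf.union(i, j)
                if in_mst or retain_ties:
                    edges_out.append((i, j, w, in_mst))
    for i, j, w, in_mst in edges_out:
        g.add_edge(i, j, weight=w, mst=bool(in_mst))
    return MSNGraph(nodes=nodes, edges=edges_out, metric=metric, graph=g)


def build_msn(
    stratum: HaplotypeDataset,
    *,
    metric: str = "hamming",
    retain_ties: bool = True,
) -> MSNGraph:
    """Collapse a stratum and build its minimum spanning network."""
    nodes = collapse_haplotypes(stratum)
    x = np.asarray([nd.haplotype for nd in nodes], dtype=np.int64)
    if len(nodes) == 1:
        d = DistanceMatrix(("h0",), np.zeros((1, 1), dtype=np.int64), metric)
    else:
        d = DistanceMatrix(
            tuple(f"h{i}" for i in range(len(nodes))),
            squareform(_distances(x, metric)),
            metric,
        )
    return minimum_spanning_network(nodes, d, retain_ties=retain_ties)


def mean_within_distance(
    stratum: HaplotypeDataset, metric: str = "hamming"
) -> tuple[float, float]:
    """Mean and SD of distances over all unordered individual pairs.

    Computed over individuals (not collapsed nodes), so shared haplotypes
    contribute zero-distance pairs.  SD uses denominator (#pairs − 1);
    zero when only one pair exists.
    """
    if stratum.n < 2:
        raise ValueError("mean_within_distance requires at least 2 individuals")
    dvec = _distances(stratum.repeat_matrix(), metric).astype(float)
    sd = float(np.std(dvec, ddof=1)) if dvec.size > 1 else 0.0
    return float(np.mean(dvec)), sd


def write_graphml(msn: MSNGraph, path: str | Path) -> None:
    """Export a minimum spanning network to GraphML."""
    nx.write_graphml(msn.graph, str(path))
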