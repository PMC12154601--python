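"""Nested protein "neighborhoods" via walktrap community detection.

Short random walks on the weighted interaction network tend to stay inside
densely connected regions; walktrap merges nodes bottom-up by walk-distance
into a dendrogram whose cuts, from fine to coarse, expose nested levels of
complex organization.  Walks cannot cross connected components, so the
merge tree never joins components and attainable cluster counts run from
the number of components up to the number of nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedResultError
from .pairs import all_pairs
from .scoring import ScoredNetwork

__all__ = [
    "ComplexHierarchy",
    "walktrap_cluster",
    "cut_hierarchy",
    "ClusterPR",
    "cluster_pr",
    "max_f1_over_cuts",
]


@dataclass
class ComplexHierarchy:
    """Walktrap merge dendrogram over the network's nodes."""

    graph: "igraph.Graph"  # noqa: F821
    dendrogram: "igraph.VertexDendrogram"  # noqa: F821
    walk_length: int

    @property
    def names(self) -> list[str]:
        return self.graph.vs["name"]

    @property
    def n_nodes(self) -> int:
        return self.graph.vcount()

    @property
    def n_components(self) -> int:
        return len(self.graph.connected_components())

    def attainable_counts(self) -> range:
        return range(self.n_components, self.n_nodes + 1)

    def partition_at(self, n_clusters: int) -> dict[str, int]:
        """Node -> cluster id for the cut with exactly ``n_clusters``."""
        membership = self.dendrogram.as_clustering(n_clusters).membership
        return dict(zip(self.names, membership))

    def modularity_at(self, n_clusters: int) -> float:
        membership = self.dendrogram.as_clustering(n_clusters).membership
        return self.graph.modularity(membership, weights="weight")


def walktrap_cluster(network: ScoredNetwork,
                     walk_length: int = 4) -> ComplexHierarchy:
    """Weighted walktrap merge tree of the thresholded network."""
    if network.n_edges == 0:
        raise ParameterError("empty network")
    if (network.edges.weight <= 0).any():
        raise ParameterError("walktrap requires positive edge weights")
    g = network.to_igraph()
    dend = g.community_walktrap(weights="weight", steps=walk_length)
    return ComplexHierarchy(g, dend, walk_length)


def cut_hierarchy(h: ComplexHierarchy,
                  granularity: int | str) -> dict[str, int]:
    """Partition at a requested granularity.

    ``granularity`` is either a target cluster count (the nearest
    attainable count is used, with a warning when adjusted), or a name:
    ``"coarse"`` = the maximum-weighted-modularity cut, ``"fine"`` = the
    deepest cut in which every cluster still has >= 2 members.
    """
    counts = h.attainable_counts()
    if granularity == "coarse":
        best = max(counts, key=h.modularity_at)
        return h.partition_at(best)
    if granularity == "fine":
        for k in reversed(counts):
            part = h.partition_at(k)
            sizes = pd.Series(list(part.values())).value_counts()
            if (sizes >= 2).all():
                return part
        return h.partition_at(counts[0])
    if not isinstance(granularity, (int, np.integer)):
        raise ParameterError(f"unknown granularity {granularity!r}")
    target = int(granularity)
    nearest = min(counts, key=lambda k: abs(k - target))
    if nearest != target:
        warnings.warn(
            f"target cluster count {target} unattainable "
            f"(range {counts.start}-{counts.stop - 1}); using {nearest}"
        )
    return h.partition_at(nearest)


@dataclass(frozen=True)
class ClusterPR:
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        if self.precision + self.recall == 0:
            return 0.0
        return 2 * self.precision * self.recall / (self.precision + self.recall)


def cluster_pr(partition: dict[str, int],
               complexes: list[set[str]]) -> ClusterPR:
    """Pairwise co-membership precision/recall of a partition against known
    complexes, restricted to nodes present in the partition.

    Precision: fraction of predicted co-cluster pairs that are true
    co-complex pairs; recall: fraction of true co-complex pairs (both
    members clustered) that are co-clustered.
    """
    nodes = set(partition)
    true_pairs = set()
    for cpx in complexes:
        true_pairs |= all_pairs(set(cpx) & nodes)
    if not true_pairs and not partition:
        raise ParameterError("no overlap between partition and complexes")

    by_cluster: dict[int, list[str]] = {}
    for node, c in partition.items():
        by_cluster.setdefault(c, []).append(node)
    pred_pairs = set()
    for members in by_cluster.values():
        pred_pairs |= all_pairs(members)
    if not pred_pairs:
        raise UndefinedResultError(
            "all-singleton partition: precision undefined (0 predicted pairs)"
        )
    if not true_pairs:
        raise UndefinedResultError("no true co-complex pair among clustered nodes")
    tp = len(pred_pairs & true_pairs)
    return ClusterPR(tp / len(pred_pairs), tp / len(true_pairs))


def max_f1_over_cuts(h: ComplexHierarchy, complexes: list[set[str]],
                     max_levels: int = 200) -> tuple[float, int]:
    """Best F1 over dendrogram cuts (subsampled to <= ``max_levels`` evenly
    spaced cluster counts); returns (best F1, cluster count achieving it)."""
    counts = list(h.attainable_counts())
    if len(counts) > max_levels:
        idx = np.unique(np.linspace(0, len(counts) - 1, max_levels).astype(int))
        counts = [counts[i] for i in idx]
    best, best_k = 0.0, counts[0]
    for k in counts:
        try:
            pr = cluster_pr(h.partition_at(k), complexes)
        except UndefinedResultError:
            continue
        if pr.f1 > best:
            best, best_k = pr.f1, k
    return best, best_k


def write_partition_tsv(partition: dict[str, int], path) -> None:
    pd.DataFrame(
        sorted(partition.items()), columns=["orthogroup", "cluster_id"]
    ).to_csv(path, sep="\t", index=False)
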