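"""Boolean implication network (BIN) construction and clustering (CBIN).

Genes without a usable dynamic range (less than 5% high or 5% low codes)
are dropped, all remaining pairs are tested for Boolean implications, and
the EQUIVALENT subgraph is clustered: a minimum spanning forest is pruned
by the Jaccard similarity of the endpoints' equivalence neighborhoods
(edges below 0.5 are considered weak links and cut), and the surviving
connected components become gene clusters. Inter-cluster edges carry the
majority implication relation between sampled representative genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .implication import (DEFAULT_MIN_TOTAL, DEFAULT_PTHR, DEFAULT_STHR,
                          RelationType, pairwise_relations)
from .io import ExpressionMatrix
from .stepminer import DEFAULT_MARGIN, HIGH, LOW, discretize_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ImplicationNetwork", "GeneCluster", "ClusteredNetwork",
    "filter_genes", "build_bin", "cluster_equivalences",
    "check_scale_free", "select_representatives", "connect_clusters",
]


@dataclass
class ImplicationNetwork:
    """All pairwise Boolean implication relations among a gene panel.

    ``rel`` is the full genes x genes int8 matrix of :class:`RelationType`
    codes (entry [A, B] reads A -> B); ``edges`` lists each unordered pair
    with a non-NONE call once, in the lower-index -> higher-index
    orientation.
    """

    genes: list
    rel: pd.DataFrame

    def relation(self, a: str, b: str) -> RelationType:
        return RelationType(int(self.rel.at[a, b]))

    @property
    def edges(self) -> list:
        arr = self.rel.to_numpy()
        iu, ju = np.triu_indices(len(self.genes), k=1)
        out = []
        for i, j in zip(iu, ju):
            r = arr[i, j]
            if r == 0:
                r = RelationType(int(arr[j, i])).mirror()
            if r != 0:
                out.append((self.genes[i], self.genes[j], RelationType(int(r))))
        return out

    def equivalence_adjacency(self) -> np.ndarray:
        arr = self.rel.to_numpy()
        eq = arr == int(RelationType.EQUIVALENT)
        return eq | eq.T


@dataclass
class GeneCluster:
    """An equivalence cluster; members are ranked by within-cluster degree."""

    id: int
    members: list
    size: int = 0

    def __post_init__(self) -> None:
        self.size = len(self.members)


@dataclass
class ClusteredNetwork:
    """Clusters plus majority-relation edges between them (the CBIN)."""

    clusters: list
    edges: list = field(default_factory=list)  # (cluster_a, cluster_b, RelationType, votes)
    jaccard_min: float = 0.5

    def cluster(self, cid: int) -> GeneCluster:
        for c in self.clusters:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def sizes(self) -> dict:
        return {c.id: c.size for c in self.clusters}

    def gene_sets(self) -> dict:
        return {c.id: list(c.members) for c in self.clusters}

    def relation(self, a: int, b: int) -> RelationType:
        """Relation a -> b, mirroring stored edges as needed."""
        for ca, cb, r, _ in self.edges:
            if (ca, cb) == (a, b):
                return r
            if (ca, cb) == (b, a):
                return r.mirror()
        return RelationType.NONE

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for c in self.clusters:
            g.add_node(c.id, size=c.size, members=list(c.members))
        for a, b, r, votes in self.edges:
            g.add_edge(a, b, relation=r.name, votes=votes)
        return g


def filter_genes(matrix: ExpressionMatrix, min_frac: float = 0.05,
                 margin: float = DEFAULT_MARGIN,
                 codes: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Drop genes whose StepMiner coding is nearly one-sided.

    A gene is kept iff at least ``min_frac`` of its samples code HIGH *and*
    at least ``min_frac`` code LOW (boundary inclusive). Genes with a
    degenerate step fit always drop.
    """
    if codes is None:
        codes, _ = discretize_matrix(matrix, margin=margin)
    arr = codes.to_numpy()
    n = arr.shape[1]
    frac_hi = (arr == HIGH).sum(axis=1) / n
    frac_lo = (arr == LOW).sum(axis=1) / n
    keep = (frac_hi >= min_frac) & (frac_lo >= min_frac)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_genes: dropped %d of %d genes", dropped, arr.shape[0])
    if not keep.any():
        raise ValueError("no genes survive the dynamic-range filter")
    return matrix.subset_genes([g for g, k in zip(codes.index, keep) if k])


def build_bin(matrix: ExpressionMatrix, margin: float = DEFAULT_MARGIN,
              sthr: float = DEFAULT_STHR, pthr: float = DEFAULT_PTHR,
              min_total: int = DEFAULT_MIN_TOTAL,
              codes: pd.DataFrame | None = None) -> ImplicationNetwork:
    """Evaluate all gene pairs of a (filtered) matrix and keep non-NONE calls."""
    if codes is None:
        codes, _ = discretize_matrix(matrix, margin=margin)
    logger.info("build_bin: %d genes -> %d pairs", codes.shape[0],
                codes.shape[0] * (codes.shape[0] - 1) // 2)
    rel = pairwise_relations(codes, sthr=sthr, pthr=pthr, min_total=min_total)
    return ImplicationNetwork(genes=list(codes.index), rel=rel)


def cluster_equivalences(bin_net: ImplicationNetwork,
                         jaccard_min: float = 0.5) -> list[GeneCluster]:
    """Cluster the EQUIVALENT subgraph via a Jaccard-pruned spanning forest.

    A minimum spanning forest (edge weight 1 - Jaccard, so strong ties are
    preferred) of the equivalence graph is computed; forest edges whose
    endpoint equivalence neighborhoods share a Jaccard coefficient below
    ``jaccard_min`` are cut; the surviving components are the clusters,
    numbered from 1 in decreasing size order. Genes with no equivalences do
    not enter any cluster. Within a cluster, members are ranked by their
    number of equivalences to other members (the cluster representative is
    rank 1).
    """
    eq = bin_net.equivalence_adjacency()
    genes = bin_net.genes
    deg = eq.sum(axis=1)
    if not eq.any():
        logger.warning("cluster_equivalences: no EQUIVALENT edges")
        return []
    inter = (eq.astype(np.float64) @ eq.astype(np.float64))
    g = nx.Graph()
    iu, ju = np.nonzero(np.triu(eq, k=1))
    jac = np.empty(iu.size)
    for idx, (i, j) in enumerate(zip(iu, ju)):
        union = deg[i] + deg[j] - 2 - inter[i, j]  # endpoints excluded
        jac[idx] = 1.0 if union <= 0 else inter[i, j] / union
        g.add_edge(genes[i], genes[j], weight=1.0 - jac[idx], jaccard=jac[idx])
    forest = nx.minimum_spanning_tree(g, weight="weight")
    kept = nx.Graph()
    kept.add_nodes_from(g.nodes)
    for u, v, data in forest.edges(data=True):
        if data["jaccard"] >= jaccard_min:
            kept.add_edge(u, v)
    gene_pos = {gname: i for i, gname in enumerate(genes)}
    comps = []
    for comp in nx.connected_components(kept):
        members = sorted(comp)
        idxs = [gene_pos[m] for m in members]
        sub = eq[np.ix_(idxs, idxs)]
        within_deg = sub.sum(axis=1)
        order = sorted(range(len(members)),
                       key=lambda t: (-within_deg[t], members[t]))
        comps.append([members[t] for t in order])
    comps.sort(key=lambda ms: (-len(ms), ms[0]))
    return [GeneCluster(id=i + 1, members=ms) for i, ms in enumerate(comps)]


def check_scale_free(cluster_sizes) -> tuple[float, float]:
    """Least-squares slope and r^2 of log(size) vs log(rank).

    Diagnostic only: a roughly straight log-log line indicates a scale-free
    size distribution and guides the choice of the Jaccard cut-off.
    """
    sizes = np.sort(np.asarray(list(cluster_sizes), dtype=float))[::-1]
    if sizes.size < 3:
        logger.warning("check_scale_free: fewer than 3 clusters, fit is fragile")
    if sizes.size < 2 or np.all(sizes == sizes[0]):
        logger.warning("check_scale_free: degenerate size distribution")
        return float("nan"), float("nan")
    rank = np.arange(1, sizes.size + 1)
    res = sps.linregress(np.log(rank), np.log(sizes))
    return float(res.slope), float(res.rvalue ** 2)


def select_representatives(cluster: GeneCluster,
                           middle_small: str = "floor_half_plus_one") -> list[int]:
    """1-based member ranks used to represent a cluster in edge voting.

    Size > 10: ranks {1, 2, floor(n/2), floor(n/2)-1, floor(n/4),
    floor(n/8)} with duplicates removed, order preserved. Size 2..10: the
    top two plus the middle member (floor(n/2)+1 by default). Size 1: the
    single member.
    """
    n = cluster.size
    if n == 0:
        raise ValueError("empty cluster")
    if n == 1:
        return [1]
    if n <= 10:
        mid = n // 2 + 1 if middle_small == "floor_half_plus_one" else n // 2
        ranks = [1, 2, mid]
    else:
        ranks = [1, 2, n // 2, n // 2 - 1, n // 4, n // 8]
    seen, out = set(), []
    for r in ranks:
        r = min(max(r, 1), n)
        if r not in seen:
            seen.add(r)
            out.append(r)
    return out


def connect_clusters(clusters: list[GeneCluster], bin_net: ImplicationNetwork,
                     jaccard_min: float = 0.5) -> ClusteredNetwork:
    """Type the inter-cluster edges by majority vote of representatives.

    For each cluster pair (A, B), A's top representative is tested against
    B's sampled representatives; the strict majority among non-NONE
    relation tallies becomes the edge A -> B. Ties or all-NONE tallies
    leave the pair unconnected. Pairs are evaluated once in lower-id ->
    higher-id orientation (the reverse reads through relation mirroring).
    """
    edges = []
    rel = bin_net.rel
    for a in clusters:
        for b in clusters:
            if a.id >= b.id:
                continue
            top_a = a.members[0]
            votes: dict[RelationType, int] = {}
            for rank in select_representatives(b):
                gene_b = b.members[rank - 1]
                r = RelationType(int(rel.at[top_a, gene_b]))
                if r == RelationType.NONE:
                    # try the mirrored orientation before giving up
                    r = RelationType(int(rel.at[gene_b, top_a])).mirror()
                if r != RelationType.NONE:
                    votes[r] = votes.get(r, 0) + 1
            if not votes:
                continue
            n_votes = sum(votes.values())
            best, count = max(votes.items(), key=lambda kv: kv[1])
            if 2 * count > n_votes:
                edges.append((a.id, b.id, best, dict((k.name, v) for k, v in votes.items())))
    return ClusteredNetwork(clusters=list(clusters), edges=edges,
                            jaccard_min=jaccard_min)
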