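"""Model/Results front-end for the whole pipeline.

:class:`BooleanPathModel` is built from a labelled expression matrix;
``fit()`` runs discretization, gene filtering, Boolean implication network
construction, equivalence clustering, path discovery/enumeration and
supervised path selection, returning a :class:`BooleanPathResults` that
carries the clustered network, all candidate path scorecards, the winning
path with its per-class ROC-AUCs, and a ``summary()`` table. New cohorts
are scored through ``results.score(matrix)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import ExpressionMatrix
from .network import (ClusteredNetwork, ImplicationNetwork, build_bin,
                      cluster_equivalences, connect_clusters, filter_genes)
from .pathfinder import (BooleanPath, PathScorecard, discover_paths,
                         enumerate_3node_paths, select_best_path)
from .scoring import CompositeScore, composite_score
from .stepminer import DEFAULT_MARGIN, discretize_matrix

logger = logging.getLogger(__name__)

__all__ = ["BooleanPathModel", "BooleanPathResults"]


class BooleanPathModel:
    """Supervised Boolean-path model of labelled cell states.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log-scale expression, genes x samples.
    labels : Series
        sample -> class label; samples absent from the matrix are an
        error, samples of the matrix without a label are simply unused by
        the supervised step (the network itself is unsupervised).
    positive_labels : tuple
        Classes whose one-vs-rest AUCs multiply into the selection
        objective (default M1 x M2).
    """

    def __init__(self, matrix: ExpressionMatrix, labels: pd.Series, *,
                 margin: float = DEFAULT_MARGIN, sthr: float = 3.0,
                 pthr: float = 0.1, min_total: int = 8,
                 min_frac: float = 0.05, jaccard_min: float = 0.5,
                 n_starts: int = 5, positive_labels=("M1", "M2")):
        missing = [s for s in labels.index if s not in set(matrix.sample_ids)]
        if missing:
            raise ValueError(f"labelled samples absent from matrix: {missing[:5]}")
        self.matrix = matrix
        self.labels = labels.astype(str)
        self.margin = margin
        self.sthr = sthr
        self.pthr = pthr
        self.min_total = min_total
        self.min_frac = min_frac
        self.jaccard_min = jaccard_min
        self.n_starts = n_starts
        self.positive_labels = tuple(positive_labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels, **kwargs) -> "BooleanPathModel":
        """Build from a genes x samples DataFrame and a label mapping."""
        if not isinstance(labels, pd.Series):
            labels = pd.Series(dict(labels))
        return cls(ExpressionMatrix.from_dataframe(df), labels, **kwargs)

    def fit(self) -> "BooleanPathResults":
        codes, fits = discretize_matrix(self.matrix, margin=self.margin)
        filtered = filter_genes(self.matrix, min_frac=self.min_frac,
                                codes=codes)
        codes = codes.loc[filtered.gene_ids]
        bin_net = build_bin(filtered, margin=self.margin, sthr=self.sthr,
                            pthr=self.pthr, min_total=self.min_total,
                            codes=codes)
        clusters = cluster_equivalences(bin_net, jaccard_min=self.jaccard_min)
        if not clusters:
            raise ValueError("no equivalence clusters found; nothing to fit")
        cbin = connect_clusters(clusters, bin_net, jaccard_min=self.jaccard_min)
        candidates = discover_paths(cbin, n_starts=self.n_starts)
        for p in enumerate_3node_paths(cbin):
            if (p.cluster_ids, p.pivot_index) not in {
                    (q.cluster_ids, q.pivot_index) for q in candidates}:
                candidates.append(p)
        candidates = [p for p in candidates if p.has_pivot] or candidates
        if not candidates:
            raise ValueError("no candidate Boolean paths in the network")
        cluster_genes = cbin.gene_sets()
        cards = select_best_path(candidates, self.matrix, self.labels,
                                 cluster_genes,
                                 positive_labels=self.positive_labels)
        return BooleanPathResults(model=self, fits=fits, network=bin_net,
                                  cbin=cbin, scorecards=cards)


@dataclass
class BooleanPathResults:
    """Fitted pipeline state: network, candidate paths and the winner."""

    model: BooleanPathModel
    fits: pd.DataFrame
    network: ImplicationNetwork
    cbin: ClusteredNetwork
    scorecards: list = field(default_factory=list)

    @property
    def best(self) -> PathScorecard:
        if not self.scorecards:
            raise ValueError("no scored paths")
        return self.scorecards[0]

    @property
    def best_path(self) -> BooleanPath:
        return self.best.path

    @property
    def auc_by_label(self) -> dict:
        return dict(self.best.auc_by_label)

    @property
    def objective(self) -> float:
        return self.best.objective

    def path_signatures(self, path: BooleanPath | None = None) -> list:
        """(gene list, weight) pairs of a path (default: the winner)."""
        path = path or self.best_path
        sets = self.cbin.gene_sets()
        return [(sets[cid], w) for cid, w in path.weighted_clusters()]

    def score(self, matrix: ExpressionMatrix,
              path: BooleanPath | None = None) -> CompositeScore:
        """Composite score of any cohort along a fitted path.

        Thresholds and standard deviations are recomputed on the cohort
        itself so external datasets can be scored stand-alone.
        """
        return composite_score(matrix, self.path_signatures(path))

    def summary(self) -> str:
        lines = [
            "Boolean implication path model",
            "=" * 64,
            f"genes in network      : {len(self.network.genes)}",
            f"implication edges     : {len(self.network.edges)}",
            f"equivalence clusters  : {len(self.cbin.clusters)}",
            f"cluster edges (CBIN)  : {len(self.cbin.edges)}",
            f"candidate paths       : {len(self.scorecards)}",
            "",
            f"{'path':<30} {'objective':>9}  AUC by class",
            "-" * 64,
        ]
        for sc in self.scorecards[:10]:
            aucs = " ".join(f"{k}={v:.3f}" for k, v in sorted(sc.auc_by_label.items()))
            lines.append(f"{str(sc.path):<30} {sc.objective:>9.4f}  {aucs}")
        lines += [
            "-" * 64,
            f"best path: {self.best_path}  "
            f"(objective = {self.objective:.4f}, "
            f"positives = {'x'.join(self.model.positive_labels)})",
        ]
        return "\n".join(lines)
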