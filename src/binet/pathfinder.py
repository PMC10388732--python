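"""Boolean path discovery and supervised path selection.

A Boolean path is an ordered chain of clusters with exactly one
HIGH_LOW/OPPOSITE transition (the pivot) flanked by low=>low chains; read
along the path it describes a continuum in which genes on the high side
switch off while genes on the low side progressively switch on. Clusters
before the pivot carry negative integer weights (..., -2, -1) and clusters
from the pivot onwards positive ones (1, 2, ...), so a composite score
orders samples along the continuum.

Discovery follows the greedy size-first traversal: start from a big
cluster, walk the low=>low chain (bigger successors first), pivot to the
largest OPPOSITE/HIGH_LOW partner, and walk a second low=>low chain.
Selection scores each candidate path on labelled samples and ranks by the
product of one-vs-rest ROC-AUCs of the designated positive classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .implication import RelationType
from .io import ExpressionMatrix
from .network import ClusteredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "BooleanPath", "PathScorecard",
    "discover_paths", "enumerate_3node_paths", "select_best_path",
]

_PIVOT_RELATIONS = (RelationType.OPPOSITE, RelationType.HIGH_LOW)


@dataclass(frozen=True)
class BooleanPath:
    """An ordered, weighted cluster chain with one high->low transition.

    ``pivot_index`` is the position of the first positive-weight cluster;
    the pivot edge joins positions ``pivot_index - 1`` and ``pivot_index``.
    A ``pivot_index`` of 0 marks a single-arm (pure low=>low) path.
    """

    cluster_ids: tuple
    pivot_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.pivot_index <= len(self.cluster_ids):
            raise ValueError("pivot_index out of range")

    @property
    def weights(self) -> tuple:
        p = self.pivot_index
        return tuple(i - p if i < p else i - p + 1
                     for i in range(len(self.cluster_ids)))

    @property
    def has_pivot(self) -> bool:
        return 0 < self.pivot_index < len(self.cluster_ids)

    def weighted_clusters(self) -> list:
        return list(zip(self.cluster_ids, self.weights))

    def validate(self, cbin: ClusteredNetwork) -> bool:
        """Check the edge pattern against a clustered network.

        Edges before the pivot must read HIGH_HIGH forward (= LOW_LOW in
        reverse), the pivot edge OPPOSITE/HIGH_LOW, and edges after it
        LOW_LOW.
        """
        ids = self.cluster_ids
        for i in range(len(ids) - 1):
            r = cbin.relation(ids[i], ids[i + 1])
            if i == self.pivot_index - 1:
                if r not in _PIVOT_RELATIONS:
                    return False
            elif i < self.pivot_index - 1:
                if r != RelationType.HIGH_HIGH:
                    return False
            elif r != RelationType.LOW_LOW:
                return False
        return True

    def __str__(self) -> str:
        parts = [f"{c}({w:+d})" for c, w in self.weighted_clusters()]
        return " -> ".join(parts)


@dataclass
class PathScorecard:
    """Supervised performance of one path's composite score."""

    path: BooleanPath
    auc_by_label: dict
    objective: float
    composite: object = field(default=None, repr=False)


def _low_low_chain(start: int, cbin: ClusteredNetwork, visited: set) -> list:
    """Greedy low=>low walk from ``start``, larger clusters first."""
    sizes = cbin.sizes
    chain = [start]
    visited.add(start)
    current = start
    while True:
        succ = [c.id for c in cbin.clusters
                if c.id not in visited
                and cbin.relation(current, c.id) == RelationType.LOW_LOW]
        if not succ:
            return chain
        current = max(succ, key=lambda cid: (sizes[cid], -cid))
        visited.add(current)
        chain.append(current)


def discover_paths(cbin: ClusteredNetwork, n_starts: int = 5) -> list[BooleanPath]:
    """Greedy size-first discovery of pivoted Boolean paths.

    For each of the ``n_starts`` largest clusters S: walk the low=>low
    chain from S, find the largest cluster S2 with S OPPOSITE S2 or
    S HIGH_LOW S2, walk a second low=>low chain from S2, and emit
    reversed(chain2) + chain1 with the pivot between them. Starts without
    a pivot partner emit their single low=>low arm (if it has at least two
    clusters) with a warning. Duplicates are removed.
    """
    if not cbin.clusters:
        return []
    sizes = cbin.sizes
    starts = sorted(cbin.clusters, key=lambda c: (-c.size, c.id))[:n_starts]
    paths: list[BooleanPath] = []
    no_pivot_anywhere = True
    for s in starts:
        visited: set = set()
        chain1 = _low_low_chain(s.id, cbin, visited)
        pivots = [c.id for c in cbin.clusters
                  if c.id not in visited
                  and cbin.relation(s.id, c.id) in _PIVOT_RELATIONS]
        if pivots:
            no_pivot_anywhere = False
            s2 = max(pivots, key=lambda cid: (sizes[cid], -cid))
            chain2 = _low_low_chain(s2, cbin, visited)
            ids = tuple(reversed(chain2)) + tuple(chain1)
            paths.append(BooleanPath(cluster_ids=ids, pivot_index=len(chain2)))
        elif len(chain1) >= 2:
            logger.warning("discover_paths: start %d has no OPPOSITE/HIGH_LOW "
                           "pivot; emitting single-arm path", s.id)
            paths.append(BooleanPath(cluster_ids=tuple(chain1), pivot_index=0))
    if no_pivot_anywhere and not paths:
        logger.warning("discover_paths: no pivot found from any start")
    seen, unique = set(), []
    for p in paths:
        key = (p.cluster_ids, p.pivot_index)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


def enumerate_3node_paths(cbin: ClusteredNetwork) -> list[BooleanPath]:
    """All transitive 3-cluster paths A -> B -> C with the pivot at A-B.

    The A-B edge must be OPPOSITE or HIGH_LOW and the B-C edge low=>low;
    weights are (-1, 1, 2). Mirrored readings (C, B, A) describe the same
    continuum and are not emitted separately.
    """
    ids = [c.id for c in cbin.clusters]
    out = []
    for a, b, c in itertools.permutations(ids, 3):
        if cbin.relation(a, b) in _PIVOT_RELATIONS \
                and cbin.relation(b, c) == RelationType.LOW_LOW:
            out.append(BooleanPath(cluster_ids=(a, b, c), pivot_index=1))
    return out


def select_best_path(paths: list[BooleanPath], matrix: ExpressionMatrix,
                     labels: pd.Series, cluster_genes: dict,
                     positive_labels=("M1", "M2"),
                     low_labels=None) -> list[PathScorecard]:
    """Rank candidate paths by the product of positive-class ROC-AUCs.

    Each path's composite score is computed on ``matrix``; one-vs-rest
    classification AUC is evaluated per label over the labelled samples;
    the objective is the product of the AUCs of ``positive_labels``.

    The composite score runs from the reactive (low) to the tolerant
    (high) end of the continuum, so the AUC of a class expected at the
    low end is evaluated on the reversed score: ``low_labels`` defaults
    to the first positive label (M1-like). Classes with no designated
    side report the direction-free separability max(a, 1 - a). Under
    random labels every reported AUC is centred on 0.5, so the null
    objective is ~0.25 for two positive classes.

    Paths referencing unknown clusters, or labels with fewer than 2
    samples on a side, are skipped with a warning. Returns scorecards
    sorted by objective descending (ties broken by cluster ids, for
    determinism).
    """
    from .scoring import composite_score, evaluate_auc

    if not paths:
        raise ValueError("no candidate paths")
    labels = labels.dropna()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("labels must cover at least 2 classes")
    counts = labels.value_counts()
    usable = [c for c in classes if counts[c] >= 2 and (len(labels) - counts[c]) >= 2]
    skipped_classes = sorted(set(classes) - set(usable))
    if skipped_classes:
        logger.warning("select_best_path: classes %s have <2 samples on a side; "
                       "their AUC is undefined", skipped_classes)
    if any(p not in usable for p in positive_labels):
        raise ValueError(f"positive labels {positive_labels} not all evaluable")
    if low_labels is None:
        low_labels = {positive_labels[0]} if positive_labels else set()
    high_labels = set(positive_labels) - set(low_labels)
    cards = []
    sample_labels = labels.loc[[s for s in labels.index if s in set(matrix.sample_ids)]]
    sub = matrix.subset_samples(list(sample_labels.index))
    for path in paths:
        try:
            sigs = [(cluster_genes[cid], w) for cid, w in path.weighted_clusters()]
        except KeyError as exc:
            logger.warning("select_best_path: path %s references unknown cluster "
                           "%s; skipped", path, exc)
            continue
        cs = composite_score(sub, sigs)
        aucs = {}
        for cls in usable:
            raw = evaluate_auc(cs.score, (sample_labels == cls).to_numpy())
            if cls in low_labels:
                aucs[cls] = 1.0 - raw
            elif cls in high_labels:
                aucs[cls] = raw
            else:
                aucs[cls] = max(raw, 1.0 - raw)
        objective = 1.0
        for p in positive_labels:
            objective *= aucs[p]
        cards.append(PathScorecard(path=path, auc_by_label=aucs,
                                   objective=objective, composite=cs))
    cards.sort(key=lambda sc: (-sc.objective, sc.path.cluster_ids))
    return cards
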