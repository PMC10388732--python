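"""Composite signature scores, sample classification, survival
stratification and circadian normalization.

Every gene is normalized by a modified z-score centred on its own
StepMiner threshold, z = (expr - thr) / (3 * stddev); cluster scores are
the per-sample means of their genes' z rows, and a path's composite score
is the weighted sum of its cluster scores. By convention low composite
scores mark the "reactive" (M1-like) end of the continuum and high scores
the "tolerant" (M2-like) end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet
from .stepminer import DEFAULT_MARGIN, DegenerateStepError, fit_step

logger = logging.getLogger(__name__)

__all__ = [
    "CompositeScore", "SurvivalStratification",
    "gene_zscore", "cluster_score", "composite_score",
    "evaluate_auc", "stratify_survival", "circadian_normalize",
]

REACTIVE = "REACTIVE"
TOLERANT = "TOLERANT"
INTERMEDIATE_CALL = "INTERMEDIATE"


@dataclass
class CompositeScore:
    """Per-sample composite signature score with its own threshold.

    Calls follow the StepMiner threshold on the score distribution with a
    noise margin: score < threshold - margin -> REACTIVE, score >
    threshold + margin -> TOLERANT, else INTERMEDIATE.
    """

    sample_ids: list
    score: np.ndarray
    threshold: float
    margin: float
    calls: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.calls:
            self.calls = [
                REACTIVE if s < self.threshold - self.margin
                else TOLERANT if s > self.threshold + self.margin
                else INTERMEDIATE_CALL
                for s in self.score
            ]

    def as_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.sample_ids, name="score")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.score, "call": self.calls},
                            index=pd.Index(self.sample_ids, name="sample"))


@dataclass
class SurvivalStratification:
    """Two-group log-rank stratification of a cohort by composite score."""

    threshold: float
    n_low: int
    n_high: int
    statistic: float
    p_value: float
    candidate_p: dict


def gene_zscore(expr_row, threshold: float, stddev: float | None = None) -> np.ndarray:
    """Modified z-score of one gene row: (expr - threshold) / (3 * stddev).

    ``stddev`` defaults to the population standard deviation over the
    row's finite values; a zero stddev yields an all-zero row (warned).
    NaN inputs stay NaN.
    """
    arr = np.asarray(expr_row, dtype=float)
    if stddev is None:
        finite = arr[np.isfinite(arr)]
        stddev = float(finite.std()) if finite.size else 0.0
    if stddev == 0:
        logger.warning("gene_zscore: zero standard deviation; returning zeros")
        out = np.zeros_like(arr)
        out[~np.isfinite(arr)] = np.nan
        return out
    return (arr - threshold) / (3.0 * stddev)


def _signature_zmatrix(matrix: ExpressionMatrix, genes) -> tuple[np.ndarray, float]:
    """Z rows for the genes of one signature present in the matrix.

    Returns the stacked z matrix and the mean stddev of the used genes
    (needed for noise-margin propagation).
    """
    members = set(genes.members if isinstance(genes, GeneSet) else
                  (str(g).upper() for g in genes))
    present = [g for g in matrix.gene_ids if g in members]
    name = genes.name if isinstance(genes, GeneSet) else "signature"
    if not present:
        raise ValueError(f"no genes of signature {name!r} present in matrix")
    if len(present) < len(members):
        logger.info("signature %r: %d of %d genes present", name,
                    len(present), len(members))
    zrows, sds = [], []
    for g in present:
        row = matrix.data.loc[g].to_numpy(dtype=float)
        finite = row[np.isfinite(row)]
        sd = float(finite.std()) if finite.size else 0.0
        try:
            thr = fit_step(row).threshold
        except (DegenerateStepError, ValueError):
            thr = float(finite.mean()) if finite.size else 0.0
        zrows.append(gene_zscore(row, thr, sd))
        sds.append(sd)
    positive = [s for s in sds if s > 0]
    mean_sd = float(np.mean(positive)) if positive else 0.0
    return np.vstack(zrows), mean_sd


def cluster_score(matrix: ExpressionMatrix, cluster) -> np.ndarray:
    """Mean modified z-score of a cluster's genes, per sample."""
    z, _ = _signature_zmatrix(matrix, cluster)
    with np.errstate(invalid="ignore"):
        return np.nanmean(z, axis=0)


def composite_score(matrix: ExpressionMatrix, signatures,
                    margin: float | None = None,
                    expression_margin: float = DEFAULT_MARGIN) -> CompositeScore:
    """Weighted sum of cluster scores along a Boolean path.

    Parameters
    ----------
    signatures : sequence of (genes, weight)
        Gene sets (or iterables of gene IDs) with their path weights,
        e.g. [(c13, -1), (c14, 1), (c3, 2)].
    margin : float, optional
        Explicit noise margin on the composite score. By default the
        +-``expression_margin`` band around each gene's threshold is
        propagated through the z-normalization and the weights:
        sum_i |w_i| * expression_margin / (3 * mean stddev of cluster i).
    """
    if not signatures:
        raise ValueError("composite_score needs at least one signature")
    total = np.zeros(matrix.shape[1])
    prop_margin = 0.0
    for genes, weight in signatures:
        z, mean_sd = _signature_zmatrix(matrix, genes)
        with np.errstate(invalid="ignore"):
            total = total + weight * np.nanmean(z, axis=0)
        if mean_sd > 0:
            prop_margin += abs(weight) * expression_margin / (3.0 * mean_sd)
    if margin is None:
        margin = prop_margin
    try:
        threshold = fit_step(total).threshold
    except (DegenerateStepError, ValueError):
        logger.warning("composite_score: degenerate score distribution; "
                       "threshold set to the mean")
        threshold = float(np.mean(total))
    return CompositeScore(sample_ids=list(matrix.sample_ids),
                          score=np.asarray(total, dtype=float),
                          threshold=float(threshold), margin=float(margin))


def evaluate_auc(scores, binary_labels) -> float:
    """Rank-based ROC-AUC of a score for a binary label (midrank ties).

    Equals the Mann-Whitney U statistic divided by n1*n0, i.e. the AUC of
    any univariate monotone classifier on the score.
    """
    from sklearn.metrics import roc_auc_score

    y = np.asarray(binary_labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("evaluate_auc needs both classes present")
    return float(roc_auc_score(y, s))


def stratify_survival(scores: CompositeScore, cohort: pd.DataFrame,
                      min_group: int = 2) -> SurvivalStratification:
    """Split a survival cohort at the best of three candidate thresholds.

    The candidates are the score's StepMiner threshold and the threshold
    +- its noise margin. Each candidate defines low/high score groups; a
    two-group log-rank test is run for every candidate that leaves at
    least ``min_group`` samples per side, and the candidate with the
    smallest p-value is returned together with all candidate p-values.
    """
    from lifelines.statistics import logrank_test

    s = scores.as_series()
    common = [x for x in cohort["sample"] if x in s.index]
    if len(common) < 2 * min_group:
        raise ValueError("survival cohort shares too few samples with the scores")
    coh = cohort.set_index("sample").loc[common]
    vals = s.loc[common].to_numpy()
    candidates = {
        "threshold": scores.threshold,
        "threshold-margin": scores.threshold - scores.margin,
        "threshold+margin": scores.threshold + scores.margin,
    }
    results = {}
    best = None
    for name, thr in candidates.items():
        low = vals < thr
        if low.sum() < min_group or (~low).sum() < min_group:
            logger.info("stratify_survival: candidate %s leaves a group "
                        "below %d samples; skipped", name, min_group)
            results[name] = float("nan")
            continue
        lr = logrank_test(coh["time"].to_numpy()[low], coh["time"].to_numpy()[~low],
                          event_observed_A=coh["event"].to_numpy()[low],
                          event_observed_B=coh["event"].to_numpy()[~low])
        results[name] = float(lr.p_value)
        if best is None or lr.p_value < best[2]:
            best = (thr, low, float(lr.p_value), float(lr.test_statistic))
    if best is None:
        raise ValueError("every candidate threshold left an empty group")
    thr, low, p, stat = best
    return SurvivalStratification(threshold=float(thr), n_low=int(low.sum()),
                                  n_high=int((~low).sum()), statistic=stat,
                                  p_value=p, candidate_p=results)


def circadian_normalize(scores, clock_values, group_labels) -> np.ndarray:
    """Remove the circadian trend from composite scores.

    Macrophage state swings between reactive and tolerant across the
    day-night cycle; clock-gene expression is used to adjust for it.
    Per sample group, the score (y) and clock value (x) are rescaled by
    the group's dynamic ranges S1 (scores) and S2 (clock): with (S3, S4)
    the signed offsets of a sample from the group mean point,

        x' = x - S3 * (S2 + 1) / (S1 + 1)
        y' = y + S4 * (S1 + 1) / (S2 + 1)

    A single linear regression of y' on x' across all samples then
    estimates the residual trend, which is subtracted; the residuals are
    the normalized scores. Groups with a zero range in either variable
    are left untransformed (warned).
    """
    y = np.asarray(scores, dtype=float)
    x = np.asarray(clock_values, dtype=float)
    groups = np.asarray(group_labels)
    if not (len(y) == len(x) == len(groups)):
        raise ValueError("scores, clock values and groups must align")
    xt, yt = x.copy(), y.copy()
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() < 2:
            logger.warning("circadian_normalize: group %r has <2 samples; skipped", g)
            continue
        s1 = y[sel].max() - y[sel].min()   # score range
        s2 = x[sel].max() - x[sel].min()   # clock range
        if s1 == 0 or s2 == 0:
            logger.warning("circadian_normalize: group %r has zero range; skipped", g)
            continue
        s3 = x[sel] - x[sel].mean()
        s4 = y[sel] - y[sel].mean()
        xt[sel] = x[sel] - s3 * (s2 + 1.0) / (s1 + 1.0)
        yt[sel] = y[sel] + s4 * (s1 + 1.0) / (s2 + 1.0)
    if np.ptp(xt) == 0:
        trend = np.full_like(yt, yt.mean())
    else:
        slope, intercept = np.polyfit(xt, yt, 1)
        trend = slope * xt + intercept
    return yt - trend
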