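"""Statistical utilities: proportion z-test, hypergeometric overlap,
Benjamini-Hochberg adjustment, and the proteomics induction filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ProportionTest", "OverlapTest",
    "two_proportion_ztest", "hypergeometric_overlap", "bh_adjust",
    "protein_induction_filter",
]


@dataclass(frozen=True)
class ProportionTest:
    """Two-sample z-test of proportions, two-tailed.

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)) with the pooled
    proportion p = (x1 + x2) / (n1 + n2).
    """

    x1: int
    n1: int
    x2: int
    n2: int
    p1: float
    p2: float
    p_pooled: float
    z: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric test of a gene-set overlap."""

    size_a: int
    size_b: int
    overlap: int
    universe: int
    p_value: float
    neg_log10_p: float


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> ProportionTest:
    """Two-tailed z-test comparing proportions x1/n1 and x2/n2.

    A pooled proportion of exactly 0 or 1 leaves z undefined; the result
    is flagged degenerate with p_value 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    if p in (0.0, 1.0):
        logger.warning("two_proportion_ztest: pooled proportion is %g; "
                       "z undefined", p)
        return ProportionTest(x1, n1, x2, n2, p1, p2, p, float("nan"), 1.0,
                              degenerate=True)
    z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    p_value = 2.0 * sps.norm.sf(abs(z))
    return ProportionTest(x1, n1, x2, n2, p1, p2, p, float(z), float(p_value))


def hypergeometric_overlap(set_a: GeneSet, set_b: GeneSet,
                           universe: GeneSet) -> OverlapTest:
    """Enrichment p-value of the overlap of two gene sets in a universe.

    Members outside the universe are trimmed (logged). The p-value is the
    upper-tail hypergeometric probability of an overlap at least as large
    as observed.
    """
    uni = set(universe.members)
    if not uni:
        raise ValueError("empty universe")
    a = set(set_a.members) & uni
    b = set(set_b.members) & uni
    trimmed = (len(set_a) - len(a)) + (len(set_b) - len(b))
    if trimmed:
        logger.info("hypergeometric_overlap: trimmed %d members outside "
                    "the universe", trimmed)
    k = len(a & b)
    # P(X >= k) for X ~ Hypergeom(N=|U|, K=|a|, n=|b|)
    p = float(sps.hypergeom.sf(k - 1, len(uni), len(a), len(b)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return OverlapTest(size_a=len(a), size_b=len(b), overlap=k,
                       universe=len(uni), p_value=p,
                       neg_log10_p=float(-np.log10(p)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def protein_induction_filter(intensity_a: pd.DataFrame, intensity_b: pd.DataFrame,
                             fold_a: float = 2.0, fold_b: float = 1.5
                             ) -> tuple[list, list]:
    """Proteins induced under condition A or B across all time points.

    ``intensity_a`` and ``intensity_b`` are proteins x time-points tables
    of raw intensities under the two stimulations (e.g. LPS/IFNg vs IL4).
    A protein is induced in A when the per-time-point ratio a/b is >=
    ``fold_a`` at every time point, and induced in B when b/a >= ``fold_b``
    at every time point (the cut-offs mirror the 2-fold and 1.5-fold
    M1/M2 induction thresholds). Proteins with any nonpositive intensity
    are excluded (logged).
    """
    if not intensity_a.index.equals(intensity_b.index) \
            or not intensity_a.columns.equals(intensity_b.columns):
        raise ValueError("intensity tables must share proteins and time points")
    a = intensity_a.to_numpy(dtype=float)
    b = intensity_b.to_numpy(dtype=float)
    valid = (a > 0).all(axis=1) & (b > 0).all(axis=1)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("protein_induction_filter: excluded %d proteins with "
                    "nonpositive intensities", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
        induced_a = valid & (ratio >= fold_a).all(axis=1)
        induced_b = valid & ((1.0 / ratio) >= fold_b).all(axis=1)
    proteins = intensity_a.index
    return list(proteins[induced_a]), list(proteins[induced_b])
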