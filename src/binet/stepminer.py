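"""StepMiner: adaptive one-step regression on sorted expression values.

A gene's expression values are sorted ascending and a rising step function
is fitted by evaluating every step position k (the first k values form the
low segment, the rest the high segment; each segment is fitted by its mean).
The k minimizing the residual sum of squares wins; the midpoint of the two
segment means is the StepMiner threshold that separates "low" from "high"
expression. A noise margin (default +-0.5, i.e. 2-fold on a log2 scale)
around the threshold defines an "intermediate" band whose values are ignored
by downstream Boolean analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LOW", "INTERMEDIATE", "HIGH",
    "StepFit", "TernaryVector", "DegenerateStepError",
    "fit_step", "stepminer_threshold", "discretize", "discretize_matrix",
]

LOW: int = -1
INTERMEDIATE: int = 0
HIGH: int = 1

DEFAULT_MARGIN = 0.5


class DegenerateStepError(ValueError):
    """Raised when the input has no variation (a step cannot be placed)."""


@dataclass(frozen=True)
class StepFit:
    """Result of the one-step fit on a sorted value vector.

    Attributes
    ----------
    n : number of finite values fitted
    k : step position = size of the low segment (1 <= k <= n-1)
    mu_low, mu_high : segment means (mu_low <= mu_high after sorting)
    sse : residual sum of squares of the fitted step
    fstat : regression F statistic with m model degrees of freedom
    threshold : (mu_low + mu_high) / 2
    m : model degrees of freedom used in the F statistic
    """

    n: int
    k: int
    mu_low: float
    mu_high: float
    sse: float
    fstat: float
    threshold: float
    m: int = 3


@dataclass
class TernaryVector:
    """Low/intermediate/high codes for a value vector at a given threshold."""

    codes: np.ndarray
    threshold: float
    margin: float = DEFAULT_MARGIN


def _step_sse_profile(sorted_vals: np.ndarray) -> np.ndarray:
    """SSE of the best two-mean fit for every step position k = 1..n-1."""
    n = sorted_vals.size
    s = np.cumsum(sorted_vals)
    total = s[-1]
    sq = float(np.dot(sorted_vals, sorted_vals))
    k = np.arange(1, n)
    low_sum = s[:-1]
    high_sum = total - low_sum
    # SSE(k) = sum x^2 - S_k^2/k - (S_n - S_k)^2/(n-k)
    return sq - low_sum**2 / k - high_sum**2 / (n - k)


def fit_step(values, m: int = 3) -> StepFit:
    """Fit a rising step to ``values`` (sorted internally).

    Parameters
    ----------
    values : array-like
        At least 4 finite values; NaNs are dropped.
    m : int
        Model degrees of freedom of the adaptive regression (two segment
        means plus the step position).

    Raises
    ------
    ValueError
        Fewer than 4 finite values.
    DegenerateStepError
        All values equal; no step exists.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n < 4:
        raise ValueError(f"fit_step needs at least 4 finite values, got {n}")
    x = np.sort(arr)
    if x[0] == x[-1]:
        raise DegenerateStepError("constant vector: step fit is degenerate")
    sse = _step_sse_profile(x)
    k = int(np.argmin(sse)) + 1  # ties resolve to the smallest k
    mu_low = float(x[:k].mean())
    mu_high = float(x[k:].mean())
    best_sse = max(float(sse[k - 1]), 0.0)
    xbar = float(x.mean())
    fitted_ss = k * (mu_low - xbar) ** 2 + (n - k) * (mu_high - xbar) ** 2
    if n > m and best_sse > 0:
        fstat = (fitted_ss / (m - 1)) / (best_sse / (n - m))
    else:
        fstat = float("inf") if fitted_ss > 0 else 0.0
    return StepFit(n=n, k=k, mu_low=mu_low, mu_high=mu_high, sse=best_sse,
                   fstat=float(fstat), threshold=(mu_low + mu_high) / 2.0, m=m)


def stepminer_threshold(values, m: int = 3) -> float:
    """Midpoint of the two segment means of the best step fit."""
    return fit_step(values, m=m).threshold


def discretize(values, threshold: float, margin: float = DEFAULT_MARGIN) -> TernaryVector:
    """Code values as LOW/INTERMEDIATE/HIGH around ``threshold`` +- ``margin``.

    Preserves the input order. NaN values code as INTERMEDIATE (they carry
    no Boolean information) and are logged.
    """
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    arr = np.asarray(values, dtype=float)
    codes = np.zeros(arr.shape, dtype=np.int8)
    codes[arr < threshold - margin] = LOW
    codes[arr > threshold + margin] = HIGH
    n_na = int(np.isnan(arr).sum())
    if n_na:
        logger.info("discretize: %d missing values coded INTERMEDIATE", n_na)
    return TernaryVector(codes=codes, threshold=float(threshold), margin=float(margin))


def discretize_matrix(matrix: ExpressionMatrix, margin: float = DEFAULT_MARGIN,
                      m: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene StepMiner fit + ternary coding of a whole matrix.

    Returns
    -------
    codes : DataFrame (genes x samples, int8 in {-1, 0, 1})
        Genes with a degenerate (constant) fit are all-INTERMEDIATE.
    fits : DataFrame indexed by gene with columns threshold, sse, fstat, k,
        mu_low, mu_high, degenerate.
    """
    rows = []
    codes = np.zeros(matrix.shape, dtype=np.int8)
    vals = matrix.values
    for i, gene in enumerate(matrix.gene_ids):
        try:
            fit = fit_step(vals[i], m=m)
        except DegenerateStepError:
            rows.append((np.nan, np.nan, np.nan, 0, np.nan, np.nan, True))
            continue
        except ValueError:
            rows.append((np.nan, np.nan, np.nan, 0, np.nan, np.nan, True))
            continue
        codes[i] = discretize(vals[i], fit.threshold, margin).codes
        rows.append((fit.threshold, fit.sse, fit.fstat, fit.k,
                     fit.mu_low, fit.mu_high, False))
    fits = pd.DataFrame(rows, index=matrix.gene_ids,
                        columns=["threshold", "sse", "fstat", "k",
                                 "mu_low", "mu_high", "degenerate"])
    n_degen = int(fits["degenerate"].sum())
    if n_degen:
        logger.warning("discretize_matrix: %d genes had degenerate step fits", n_degen)
    codes_df = pd.DataFrame(codes, index=matrix.gene_ids, columns=matrix.sample_ids)
    return codes_df, fits
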