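"""Single-cell application of composite scores: quadrant assignment,
group enrichment and pseudobulk mixtures.

Each cell gets two composite scores, a reactive axis (e.g. the C#13
signature with weight -1) and a tolerant axis (e.g. C#14 -> C#3 with
weights 1, 2), computed exactly as for bulk samples. StepMiner thresholds
on the two per-cell score distributions split the scatter plot into four
quadrants; the bottom-left quadrant enriches reactive (M1-like) cells and
the top-right tolerant (M2-like) cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .scoring import composite_score
from .stats import two_proportion_ztest

logger = logging.getLogger(__name__)

__all__ = [
    "score_cells", "quadrant_enrichment", "make_pseudobulk", "gate_cells",
    "QUADRANTS",
]

QUADRANTS = ("BL", "BR", "TL", "TR")


def _quadrant(x_low: np.ndarray, y_low: np.ndarray) -> np.ndarray:
    out = np.empty(x_low.shape, dtype=object)
    out[x_low & y_low] = "BL"
    out[~x_low & y_low] = "BR"
    out[x_low & ~y_low] = "TL"
    out[~x_low & ~y_low] = "TR"
    return out


def score_cells(cell_matrix: ExpressionMatrix, sig_x, sig_y,
                margin: float = 0.0) -> pd.DataFrame:
    """Two-axis composite scores and quadrant assignment per cell.

    Parameters
    ----------
    sig_x, sig_y : sequence of (genes, weight)
        Path fragments for the reactive (x) and tolerant (y) axes.
    margin : float
        Optional noise margin on the quadrant thresholds; a cell on the
        boundary (score == threshold) falls on the low side.

    Returns
    -------
    DataFrame indexed by cell with columns score_x, score_y, thr_x,
    thr_y, quadrant.
    """
    cs_x = composite_score(cell_matrix, sig_x, margin=margin)
    cs_y = composite_score(cell_matrix, sig_y, margin=margin)
    x, y = cs_x.score, cs_y.score
    x_low = x < cs_x.threshold + 1e-12  # boundary cells go to the low side
    y_low = y < cs_y.threshold + 1e-12
    return pd.DataFrame({
        "score_x": x, "score_y": y,
        "thr_x": cs_x.threshold, "thr_y": cs_y.threshold,
        "quadrant": _quadrant(x_low, y_low),
    }, index=pd.Index(cell_matrix.sample_ids, name="cell"))


def quadrant_enrichment(assignment: pd.DataFrame, cell_groups: pd.Series,
                        quadrant: str = "BL",
                        pairs=None) -> pd.DataFrame:
    """Per-group occupancy of a quadrant plus two-proportion z-tests.

    ``cell_groups`` maps cell -> group label. For each requested pair of
    groups (all ordered pairs of distinct groups by default) the
    difference in quadrant proportions is tested with the two-tailed
    two-proportion z-test. Empty groups are excluded.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    groups = cell_groups.loc[[c for c in assignment.index if c in cell_groups.index]]
    in_quad = assignment.loc[groups.index, "quadrant"] == quadrant
    tallies = {}
    for g in pd.unique(groups):
        sel = groups == g
        n = int(sel.sum())
        if n == 0:
            continue
        tallies[g] = (int(in_quad[sel].sum()), n)
    if len(tallies) < 2:
        raise ValueError("quadrant_enrichment needs at least 2 non-empty groups")
    if pairs is None:
        keys = list(tallies)
        pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1:]]
    rows = []
    for a, b in pairs:
        xa, na = tallies[a]
        xb, nb = tallies[b]
        zt = two_proportion_ztest(xa, na, xb, nb)
        rows.append({"group_a": a, "group_b": b,
                     "prop_a": zt.p1, "prop_b": zt.p2,
                     "n_a": na, "n_b": nb, "z": zt.z, "p_value": zt.p_value})
    return pd.DataFrame(rows)


def make_pseudobulk(cell_matrix: ExpressionMatrix, cell_labels: pd.Series,
                    composition: dict, n_cells: int, seed: int = 0,
                    background_label: str | None = None) -> pd.Series:
    """Average expression over a random cell mixture.

    ``composition`` maps label -> fraction of ``n_cells``; fractions must
    sum to at most 1 and any remainder is drawn from ``background_label``.
    Cells are sampled without replacement per label; deterministic given
    ``seed``. Returns the per-gene mean expression of the mixture.
    """
    fracs = dict(composition)
    if any(f < 0 for f in fracs.values()) or sum(fracs.values()) > 1 + 1e-9:
        raise ValueError("composition fractions must be nonnegative and sum <= 1")
    counts = {lab: int(round(f * n_cells)) for lab, f in fracs.items()}
    remainder = n_cells - sum(counts.values())
    if remainder > 0:
        if background_label is None:
            raise ValueError("composition sums below 1 but no background_label given")
        counts[background_label] = counts.get(background_label, 0) + remainder
    rng = np.random.default_rng(seed)
    labels = cell_labels.loc[[c for c in cell_matrix.sample_ids
                              if c in cell_labels.index]]
    chosen: list[str] = []
    for lab, k in counts.items():
        if k == 0:
            continue
        pool = list(labels.index[labels == lab])
        if len(pool) < k:
            raise ValueError(f"label {lab!r}: requested {k} cells, only "
                             f"{len(pool)} available")
        chosen.extend(rng.choice(pool, size=k, replace=False))
    mean = cell_matrix.data.loc[:, chosen].mean(axis=1)
    mean.name = "pseudobulk"
    return mean


def gate_cells(cell_matrix: ExpressionMatrix, gene_x: str, gene_y: str,
               cutoff_x: float = 2.5, cutoff_y: float = 2.5) -> pd.Series:
    """Two-marker gate: cells above both cutoffs (e.g. TYROBP/FCER1G > 2.5).

    Returns a boolean Series over cells; used to select a cell population
    (such as macrophages) before scoring.
    """
    gx, gy = gene_x.upper(), gene_y.upper()
    for g in (gx, gy):
        if g not in cell_matrix.data.index:
            raise KeyError(f"marker gene {g!r} absent from matrix")
    mask = (cell_matrix.data.loc[gx] > cutoff_x) & (cell_matrix.data.loc[gy] > cutoff_y)
    mask.name = "gated"
    return mask
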