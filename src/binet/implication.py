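"""Boolean implication relationships between pairs of discretized genes.

For two genes coded low/high (intermediates excluded), the paired samples
fall into four scatter-plot quadrants a00, a01, a10, a11 (first index =
gene A's code, second = gene B's, 0 = low, 1 = high). A quadrant is
*sparse* when it holds significantly fewer samples than expected under
independence; the BooleanNet statistic

    S_ij = (e_ij - a_ij) / sqrt(e_ij),   e_ij = (row margin * col margin) / total

together with the error rate p_ij (mean of the two conditional
probabilities of landing in the quadrant given the A row and given the B
column) decides sparsity: sparse iff S_ij > sThr and p_ij < pThr (defaults
3 and 0.1). One sparse quadrant gives an asymmetric implication, a sparse
diagonal pair gives EQUIVALENT (01+10) or OPPOSITE (00+11).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stepminer import TernaryVector, LOW, HIGH

logger = logging.getLogger(__name__)

__all__ = [
    "RelationType", "QuadrantTable",
    "quadrant_counts", "quadrant_stats", "classify_relation",
    "pairwise_relations", "permutation_fdr",
    "DEFAULT_STHR", "DEFAULT_PTHR", "DEFAULT_MIN_TOTAL",
]

DEFAULT_STHR = 3.0
DEFAULT_PTHR = 0.1
#: pairs with fewer retained (non-intermediate) samples than this are NONE
DEFAULT_MIN_TOTAL = 8


class RelationType(enum.IntEnum):
    """The six Boolean implication relationships (plus NONE).

    Asymmetric types read "A <x> implies B <y>": LOW_LOW is
    "A low => B low", HIGH_LOW is "A high => B low", etc.
    """

    NONE = 0
    EQUIVALENT = 1
    OPPOSITE = 2
    LOW_LOW = 3
    LOW_HIGH = 4
    HIGH_HIGH = 5
    HIGH_LOW = 6

    @property
    def symmetric(self) -> bool:
        return self in (RelationType.EQUIVALENT, RelationType.OPPOSITE,
                        RelationType.LOW_HIGH, RelationType.HIGH_LOW)

    def mirror(self) -> "RelationType":
        """The relation read in the B -> A direction."""
        if self == RelationType.LOW_LOW:
            return RelationType.HIGH_HIGH
        if self == RelationType.HIGH_HIGH:
            return RelationType.LOW_LOW
        return self


#: sparse quadrant -> asymmetric relation called for it
_QUADRANT_RELATION = {
    "00": RelationType.LOW_HIGH,   # A low => B high
    "01": RelationType.LOW_LOW,    # A low => B low
    "10": RelationType.HIGH_HIGH,  # A high => B high
    "11": RelationType.HIGH_LOW,   # A high => B low
}


@dataclass
class QuadrantTable:
    """2x2 counts of paired low/high codes with per-quadrant statistics."""

    a00: int
    a01: int
    a10: int
    a11: int
    e: dict = field(default_factory=dict)   # expected counts
    s: dict = field(default_factory=dict)   # sparsity statistics
    p: dict = field(default_factory=dict)   # error rates

    @property
    def total(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    @property
    def counts(self) -> dict:
        return {"00": self.a00, "01": self.a01, "10": self.a10, "11": self.a11}

    @property
    def nAlow(self) -> int:
        return self.a00 + self.a01

    @property
    def nBlow(self) -> int:
        return self.a00 + self.a10


def quadrant_counts(a, b) -> QuadrantTable:
    """Count quadrant occupancy for two ternary code vectors.

    Positions where either code is INTERMEDIATE are excluded.
    """
    ca = a.codes if isinstance(a, TernaryVector) else np.asarray(a, dtype=np.int8)
    cb = b.codes if isinstance(b, TernaryVector) else np.asarray(b, dtype=np.int8)
    if ca.shape != cb.shape:
        raise ValueError(f"code vectors differ in length: {ca.shape} vs {cb.shape}")
    keep = (ca != 0) & (cb != 0)
    ca, cb = ca[keep], cb[keep]
    return QuadrantTable(
        a00=int(((ca == LOW) & (cb == LOW)).sum()),
        a01=int(((ca == LOW) & (cb == HIGH)).sum()),
        a10=int(((ca == HIGH) & (cb == LOW)).sum()),
        a11=int(((ca == HIGH) & (cb == HIGH)).sum()),
    )


def quadrant_stats(q: QuadrantTable) -> QuadrantTable:
    """Fill expected counts, sparsity statistics and error rates in place.

    Quadrants with zero expectation or a zero conditional denominator have
    their S/p marked NaN (undefined, never sparse).
    """
    total = q.total
    if total == 0:
        raise ValueError("quadrant table has no retained samples")
    row = {0: q.a00 + q.a01, 1: q.a10 + q.a11}   # A margins
    col = {0: q.a00 + q.a10, 1: q.a01 + q.a11}   # B margins
    for i in (0, 1):
        for j in (0, 1):
            key = f"{i}{j}"
            a = q.counts[key]
            e = row[i] * col[j] / total
            q.e[key] = e
            q.s[key] = (e - a) / np.sqrt(e) if e > 0 else np.nan
            if row[i] > 0 and col[j] > 0:
                q.p[key] = 0.5 * (a / row[i] + a / col[j])
            else:
                q.p[key] = np.nan
    return q


def classify_relation(q: QuadrantTable, sthr: float = DEFAULT_STHR,
                      pthr: float = DEFAULT_PTHR,
                      min_total: int = DEFAULT_MIN_TOTAL) -> RelationType:
    """Call the Boolean implication relation for a quadrant table.

    A quadrant is sparse iff S > sthr and p < pthr (undefined statistics are
    never sparse). Diagonal sparse pairs give EQUIVALENT / OPPOSITE; exactly
    one sparse quadrant gives the matching asymmetric relation; any other
    pattern (including < min_total retained samples) is NONE.
    """
    if q.total < min_total:
        return RelationType.NONE
    if not q.s:
        quadrant_stats(q)
    sparse = {key for key in ("00", "01", "10", "11")
              if np.isfinite(q.s[key]) and np.isfinite(q.p[key])
              and q.s[key] > sthr and q.p[key] < pthr}
    if sparse == {"01", "10"}:
        return RelationType.EQUIVALENT
    if sparse == {"00", "11"}:
        return RelationType.OPPOSITE
    if len(sparse) == 1:
        return _QUADRANT_RELATION[next(iter(sparse))]
    if len(sparse) > 1:
        logger.debug("unclassifiable sparse pattern %s -> NONE", sorted(sparse))
    return RelationType.NONE


# -- vectorized all-pairs engine -----------------------------------------

def pairwise_relations(codes, sthr: float = DEFAULT_STHR, pthr: float = DEFAULT_PTHR,
                       min_total: int = DEFAULT_MIN_TOTAL) -> pd.DataFrame:
    """Relation matrix for all gene pairs of a ternary code matrix.

    Parameters
    ----------
    codes : DataFrame or array, genes x samples, values in {-1, 0, 1}.

    Returns
    -------
    DataFrame (genes x genes, int8) where entry [A, B] is the
    :class:`RelationType` of A -> B. The diagonal is NONE.
    """
    if isinstance(codes, pd.DataFrame):
        genes = list(codes.index)
        arr = codes.to_numpy(dtype=np.int8)
    else:
        arr = np.asarray(codes, dtype=np.int8)
        genes = list(range(arr.shape[0]))
    lo = (arr == LOW).astype(np.float64)
    hi = (arr == HIGH).astype(np.float64)
    a = {
        "00": lo @ lo.T, "01": lo @ hi.T,
        "10": hi @ lo.T, "11": hi @ hi.T,
    }
    total = a["00"] + a["01"] + a["10"] + a["11"]
    row = {0: a["00"] + a["01"], 1: a["10"] + a["11"]}
    col = {0: a["00"] + a["10"], 1: a["01"] + a["11"]}
    sparse = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in (0, 1):
            for j in (0, 1):
                key = f"{i}{j}"
                e = row[i] * col[j] / np.maximum(total, 1)
                s = np.where(e > 0, (e - a[key]) / np.sqrt(np.maximum(e, 1e-300)), np.nan)
                denom_ok = (row[i] > 0) & (col[j] > 0)
                p = np.where(denom_ok,
                             0.5 * (a[key] / np.maximum(row[i], 1)
                                    + a[key] / np.maximum(col[j], 1)),
                             np.nan)
                sparse[key] = (e > 0) & denom_ok & (s > sthr) & (p < pthr)
    n_sparse = sum(m.astype(np.int8) for m in sparse.values())
    rel = np.zeros(total.shape, dtype=np.int8)
    one = n_sparse == 1
    for key, r in _QUADRANT_RELATION.items():
        rel[one & sparse[key]] = int(r)
    rel[(n_sparse == 2) & sparse["01"] & sparse["10"]] = int(RelationType.EQUIVALENT)
    rel[(n_sparse == 2) & sparse["00"] & sparse["11"]] = int(RelationType.OPPOSITE)
    rel[total < min_total] = int(RelationType.NONE)
    np.fill_diagonal(rel, int(RelationType.NONE))
    return pd.DataFrame(rel, index=genes, columns=genes)


def _nonnone_pair_fraction(rel: pd.DataFrame) -> float:
    arr = rel.to_numpy()
    g = arr.shape[0]
    iu = np.triu_indices(g, k=1)
    upper = arr[iu]
    lower = arr.T[iu]
    called = (upper != 0) | (lower != 0)
    n_pairs = iu[0].size
    return float(called.sum() / n_pairs) if n_pairs else 0.0


def permutation_fdr(codes, n_perm: int = 5, sthr: float = DEFAULT_STHR,
                    pthr: float = DEFAULT_PTHR, seed: int = 0,
                    min_total: int = DEFAULT_MIN_TOTAL) -> float:
    """Permutation estimate of the false discovery rate of relation calls.

    Each permutation shuffles every gene's codes independently across
    samples (the StepMiner threshold is a function of the sorted values, so
    permuting codes is equivalent to permuting expression values and
    re-discretizing), calls relations on all pairs, and records the
    fraction of pairs with a non-NONE call; the mean over permutations is
    returned. Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(codes, pd.DataFrame):
        arr = codes.to_numpy(dtype=np.int8)
    else:
        arr = np.asarray(codes, dtype=np.int8)
    if arr.shape[1] < DEFAULT_MIN_TOTAL:
        logger.warning("permutation_fdr: only %d samples; calls are unreliable",
                       arr.shape[1])
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_perm):
        shuffled = rng.permuted(arr, axis=1)
        rel = pairwise_relations(shuffled, sthr=sthr, pthr=pthr, min_total=min_total)
        fracs.append(_nonnone_pair_fraction(rel))
    return float(np.mean(fracs))
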