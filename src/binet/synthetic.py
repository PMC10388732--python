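"""Synthetic expression data with planted Boolean structure.

The default blueprint emulates a pooled macrophage polarization cohort:
three gene clusters (named 13, 14 and 3 after their roles: 13 = reactive
arm, 14 -> 3 = tolerant arm) whose latent activities across three sample
states realize the planted relation plan

    13 OPPOSITE 14,  14 LOW_LOW 3,  13 HIGH_LOW 3  (implied transitively)

M1-like samples are 13-high/14-low/3-low, M2-like samples the reverse
(13-low/14-high/3-high) and M0-like samples the intermediate
13-low/14-high/3-low, which leaves exactly the planned quadrants empty.
A labelled subset (M0/M1/M2) mirrors a supervised training design; the
remaining samples are unlabelled but occupy the same latent states so the
relation plan is statistically callable at the default thresholds.
Everything is a pure function of the blueprint seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .implication import RelationType
from .stepminer import fit_step, DegenerateStepError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorBlueprint", "SyntheticDataset",
    "generate_polarized_matrix", "generate_single_cells",
    "generate_pseudobulk_panel", "generate_survival_cohort",
]

#: latent cluster activity (0 = low, 1 = high) per sample state
STATE_TEMPLATES = {
    "M1": {13: 1, 14: 0, 3: 0},
    "M2": {13: 0, 14: 1, 3: 1},
    "M0": {13: 0, 14: 1, 3: 0},
}


@dataclass
class GeneratorBlueprint:
    """Parameters of the planted-structure generator.

    Cluster sizes echo the reactive/tolerant signature proportions
    (48/90/47 genes); labelled class counts echo a supervised training
    cohort (M0 = 47, M1 = 13, M2 = 8); unlabelled samples fill the cohort
    to a network-worthy size with the same three latent states.
    """

    cluster_sizes: dict = field(default_factory=lambda: {13: 48, 14: 90, 3: 47})
    labeled_counts: dict = field(default_factory=lambda: {"M0": 47, "M1": 13, "M2": 8})
    unlabeled_counts: dict = field(default_factory=lambda: {"M0": 43, "M1": 43, "M2": 43})
    low_mean: float = 4.0
    high_mean: float = 8.0
    noise_sd: float = 0.25
    latent_jitter_sd: float = 0.05
    gene_offset_sd: float = 0.3
    background_genes: int = 30
    seed: int = 0

    @property
    def relation_plan(self) -> dict:
        """Planned inter-cluster relations implied by the state templates."""
        return {
            (13, 14): RelationType.OPPOSITE,
            (14, 3): RelationType.LOW_LOW,
            (13, 3): RelationType.HIGH_LOW,
        }

    def __post_init__(self) -> None:
        for st in list(self.labeled_counts) + list(self.unlabeled_counts):
            if st not in STATE_TEMPLATES:
                raise ValueError(f"unknown sample state {st!r}")
        if self.high_mean - self.low_mean < 3 * self.noise_sd:
            raise ValueError("state separation below 3 noise sd: relation "
                             "plan not realizable")


@dataclass
class SyntheticDataset:
    """A generated matrix with its ground truth."""

    matrix: ExpressionMatrix
    annotation: pd.Series              # labelled samples only
    gene_clusters: dict                # planted cluster id -> gene list
    latent: pd.DataFrame               # cluster x sample latent activity
    states: pd.Series                  # every sample's latent state
    blueprint: GeneratorBlueprint


def _gene_names(bp: GeneratorBlueprint) -> tuple[dict, list]:
    clusters = {cid: [f"C{cid}G{i + 1:03d}" for i in range(n)]
                for cid, n in bp.cluster_sizes.items()}
    background = [f"BG{i + 1:03d}" for i in range(bp.background_genes)]
    return clusters, background


def generate_polarized_matrix(bp: GeneratorBlueprint | None = None
                              ) -> SyntheticDataset:
    """Generate a bulk expression matrix with the planted relation plan.

    Expression of a cluster gene is ``low_mean + (high - low) * activity``
    plus a per-gene baseline offset and i.i.d. Gaussian noise; activity is
    the state template plus a small per-sample jitter. Background genes
    are pure i.i.d. noise around the mid-scale.
    """
    bp = bp or GeneratorBlueprint()
    rng = np.random.default_rng(bp.seed)
    clusters, background = _gene_names(bp)

    samples, states, labelled = [], [], {}
    for st, n in sorted(bp.labeled_counts.items()):
        for i in range(n):
            sid = f"{st}_{i + 1:03d}"
            samples.append(sid)
            states.append(st)
            labelled[sid] = st
    for st, n in sorted(bp.unlabeled_counts.items()):
        for i in range(n):
            samples.append(f"U{st}_{i + 1:03d}")
            states.append(st)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("blueprint defines no samples")

    span = bp.high_mean - bp.low_mean
    latent = {}
    rows, gene_ids, gene_cluster = [], [], {}
    for cid in bp.cluster_sizes:
        template = np.array([STATE_TEMPLATES[st][cid] for st in states], float)
        activity = template + rng.normal(0.0, bp.latent_jitter_sd, n_samples)
        latent[cid] = activity
        for g in clusters[cid]:
            offset = rng.normal(0.0, bp.gene_offset_sd)
            rows.append(bp.low_mean + offset + span * activity
                        + rng.normal(0.0, bp.noise_sd, n_samples))
            gene_ids.append(g)
            gene_cluster[g] = cid
    mid = (bp.low_mean + bp.high_mean) / 2.0
    for g in background:
        rows.append(rng.normal(mid, 1.0, n_samples))
        gene_ids.append(g)

    matrix = ExpressionMatrix(pd.DataFrame(np.vstack(rows), index=gene_ids,
                                           columns=samples))
    return SyntheticDataset(
        matrix=matrix,
        annotation=pd.Series(labelled, name="label"),
        gene_clusters={cid: list(clusters[cid]) for cid in clusters},
        latent=pd.DataFrame(latent, index=samples).T,
        states=pd.Series(states, index=samples, name="state"),
        blueprint=bp,
    )


def generate_single_cells(bp: GeneratorBlueprint | None = None,
                          n_cells_per_class: dict | None = None,
                          dropout_rate: float = 0.0,
                          background_expr: float = 0.3) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate a log-scale single-cell matrix with planted polarization.

    Macrophage classes (M0/M1/M2) follow the bulk state templates; the
    extra ``BG`` class models non-macrophage background cells that barely
    express the signature genes (log level ``background_expr``). Entries
    are zeroed with probability ``dropout_rate``. Deterministic given the
    blueprint seed.
    """
    bp = bp or GeneratorBlueprint()
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    n_cells_per_class = n_cells_per_class or {"M0": 200, "M1": 200, "M2": 200}
    rng = np.random.default_rng(bp.seed + 1)
    clusters, background = _gene_names(bp)
    span = bp.high_mean - bp.low_mean
    mid = (bp.low_mean + bp.high_mean) / 2.0

    cells, labels = [], []
    for cls, n in sorted(n_cells_per_class.items()):
        if n == 0:
            logger.warning("generate_single_cells: class %r has 0 cells", cls)
        for i in range(n):
            cells.append(f"{cls}c{i + 1:04d}")
            labels.append(cls)
    if not cells:
        raise ValueError("no cells requested")

    gene_ids, rows = [], []
    for cid, genes in clusters.items():
        means = np.array([
            background_expr if cls == "BG"
            else bp.low_mean + span * STATE_TEMPLATES[cls][cid]
            for cls in labels
        ])
        for g in genes:
            rows.append(np.maximum(means + rng.normal(0.0, bp.noise_sd, len(cells)), 0.0))
            gene_ids.append(g)
    for g in background:
        rows.append(np.maximum(rng.normal(mid, 1.0, len(cells)), 0.0))
        gene_ids.append(g)
    arr = np.vstack(rows)
    if dropout_rate > 0:
        arr = arr * (rng.random(arr.shape) >= dropout_rate)
    matrix = ExpressionMatrix(pd.DataFrame(arr, index=gene_ids, columns=cells))
    return matrix, pd.Series(labels, index=cells, name="label")


def generate_pseudobulk_panel(cell_matrix: ExpressionMatrix, cell_labels: pd.Series,
                              compositions: dict, n_cells: int = 100,
                              seed: int = 0,
                              background_label: str = "BG") -> ExpressionMatrix:
    """Build a panel of pseudobulk samples on the count scale.

    Cell log-expression is unlogged to counts (2^x - 1), averaged over the
    sampled mixture, and re-logged (log2(mean + 1)) — the standard
    pseudobulk route, whose log compression is what lets partial mixtures
    resemble their dominant constituents. ``compositions`` maps sample
    name -> {label: fraction}; the remainder of each mixture comes from
    ``background_label``.
    """
    from .singlecell import make_pseudobulk

    counts = ExpressionMatrix(np.exp2(cell_matrix.data) - 1.0)
    cols = {}
    for i, (name, comp) in enumerate(sorted(compositions.items())):
        mean_counts = make_pseudobulk(counts, cell_labels, comp, n_cells,
                                      seed=seed + i,
                                      background_label=background_label)
        cols[name] = np.log2(mean_counts.to_numpy() + 1.0)
    return ExpressionMatrix(pd.DataFrame(cols, index=cell_matrix.gene_ids))


def generate_survival_cohort(scores, hazard_ratio: float, n: int | None = None,
                             seed: int = 0, base_rate: float = 0.1,
                             censor_max: float = 30.0) -> pd.DataFrame:
    """Exponential survival times tied to a score split.

    Samples with scores above the StepMiner threshold of the score
    distribution have their event rate multiplied by ``hazard_ratio``;
    censoring is independent Uniform(0, ``censor_max``). ``censor_max``
    of 0 censors everything (all events 0). Deterministic given ``seed``.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if hasattr(scores, "score"):
        vals = np.asarray(scores.score, dtype=float)
        ids = list(scores.sample_ids)
        thr = scores.threshold
    else:
        vals = np.asarray(scores, dtype=float)
        ids = [f"S{i + 1:04d}" for i in range(vals.size)]
        try:
            thr = fit_step(vals).threshold
        except (DegenerateStepError, ValueError):
            thr = float(np.median(vals))
    if n is not None:
        vals, ids = vals[:n], ids[:n]
    rng = np.random.default_rng(seed)
    rate = base_rate * np.where(vals > thr, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, censor_max, vals.size) if censor_max > 0 \
        else np.zeros(vals.size)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    if event.sum() == 0:
        logger.warning("generate_survival_cohort: every sample is censored")
    return pd.DataFrame({"sample": ids, "time": time, "event": event})
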