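"""Reading and writing expression matrices, annotations, gene sets and
survival tables.

The central container is :class:`ExpressionMatrix`, a thin wrapper around a
genes x samples :class:`pandas.DataFrame` of log-scale expression values.
Gene identifiers are upper-cased on construction so that human and mouse
symbol conventions (TNF vs Tnf) unify; duplicate gene rows are collapsed by
keeping the most variable row, the standard probe-set reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "read_expression_matrix",
    "read_annotation",
    "read_gene_set",
    "read_survival",
    "read_ortholog_map",
    "map_orthologs",
    "transform_tpm",
    "transform_log2_tpm1",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by gene ID, columns by sample ID. NaN marks missing
        values; infinities are rejected.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("empty expression matrix")
        df = df.astype(float)
        df.index = df.index.astype(str).str.upper()
        if df.index.has_duplicates:
            df = _collapse_duplicates(df)
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        if np.isinf(df.to_numpy()).any():
            raise ValueError("expression matrix contains infinite values")
        self.data = df

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.data.index if g in set(genes)]
        return ExpressionMatrix(self.data.loc[keep].copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)].copy())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "Gene"
        out.to_csv(path, sep="\t", float_format="%.10g")


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the most variable row among duplicated gene IDs."""
    var = df.var(axis=1, ddof=0).fillna(-np.inf)
    order = np.argsort(-var.to_numpy(), kind="stable")
    dedup = df.iloc[order][~df.index[order].duplicated()]
    n_dropped = df.shape[0] - dedup.shape[0]
    logger.warning("collapsed %d duplicate gene rows (kept max-variance row)", n_dropped)
    # restore first-occurrence order
    first = df.index[~df.index.duplicated()]
    return dedup.loc[first]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (upper-cased)."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m).upper() for m in self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))


# -- readers -------------------------------------------------------------

def read_expression_matrix(path: str | Path, format: str = "tsv",
                           genes_path: str | Path | None = None,
                           cells_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix.

    ``tsv``: header row of sample IDs, first column gene IDs.
    ``mtx-triplet``: matrix-market triplet file plus sidecar one-per-line
    gene and cell/sample ID lists (``genes_path``, ``cells_path``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv_matrix(path)
    if format == "mtx-triplet":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx-triplet input needs genes_path and cells_path sidecars")
        from scipy.io import mmread

        mat = mmread(str(path))
        genes = [l.strip() for l in Path(genes_path).read_text().splitlines() if l.strip()]
        cells = [l.strip() for l in Path(cells_path).read_text().splitlines() if l.strip()]
        arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if arr.shape != (len(genes), len(cells)):
            raise ParseError(
                f"{path}: matrix shape {arr.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)")
        return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=cells))
    raise ValueError(f"unknown format {format!r}")


def _read_tsv_matrix(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if len(cols) < 2:
        raise ParseError(f"{path}:1: header must contain at least one sample column")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        # locate the first bad cell for a precise message
        for j, col in enumerate(df.columns):
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = conv.isna() & df[col].notna() & (df[col].str.strip().str.upper() != "NA")
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: non-numeric value {df[col].iloc[i]!r} at "
                    f"gene row {df.index[i]!r} (row {i + 2}), column {col!r}") from None
        raise
    return ExpressionMatrix(values)


def read_annotation(path: str | Path) -> pd.Series:
    """Two-column TSV sample_id -> label; returns a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: annotation needs two columns (sample, label)")
    first = df.iloc[0]
    if first.iloc[0].lower() in {"sample", "sample_id", "sampleid"}:
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="label")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Gene set file: one gene ID per line, '#' comments allowed."""
    path = Path(path)
    members = [l.strip() for l in path.read_text().splitlines()
               if l.strip() and not l.startswith("#")]
    return GeneSet(name or path.stem, frozenset(members))


def read_survival(path: str | Path) -> pd.DataFrame:
    """Three-column TSV: sample, time, event (0/1)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: survival table needs columns sample, time, event")
    if not df.iloc[0, 1].replace(".", "", 1).replace("-", "", 1).isdigit():
        df = df.iloc[1:]
    out = pd.DataFrame({
        "sample": df.iloc[:, 0].to_numpy(),
        "time": pd.to_numeric(df.iloc[:, 1]).to_numpy(),
        "event": pd.to_numeric(df.iloc[:, 2]).astype(int).to_numpy(),
    })
    if (out["time"] < 0).any() or not np.isfinite(out["time"]).all():
        raise ValueError("survival times must be finite and nonnegative")
    if not out["event"].isin([0, 1]).all():
        raise ValueError("events must be 0/1")
    return out


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog map needs two columns (source, target)")
    return df.iloc[:, :2].rename(columns={0: "source", 1: "target"})


# -- transforms ----------------------------------------------------------

def transform_tpm(tpm):
    """Log-scale transform of TPM values: log2(TPM) above 1, TPM - 1 below.

    Continuous at 1 (both branches give 0) and monotone on [0, inf).
    """
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be nonnegative")
    out = np.where(arr > 1, np.log2(np.maximum(arr, 1e-300)), arr - 1.0)
    return out if out.ndim else float(out)


def transform_log2_tpm1(tpm):
    """Alternative transform log2(TPM + 1), used by some platforms."""
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be nonnegative")
    out = np.log2(arr + 1.0)
    return out if out.ndim else float(out)


def map_orthologs(matrix: ExpressionMatrix, mapping: pd.DataFrame | Mapping[str, str]) -> ExpressionMatrix:
    """Rename genes through a source -> target ortholog table.

    Unmapped genes are dropped (count logged); one-to-many mappings keep the
    first listed target.
    """
    if isinstance(mapping, Mapping):
        pairs = [(str(k).upper(), str(v).upper()) for k, v in mapping.items()]
    else:
        if mapping.shape[0] == 0:
            raise ValueError("empty ortholog mapping")
        pairs = [(str(s).upper(), str(t).upper())
                 for s, t in zip(mapping.iloc[:, 0], mapping.iloc[:, 1])]
    lut: dict[str, str] = {}
    for s, t in pairs:
        if s in lut:
            if lut[s] != t:
                logger.warning("one-to-many mapping for %s: keeping %s", s, lut[s])
            continue
        lut[s] = t
    if not lut:
        raise ValueError("empty ortholog mapping")
    keep = [g for g in matrix.gene_ids if g in lut]
    dropped = matrix.shape[0] - len(keep)
    if dropped:
        logger.info("map_orthologs: dropped %d unmapped genes", dropped)
    if not keep:
        raise ValueError("no genes remain after ortholog mapping")
    df = matrix.data.loc[keep].copy()
    df.index = [lut[g] for g in keep]
    return ExpressionMatrix(df)
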