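"""Cell-level quality control and normalization/scaling.

QC removes cells with fewer than ``min_genes`` or more than ``max_genes``
detected genes and cells whose mitochondrial fraction exceeds
``max_mito_fraction`` (all comparisons strict on the violating side, so
cells sitting exactly on a threshold are retained). Normalization is
per-cell depth normalization to a fixed target sum followed by log(1+x).
Scaling is a per-gene z-score whose statistics are fit on a stated
population and can be re-applied to new cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._matrix import LabeledExpressionMatrix

__all__ = [
    "QCThresholds",
    "ScalingStats",
    "qc_filter",
    "compute_mito_fraction",
    "lognormalize",
    "fit_scaling",
    "apply_scaling",
    "invert_scaling",
]


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0 <= self.min_genes < self.max_genes:
            raise ValueError("need 0 <= min_genes < max_genes")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in (0, 1]")


@dataclass
class ScalingStats:
    """Per-gene mean/sd for z-scoring, tied to the population they came from."""

    genes: pd.Index
    mean: np.ndarray
    sd: np.ndarray
    source_population: str = ""

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.genes) == len(self.mean) == len(self.sd)):
            raise ValueError("genes, mean and sd must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of sd == 0 genes."""
        return self.sd == 0

    def subset(self, genes) -> "ScalingStats":
        genes = pd.Index(genes)
        missing = genes.difference(self.genes)
        if len(missing):
            raise KeyError(f"genes absent from scaling stats: {list(missing)}")
        idx = self.genes.get_indexer(genes)
        return ScalingStats(genes, self.mean[idx], self.sd[idx],
                            self.source_population)


def compute_mito_fraction(matrix: LabeledExpressionMatrix,
                          mito_prefix: str = "MT-") -> np.ndarray:
    """Fraction of per-cell counts coming from genes with a name prefix."""
    is_mito = matrix.gene_names.str.upper().str.startswith(mito_prefix.upper())
    totals = matrix.values.sum(axis=0)
    mito = matrix.values[np.asarray(is_mito), :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    return frac


def qc_filter(
    matrix: LabeledExpressionMatrix,
    thresholds: QCThresholds = QCThresholds(),
    mito_prefix: str = "MT-",
):
    """Remove cells violating any QC rule.

    Returns ``(filtered_matrix, removed)`` where ``removed`` is a DataFrame
    with columns ``cell_id`` and ``reason`` (semicolon-joined when a cell
    violates several rules).
    """
    if matrix.n_cells == 0:
        raise ValueError("qc_filter: matrix has no cells")
    detected = matrix.genes_detected
    mito = matrix.mito_fraction
    if mito is None:
        mito = compute_mito_fraction(matrix, mito_prefix)

    low = detected < thresholds.min_genes
    high = detected > thresholds.max_genes
    himito = mito > thresholds.max_mito_fraction
    bad = low | high | himito

    reasons = []
    for i in np.flatnonzero(bad):
        r = []
        if low[i]:
            r.append("low_genes")
        if high[i]:
            r.append("high_genes")
        if himito[i]:
            r.append("high_mito")
        reasons.append(";".join(r))
    removed = pd.DataFrame({
        "cell_id": matrix.cell_ids[bad],
        "reason": reasons,
    })
    if bad.all():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    kept = matrix.subset_cells(~bad)
    if kept.mito_fraction is None:
        kept.mito_fraction = mito[~bad]
    return kept, removed


def lognormalize(matrix: LabeledExpressionMatrix,
                 target_sum: float = 1e4) -> LabeledExpressionMatrix:
    """Depth-normalize each cell to ``target_sum`` total, then log(1+x)."""
    if matrix.normalized:
        raise ValueError("matrix is already flagged normalized")
    totals = matrix.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        names = list(matrix.cell_ids[zero][:5])
        raise ValueError(f"cells with zero total counts: {names}")
    values = np.log1p(matrix.values * (target_sum / totals))
    return LabeledExpressionMatrix(
        values=values,
        gene_names=matrix.gene_names,
        cell_ids=matrix.cell_ids,
        labels=matrix.labels,
        genes_detected=matrix.genes_detected,
        mito_fraction=matrix.mito_fraction,
        normalized=True,
    )


def fit_scaling(matrix: LabeledExpressionMatrix,
                source_population: str = "train") -> ScalingStats:
    """Per-gene mean and (population, ddof=0) standard deviation."""
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1)
    return ScalingStats(matrix.gene_names, mean, sd, source_population)


def apply_scaling(matrix: LabeledExpressionMatrix,
                  stats: ScalingStats) -> LabeledExpressionMatrix:
    """Z-score each gene of ``matrix`` using ``stats``.

    Genes with sd == 0 in the stats are mapped to all-zero rows with a
    warning. Genes named in the stats but absent from the matrix raise.
    """
    stats = stats.subset(stats.genes)  # validated copy
    missing = stats.genes.difference(matrix.gene_names)
    if len(missing):
        raise KeyError(f"genes in scaling stats missing from matrix: {list(missing)}")
    sub = matrix.subset_genes(stats.genes)
    sd = stats.sd.copy()
    if stats.degenerate.any():
        warnings.warn(
            f"{int(stats.degenerate.sum())} gene(s) have sd == 0; scaled to 0",
            stacklevel=2,
        )
        sd[stats.degenerate] = 1.0
    values = (sub.values - stats.mean[:, None]) / sd[:, None]
    values[stats.degenerate, :] = 0.0
    return LabeledExpressionMatrix(
        values=values,
        gene_names=stats.genes,
        cell_ids=sub.cell_ids,
        labels=sub.labels,
        genes_detected=sub.genes_detected,
        mito_fraction=sub.mito_fraction,
        normalized=True,
    )


def invert_scaling(matrix: LabeledExpressionMatrix,
                   stats: ScalingStats) -> LabeledExpressionMatrix:
    """Undo :func:`apply_scaling` (degenerate genes recover their mean)."""
    sub = matrix.subset_genes(stats.genes)
    values = sub.values * np.where(stats.degenerate, 1.0, stats.sd)[:, None] \
        + stats.mean[:, None]
    out = sub.copy()
    out.values = values
    return out
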