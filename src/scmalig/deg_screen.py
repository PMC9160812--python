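"""Differential expression screen between malignant and normal cells.

Per gene: a two-sided Wilcoxon/Mann-Whitney rank-sum p-value on normalized
expression, a pseudocounted log2 fold change of class means, and
Benjamini-Hochberg FDR adjustment; records are then filtered on
``fdr < fdr_max`` (strict) and ``|log2fc| >= min_abs_log2fc`` (inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._matrix import LabeledExpressionMatrix

__all__ = [
    "wilcoxon_per_gene",
    "log2_fold_change",
    "bh_adjust",
    "run_deg",
    "deg_filter",
]

DEG_COLUMNS = ["gene", "mean_malignant", "mean_normal", "log2fc",
               "p_value", "fdr", "direction"]


def wilcoxon_per_gene(matrix: LabeledExpressionMatrix,
                      exact_limit: int = 25) -> pd.DataFrame:
    """Two-sided Mann-Whitney p-value per gene (malignant vs normal).

    Uses midranks for ties and the tie-corrected normal approximation for
    large samples; below ``exact_limit`` cells in the smaller class the
    exact null distribution is used where scipy supports it. A gene whose
    values are identical across all cells gets p = 1.
    """
    mal = matrix.is_malignant
    n1, n0 = int(mal.sum()), int((~mal).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need >= 2 cells per class; got {n1} malignant, {n0} normal")
    X1, X0 = matrix.values[:, mal], matrix.values[:, ~mal]

    if min(n1, n0) <= exact_limit:
        pvals = np.empty(matrix.n_genes)
        for i in range(matrix.n_genes):
            pvals[i] = stats.mannwhitneyu(
                X1[i], X0[i], alternative="two-sided", method="auto"
            ).pvalue
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            pvals = stats.mannwhitneyu(
                X1, X0, alternative="two-sided", method="asymptotic", axis=1
            ).pvalue
    constant = np.ptp(matrix.values, axis=1) == 0
    pvals = np.where(constant | ~np.isfinite(pvals), 1.0, pvals)
    return pd.DataFrame({"gene": matrix.gene_names, "p_value": pvals})


def log2_fold_change(matrix: LabeledExpressionMatrix,
                     pseudocount: float = 1.0,
                     convention: str = "simple") -> pd.DataFrame:
    """Per-gene log2 ratio of pseudocounted class means.

    ``convention="simple"`` takes class means of the values as given;
    ``convention="seurat"`` takes means of ``expm1(values)`` first, i.e.
    the linear-scale convention used on log1p-normalized data.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if convention not in ("simple", "seurat"):
        raise ValueError("convention must be 'simple' or 'seurat'")
    mal = matrix.is_malignant
    vals = np.expm1(matrix.values) if convention == "seurat" else matrix.values
    mean_mal = vals[:, mal].mean(axis=1)
    mean_norm = vals[:, ~mal].mean(axis=1)
    log2fc = np.log2((mean_mal + pseudocount) / (mean_norm + pseudocount))
    return pd.DataFrame({
        "gene": matrix.gene_names,
        "mean_malignant": mean_mal,
        "mean_normal": mean_norm,
        "log2fc": log2fc,
    })


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_deg(matrix: LabeledExpressionMatrix,
            pseudocount: float = 1.0,
            convention: str = "simple",
            exact_limit: int = 25) -> pd.DataFrame:
    """Full per-gene DE table: means, log2fc, p, BH FDR and direction."""
    pv = wilcoxon_per_gene(matrix, exact_limit=exact_limit)
    fc = log2_fold_change(matrix, pseudocount=pseudocount, convention=convention)
    out = fc.merge(pv, on="gene")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out[DEG_COLUMNS]


def deg_filter(records: pd.DataFrame,
               fdr_max: float = 0.01,
               min_abs_log2fc: float = 0.5) -> pd.DataFrame:
    """Keep records with fdr < fdr_max (strict) and |log2fc| >= min (inclusive)."""
    keep = (records["fdr"] < fdr_max) & (records["log2fc"].abs() >= min_abs_log2fc)
    return records.loc[keep].reset_index(drop=True)
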