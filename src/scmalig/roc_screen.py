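"""Per-gene ROC analysis: rank-based AUC, Youden-optimal cut-point, screening.

AUC is computed with malignant as the positive class and expression as the
score, via midranks (ties contribute 1/2), so it equals the Mann-Whitney
U statistic divided by ``n_pos * n_neg``. Screening retains genes whose
oriented AUC ``max(auc, 1 - auc)`` strictly exceeds the threshold, so
down-regulated discriminators are kept alongside up-regulated ones.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._matrix import MALIGNANT, LabeledExpressionMatrix

__all__ = ["gene_auc", "youden_cutpoint", "roc_table", "roc_screen"]

ROC_COLUMNS = ["gene", "auc", "auc_oriented", "direction",
               "sensitivity", "specificity", "threshold"]


def _as_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    if labels.dtype.kind in "iu":
        return labels.astype(bool)
    return labels == MALIGNANT


def gene_auc(scores, labels) -> float:
    """Rank-based ROC AUC of ``scores`` for the positive class in ``labels``.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _as_mask(labels)
    n_pos = int(pos.sum())
    n_neg = int(len(scores) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_cutpoint(scores, labels):
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct scores plus +/-inf;
    a cell is called positive when its score >= threshold. Ties in J are
    broken toward higher sensitivity, then lower threshold. Constant
    scores have no defined threshold: returns ``(nan, 1.0, 0.0)`` (the
    all-positive rule) with a warning.

    Returns ``(threshold, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    pos = _as_mask(labels)
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("both classes must be non-empty")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        warnings.warn("constant scores: Youden threshold undefined", stacklevel=2)
        return (float("nan"), 1.0, 0.0)
    thr = np.concatenate(([-np.inf], (uniq[1:] + uniq[:-1]) / 2.0, [np.inf]))
    pos_sorted = np.sort(scores[pos])
    neg_sorted = np.sort(scores[~pos])
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)
    # #pos >= t and #neg < t per candidate threshold
    sens = (n_pos - np.searchsorted(pos_sorted, thr, side="left")) / n_pos
    spec = np.searchsorted(neg_sorted, thr, side="left") / n_neg
    j = sens + spec - 1.0
    best = np.lexsort((thr, -sens, -j))[0]
    return (float(thr[best]), float(sens[best]), float(spec[best]))


def roc_table(matrix: LabeledExpressionMatrix, genes=None) -> pd.DataFrame:
    """Per-gene ROC summary (one row per gene, structure of a marker table).

    ``auc`` uses raw expression as the score; ``auc_oriented`` is
    ``max(auc, 1 - auc)`` and ``direction`` records which orientation won.
    Sensitivity/specificity come from the Youden cut-point on the oriented
    score (expression for up genes, negated expression for down genes);
    ``threshold`` is on that oriented scale.
    """
    if genes is None:
        genes = matrix.gene_names
    genes = pd.Index(genes)
    sub = matrix.subset_genes(genes)
    labels = sub.is_malignant
    rows = []
    for i, gene in enumerate(genes):
        scores = sub.values[i, :]
        auc = gene_auc(scores, labels)
        direction = "up" if auc >= 0.5 else "down"
        oriented_scores = scores if auc >= 0.5 else -scores
        thr, sens, spec = youden_cutpoint(oriented_scores, labels)
        rows.append((gene, auc, max(auc, 1.0 - auc), direction, sens, spec, thr))
    return pd.DataFrame(rows, columns=ROC_COLUMNS)


def roc_screen(matrix: LabeledExpressionMatrix, deg_genes,
               auc_min: float = 0.60) -> pd.DataFrame:
    """Retain genes whose oriented AUC strictly exceeds ``auc_min``."""
    table = roc_table(matrix, deg_genes)
    return table.loc[table["auc_oriented"] > auc_min].reset_index(drop=True)
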