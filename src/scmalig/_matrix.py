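"""Labeled gene-by-cell expression container shared by all pipeline stages.

Orientation is fixed: genes in rows, cells in columns, at every interface.
Labels are per-cell strings, either ``"malignant"`` or ``"normal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MALIGNANT = "malignant"
NORMAL = "normal"
VALID_LABELS = frozenset({MALIGNANT, NORMAL})


@dataclass
class LabeledExpressionMatrix:
    """Gene-by-cell expression values plus per-cell labels and QC metadata.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_genes, n_cells)``. Non-negative when
        ``normalized`` is False (raw); may be any finite real after scaling.
    gene_names, cell_ids
        Unique identifiers for rows and columns.
    labels
        Per-cell label, ``"malignant"`` or ``"normal"``.
    genes_detected
        Per-cell count of genes with value > 0; computed from ``values``
        when not supplied.
    mito_fraction
        Per-cell mitochondrial fraction in [0, 1]; optional (QC computes it
        from gene-name prefixes when absent).
    normalized
        False for raw counts-like values, True after normalization/scaling.
    """

    values: np.ndarray
    gene_names: pd.Index
    cell_ids: pd.Index
    labels: np.ndarray
    genes_detected: np.ndarray | None = None
    mito_fraction: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes-by-cells array")
        self.gene_names = pd.Index(self.gene_names)
        self.cell_ids = pd.Index(self.cell_ids)
        self.labels = np.asarray(self.labels, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_names) != n_genes:
            raise ValueError("gene_names length does not match row count")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match column count")
        if len(self.labels) != n_cells:
            raise ValueError("number of labels must equal number of cells")
        if not self.gene_names.is_unique:
            raise ValueError("gene_names must be unique")
        if not self.cell_ids.is_unique:
            raise ValueError("cell_ids must be unique")
        bad = set(self.labels) - VALID_LABELS
        if bad:
            raise ValueError(f"invalid labels: {sorted(bad)!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not self.normalized and np.any(self.values < 0):
            raise ValueError("raw values must be non-negative")
        if self.genes_detected is None:
            self.genes_detected = (self.values > 0).sum(axis=0).astype(int)
        else:
            self.genes_detected = np.asarray(self.genes_detected, dtype=int)
            if len(self.genes_detected) != n_cells:
                raise ValueError("genes_detected length must equal cell count")
        if self.mito_fraction is not None:
            self.mito_fraction = np.asarray(self.mito_fraction, dtype=float)
            if len(self.mito_fraction) != n_cells:
                raise ValueError("mito_fraction length must equal cell count")
            if np.any((self.mito_fraction < 0) | (self.mito_fraction > 1)):
                raise ValueError("mito_fraction must lie in [0, 1]")

    # -- convenience -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def is_malignant(self) -> np.ndarray:
        """Boolean per-cell mask, True for malignant cells."""
        return self.labels == MALIGNANT

    @property
    def y(self) -> np.ndarray:
        """0/1 integer labels (1 = malignant)."""
        return self.is_malignant.astype(int)

    def copy(self) -> "LabeledExpressionMatrix":
        return LabeledExpressionMatrix(
            values=self.values.copy(),
            gene_names=self.gene_names.copy(),
            cell_ids=self.cell_ids.copy(),
            labels=self.labels.copy(),
            genes_detected=self.genes_detected.copy(),
            mito_fraction=None if self.mito_fraction is None else self.mito_fraction.copy(),
            normalized=self.normalized,
        )

    def subset_cells(self, mask: np.ndarray) -> "LabeledExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise ValueError("subset_cells expects a boolean mask")
        return LabeledExpressionMatrix(
            values=self.values[:, mask],
            gene_names=self.gene_names,
            cell_ids=self.cell_ids[mask],
            labels=self.labels[mask],
            genes_detected=self.genes_detected[mask],
            mito_fraction=None if self.mito_fraction is None else self.mito_fraction[mask],
            normalized=self.normalized,
        )

    def subset_genes(self, genes) -> "LabeledExpressionMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.gene_names)
        if len(missing):
            raise KeyError(f"genes absent from matrix: {list(missing)}")
        idx = self.gene_names.get_indexer(genes)
        return LabeledExpressionMatrix(
            values=self.values[idx, :],
            gene_names=genes,
            cell_ids=self.cell_ids,
            labels=self.labels,
            genes_detected=self.genes_detected,
            mito_fraction=self.mito_fraction,
            normalized=self.normalized,
        )

    def gene_values(self, gene: str) -> np.ndarray:
        i = self.gene_names.get_loc(gene)
        return self.values[i, :]
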