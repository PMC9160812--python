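"""Readers and writers for the 10x-style Matrix Market triplet and dense TSV.

A matrix directory holds ``matrix.mtx`` (genes in rows, cells in columns),
``features.tsv``, ``barcodes.tsv``, ``labels.tsv`` (cell_id<TAB>label),
``cell_qc.tsv`` (genes_detected, mito_fraction) and ``matrix_info.json``
(the normalized flag). Dense TSV has genes in rows and cells in columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from ._matrix import LabeledExpressionMatrix

__all__ = [
    "write_matrix_dir",
    "read_matrix_dir",
    "write_dense_tsv",
    "read_dense_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
]


def write_labels_tsv(matrix: LabeledExpressionMatrix, path) -> None:
    pd.DataFrame({"cell_id": matrix.cell_ids, "label": matrix.labels}) \
        .to_csv(path, sep="\t", index=False, header=False)


def read_labels_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"],
                     dtype=str)
    return df.set_index("cell_id")["label"]


def write_matrix_dir(matrix: LabeledExpressionMatrix, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csc_matrix(matrix.values))
    pd.Series(matrix.gene_names).to_csv(outdir / "features.tsv", sep="\t",
                                        index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    write_labels_tsv(matrix, outdir / "labels.tsv")
    qc = pd.DataFrame({
        "cell_id": matrix.cell_ids,
        "genes_detected": matrix.genes_detected,
    })
    if matrix.mito_fraction is not None:
        qc["mito_fraction"] = matrix.mito_fraction
    qc.to_csv(outdir / "cell_qc.tsv", sep="\t", index=False)
    with open(outdir / "matrix_info.json", "w") as fh:
        json.dump({"normalized": matrix.normalized, "orientation":
                   "genes_by_cells"}, fh)
        fh.write("\n")
    return outdir


def read_matrix_dir(indir, labels_path=None) -> LabeledExpressionMatrix:
    indir = Path(indir)
    values = np.asarray(spio.mmread(indir / "matrix.mtx").todense())
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    labels_file = Path(labels_path) if labels_path else indir / "labels.tsv"
    labels = read_labels_tsv(labels_file).reindex(barcodes).to_numpy()
    genes_detected = None
    mito = None
    qc_path = indir / "cell_qc.tsv"
    if qc_path.exists():
        qc = pd.read_csv(qc_path, sep="\t").set_index("cell_id") \
            .reindex(barcodes)
        genes_detected = qc["genes_detected"].to_numpy()
        if "mito_fraction" in qc:
            mito = qc["mito_fraction"].to_numpy()
    normalized = False
    info_path = indir / "matrix_info.json"
    if info_path.exists():
        with open(info_path) as fh:
            normalized = bool(json.load(fh).get("normalized", False))
    return LabeledExpressionMatrix(
        values=values,
        gene_names=pd.Index(genes),
        cell_ids=pd.Index(barcodes),
        labels=labels,
        genes_detected=genes_detected,
        mito_fraction=mito,
        normalized=normalized,
    )


def write_dense_tsv(matrix: LabeledExpressionMatrix, path) -> None:
    pd.DataFrame(matrix.values, index=matrix.gene_names,
                 columns=matrix.cell_ids).to_csv(path, sep="\t")


def read_dense_tsv(path, labels_path=None,
                   labels=None) -> LabeledExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if labels is None:
        if labels_path is None:
            raise ValueError("dense TSV input needs a labels file")
        labels = read_labels_tsv(labels_path).reindex(df.columns).to_numpy()
    return LabeledExpressionMatrix(
        values=df.to_numpy(),
        gene_names=pd.Index(df.index),
        cell_ids=pd.Index(df.columns),
        labels=labels,
    )
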