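"""End-to-end orchestration: QC -> normalize -> DEG -> ROC -> LASSO -> scMS.

`fit_pipeline` is the in-memory core; `run_pipeline` wraps it with input
loading (or synthetic generation), output files (marker-table-style TSVs,
model JSON, per-cell scores, metrics) and a deterministic run manifest.
The single global seed fans out to stage seeds through
``numpy.random.SeedSequence(seed).generate_state`` in a fixed order
(generator first, then cross-validation folds), so stages are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import annot_filter, deg_screen, io, lasso_select, qc_norm, \
    scms_model, synthgen
from .roc_screen import roc_screen
from ._matrix import LabeledExpressionMatrix

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "stage_seeds",
    "stratified_split",
    "fit_pipeline",
    "run_pipeline",
]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters for one run; serialized into the manifest."""

    # input: either a generator config or paths
    generator: synthgen.GeneratorConfig | None = None
    matrix_dir: str | None = None
    labels_path: str | None = None
    annotation_path: str | None = None  # None -> packaged fixture

    # QC / normalization
    min_genes: int = 200
    max_genes: int = 7000
    max_mito_fraction: float = 0.20
    mito_prefix: str = "MT-"
    target_sum: float = 1e4

    # DEG screen
    fdr_max: float = 0.01
    min_abs_log2fc: float = 0.5
    pseudocount: float = 1.0
    fc_convention: str = "seurat"

    # ROC screen
    auc_min: float = 0.60

    # LASSO selection
    n_folds: int = 10
    selection_rule: str = "cv_min"
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4

    # evaluation split
    holdout_fraction: float = 0.0

    seed: int = 0
    outdir: str = "scmalig_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = synthgen.GeneratorConfig.from_dict(d["generator"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    model: scms_model.ScoreModel
    deg_table: pd.DataFrame
    deg_passed: pd.DataFrame
    roc_table: pd.DataFrame
    path: lasso_select.PenalizedPath
    selection: lasso_select.SelectionResult
    removed_cells: pd.DataFrame
    scaling: qc_norm.ScalingStats
    metrics: dict
    funnel: dict
    normalized: LabeledExpressionMatrix


def stage_seeds(seed: int) -> dict:
    """Derive per-stage seeds (< 2**31) from the single global seed."""
    state = np.random.SeedSequence(seed).generate_state(2)
    return {"generator": int(state[0] % 2**31), "cv": int(state[1] % 2**31)}


def stratified_split(matrix: LabeledExpressionMatrix, test_fraction: float,
                     seed: int):
    """Label-stratified cell split; returns (train, test)."""
    idx = np.arange(matrix.n_cells)
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=matrix.labels)
    train_mask = np.zeros(matrix.n_cells, dtype=bool)
    train_mask[tr] = True
    return matrix.subset_cells(train_mask), matrix.subset_cells(~train_mask)


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def fit_pipeline(matrix: LabeledExpressionMatrix,
                 config: PipelineConfig | None = None,
                 annotation: dict | None = None) -> PipelineResult:
    """Run every training stage on ``matrix`` and return the fitted model.

    ``matrix`` is raw (counts-like) labeled expression; QC, normalization,
    both gene screens, cross-validated L1 selection, the final logistic
    fit, Youden cut-point choice and training-set evaluation all happen
    here. Holdout evaluation, file output and input loading live in
    :func:`run_pipeline`.
    """
    cfg = config or PipelineConfig()
    seeds = stage_seeds(cfg.seed)

    with _stage("qc"):
        thresholds = qc_norm.QCThresholds(cfg.min_genes, cfg.max_genes,
                                          cfg.max_mito_fraction)
        kept, removed = qc_norm.qc_filter(matrix, thresholds,
                                          mito_prefix=cfg.mito_prefix)
        if kept.n_cells == 0:
            raise ValueError("QC removed every cell")

    with _stage("normalize"):
        norm = kept if kept.normalized else qc_norm.lognormalize(
            kept, target_sum=cfg.target_sum)

    with _stage("deg"):
        deg_table = deg_screen.run_deg(norm, pseudocount=cfg.pseudocount,
                                       convention=cfg.fc_convention)
        deg_passed = deg_screen.deg_filter(deg_table, fdr_max=cfg.fdr_max,
                                           min_abs_log2fc=cfg.min_abs_log2fc)
        if len(deg_passed) == 0:
            raise ValueError("no genes passed the DEG screen")

    with _stage("roc"):
        roc = roc_screen(norm, deg_passed["gene"], auc_min=cfg.auc_min)
        if len(roc) == 0:
            raise ValueError("no genes passed the AUC screen")

    with _stage("annotate"):
        if annotation is None:
            annotation = annot_filter.load_annotation(cfg.annotation_path)
        roc = roc.merge(
            deg_passed[["gene", "log2fc"]].assign(
                abs_log2fc=lambda d: d["log2fc"].abs())[["gene", "abs_log2fc"]],
            on="gene", how="left")
        roc["secreted_or_membrane"] = [
            annotation[g].secreted_or_membrane if g in annotation else None
            for g in roc["gene"].str.upper()
        ]
        roc = roc.sort_values("auc_oriented", ascending=False,
                              kind="mergesort").reset_index(drop=True)
        roc.insert(0, "rank", np.arange(1, len(roc) + 1))

    with _stage("select"):
        scaling = qc_norm.fit_scaling(norm, source_population="training")
        candidates = pd.Index(roc["gene"])
        Xs = qc_norm.apply_scaling(norm.subset_genes(candidates),
                                   scaling.subset(candidates))
        path = lasso_select.cross_validate(
            Xs.values, norm.y, genes=candidates, n_folds=cfg.n_folds,
            seed=seeds["cv"], n_lambda=cfg.n_lambda,
            lambda_min_ratio=cfg.lambda_min_ratio)
        selection = lasso_select.select(path, cfg.selection_rule)
        if not selection.selected_genes:
            raise ValueError(
                f"selection rule {cfg.selection_rule!r} chose an empty model")

    with _stage("fit"):
        sel_genes = pd.Index(selection.selected_genes)
        Xsel = Xs.subset_genes(sel_genes)
        model = scms_model.fit_final_logistic(
            Xsel.values, norm.y, sel_genes,
            scaling=scaling.subset(sel_genes))

    with _stage("cutoff"):
        scored = scms_model.score(model, norm)
        model.cutoff = scms_model.choose_cutoff(scored["scms"].to_numpy(),
                                                norm.labels)

    with _stage("evaluate"):
        auc, sens, spec = scms_model.evaluate(model, norm)
        model.training_metrics = {"auc": auc, "sensitivity": sens,
                                  "specificity": spec}

    funnel = {
        "n_cells_input": matrix.n_cells,
        "n_cells_after_qc": kept.n_cells,
        "n_genes": matrix.n_genes,
        "n_deg": len(deg_passed),
        "n_auc_screened": len(roc),
        "n_selected": len(selection.selected_genes),
    }
    metrics = {
        "train_auc": auc,
        "train_sensitivity": sens,
        "train_specificity": spec,
        "cutoff": model.cutoff,
        "chosen_lambda": selection.chosen_lambda,
        "selected_genes": selection.selected_genes,
    }
    return PipelineResult(model, deg_table, deg_passed, roc, path, selection,
                          removed, scaling, metrics, funnel, norm)


def _load_input(cfg: PipelineConfig, seeds: dict) -> LabeledExpressionMatrix:
    if cfg.generator is not None:
        gen = dataclasses.replace(cfg.generator, seed=seeds["generator"])
        return synthgen.generate(gen)
    if cfg.matrix_dir is not None:
        return io.read_matrix_dir(cfg.matrix_dir, labels_path=cfg.labels_path)
    raise ValueError("config needs either a generator or a matrix_dir")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline per ``config`` and write a run directory.

    Outputs: ``removed_cells.tsv``, ``deg.tsv``, ``roc.tsv`` (AUC-ranked
    marker-table style), ``lasso_path.tsv``, ``coefficients.tsv``,
    ``model.json``, ``scores.tsv``, ``metrics.json`` and ``manifest.json``
    (config + seeds + stage gene counts). Outputs contain no timestamps so
    re-running from the manifest reproduces them byte-for-byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    with _stage("input"):
        matrix = _load_input(config, seeds)

    holdout = None
    if config.holdout_fraction > 0:
        with _stage("split"):
            matrix, holdout = stratified_split(matrix,
                                               config.holdout_fraction,
                                               seeds["cv"])

    try:
        res = fit_pipeline(matrix, config)
    finally:
        pass  # partial stage outputs are written below only on success

    res.removed_cells.to_csv(outdir / "removed_cells.tsv", sep="\t",
                             index=False)
    res.deg_table.to_csv(outdir / "deg.tsv", sep="\t", index=False)
    res.roc_table.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    res.path.to_frame().to_csv(outdir / "lasso_path.tsv", sep="\t",
                               index=False)
    pd.DataFrame(res.path.coefficients, index=res.path.genes,
                 columns=[f"{l:.6g}" for l in res.path.lambdas]) \
        .to_csv(outdir / "coefficients.tsv", sep="\t")
    res.model.save(outdir / "model.json")

    scored = scms_model.score(res.model, res.normalized)
    metrics = dict(res.metrics)
    if holdout is not None:
        with _stage("evaluate_holdout"):
            norm_holdout = qc_norm.lognormalize(holdout,
                                                target_sum=config.target_sum)
            auc, sens, spec = scms_model.evaluate(res.model, norm_holdout)
            metrics.update({"holdout_auc": auc, "holdout_sensitivity": sens,
                            "holdout_specificity": spec})
            scored = pd.concat(
                [scored, scms_model.score(res.model, norm_holdout)],
                ignore_index=True)
    scored.to_csv(outdir / "scores.tsv", sep="\t", index=False)

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "derived_seeds": seeds,
        "funnel": res.funnel,
        "outputs": sorted(p.name for p in outdir.iterdir()
                          if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
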