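"""The single-cell malignant score (scMS) model.

An unpenalized binomial logistic model over the selected genes' scaled
expression: ``x = b0 + sum_g beta_g * z_g`` and ``scMS = 1 / (1 + e^-x)``,
with a cell called malignant when ``scMS >= cutoff`` (inclusive). The
model carries the per-gene scaling statistics of its training population
so it is well-defined on new data, serializes to JSON, and a packaged
reference instance ships the published seven-gene coefficients, intercept
-4.7082 and cutoff 0.046. The reference instance has no scaling
statistics (none were published): a scaling population must be attached
before scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._matrix import MALIGNANT, NORMAL, LabeledExpressionMatrix
from .qc_norm import ScalingStats, apply_scaling, fit_scaling
from .roc_screen import gene_auc, youden_cutpoint

__all__ = [
    "ScoreModel",
    "PerfectSeparationError",
    "fit_final_logistic",
    "coefficient_standard_errors",
    "score",
    "choose_cutoff",
    "evaluate",
    "reference_model",
    "attach_scaling",
]

MODEL_FORMAT_VERSION = 1


class PerfectSeparationError(RuntimeError):
    """Raised when the logistic MLE diverges (classes perfectly separated)."""


@dataclass
class ScoreModel:
    intercept: float
    coefficients: dict  # gene -> coefficient, insertion-ordered
    scaling: ScalingStats | None = None
    cutoff: float | None = None
    training_metrics: dict | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.scaling is not None:
            if set(self.scaling.genes) != set(self.coefficients):
                raise ValueError(
                    "scaling gene set must equal coefficient gene set"
                )
        if self.cutoff is not None and not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")

    @property
    def genes(self) -> list:
        return list(self.coefficients)

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": MODEL_FORMAT_VERSION,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "scaling": None if self.scaling is None else {
                g: {"mean": float(m), "sd": float(s)}
                for g, m, s in zip(self.scaling.genes, self.scaling.mean,
                                   self.scaling.sd)
            },
            "scaling_source": None if self.scaling is None
            else self.scaling.source_population,
            "cutoff": self.cutoff,
            "training_metrics": self.training_metrics,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        scaling = None
        if d.get("scaling") is not None:
            genes = list(d["scaling"])
            scaling = ScalingStats(
                genes,
                [d["scaling"][g]["mean"] for g in genes],
                [d["scaling"][g]["sd"] for g in genes],
                d.get("scaling_source") or "",
            )
        return cls(
            intercept=float(d["intercept"]),
            coefficients={g: float(v) for g, v in d["coefficients"].items()},
            scaling=scaling,
            cutoff=d.get("cutoff"),
            training_metrics=d.get("training_metrics"),
            provenance=d.get("provenance", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _design(X: np.ndarray) -> np.ndarray:
    """Prepend an intercept column; X arrives genes-by-cells."""
    n = X.shape[1]
    return np.column_stack([np.ones(n), np.asarray(X, dtype=float).T])


def fit_final_logistic(X, y, genes, scaling: ScalingStats | None = None,
                       tol: float = 1e-10, max_iter: int = 100,
                       ridge: float = 0.0,
                       separation_limit: float = 30.0) -> ScoreModel:
    """Unpenalized ML binomial logistic fit by Newton/IRLS.

    ``X`` is scaled values, genes in rows, cells in columns; ``y`` is 0/1.
    Perfect separation (diverging coefficients or no convergence) raises
    :class:`PerfectSeparationError`; pass ``ridge > 0`` for a ridge
    fallback instead. The returned model has no cutoff yet.
    """
    genes = list(genes)
    A = _design(X)
    if A.shape[0] != len(np.asarray(y)):
        raise ValueError("X and y disagree on the number of cells")
    yv = np.asarray(y, dtype=float)
    beta = np.zeros(A.shape[1])
    converged = False
    for _ in range(max_iter):
        p = np.clip(expit(A @ beta), 1e-12, 1 - 1e-12)
        w = p * (1 - p)
        grad = A.T @ (yv - p)
        H = (A * w[:, None]).T @ A
        if ridge > 0:
            pen = np.full(A.shape[1], ridge)
            pen[0] = 0.0
            grad = grad - pen * beta
            H = H + np.diag(pen)
        step = np.linalg.solve(H + 1e-12 * np.eye(A.shape[1]), grad)
        beta = beta + step
        if np.max(np.abs(beta[1:]), initial=0.0) > separation_limit and ridge == 0:
            raise PerfectSeparationError(
                "coefficients diverging: classes may be perfectly separated "
                "(pass ridge > 0 for a penalized fallback)"
            )
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        raise PerfectSeparationError(
            "IRLS did not converge; classes may be perfectly separated "
            "(pass ridge > 0 for a penalized fallback)"
        )
    if scaling is not None:
        scaling = scaling.subset(pd.Index(genes))
    return ScoreModel(
        intercept=float(beta[0]),
        coefficients={g: float(b) for g, b in zip(genes, beta[1:])},
        scaling=scaling,
    )


def coefficient_standard_errors(X, y, model: ScoreModel) -> dict:
    """Asymptotic SEs from the inverse observed information at the fit.

    Returns ``{"(intercept)": se0, gene: se, ...}``.
    """
    A = _design(X)
    beta = np.concatenate([[model.intercept],
                           [model.coefficients[g] for g in model.genes]])
    p = np.clip(expit(A @ beta), 1e-12, 1 - 1e-12)
    H = (A * (p * (1 - p))[:, None]).T @ A
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return {"(intercept)": float(se[0]),
            **{g: float(s) for g, s in zip(model.genes, se[1:])}}


def score(model: ScoreModel, matrix: LabeledExpressionMatrix,
          assume_normalized: bool = False,
          impute_missing: bool = False) -> pd.DataFrame:
    """scMS per cell, plus the predicted label when the model has a cutoff.

    The model's own scaling statistics are applied to the matrix's
    normalized expression; genes absent from the matrix are an error
    unless ``impute_missing`` substitutes scaled zero (with a warning).
    """
    if model.scaling is None:
        raise ValueError(
            "model has no scaling statistics; attach a scaling population "
            "first (attach_scaling)"
        )
    if not matrix.normalized and not assume_normalized:
        raise ValueError(
            "matrix is not flagged normalized; lognormalize it first or pass "
            "assume_normalized=True"
        )
    genes = pd.Index(model.genes)
    present = genes.isin(matrix.gene_names)
    z = np.zeros((len(genes), matrix.n_cells))
    if not present.all():
        missing = list(genes[~present])
        if not impute_missing:
            raise KeyError(f"model genes missing from matrix: {missing}")
        warnings.warn(
            f"imputing scaled 0 for {len(missing)} missing model gene(s): "
            f"{missing}",
            stacklevel=2,
        )
    if present.any():
        sub_genes = genes[present]
        scaled = apply_scaling(matrix.subset_genes(sub_genes),
                               model.scaling.subset(sub_genes))
        z[np.flatnonzero(present), :] = scaled.values
    coef = np.array([model.coefficients[g] for g in genes])
    x = model.intercept + coef @ z
    scms = expit(x)
    out = pd.DataFrame({"cell_id": matrix.cell_ids, "scms": scms})
    if model.cutoff is not None:
        out["predicted_label"] = np.where(scms >= model.cutoff,
                                          MALIGNANT, NORMAL)
    return out


def choose_cutoff(scms, labels) -> float:
    """Youden-optimal scMS threshold (probability scale)."""
    thr, _, _ = youden_cutpoint(scms, labels)
    return float(thr)


def evaluate(model: ScoreModel, matrix: LabeledExpressionMatrix,
             assume_normalized: bool = False):
    """(auc, sensitivity, specificity) of the model on labeled cells.

    Sensitivity/specificity use the model cutoff with the inclusive
    ``scms >= cutoff`` rule.
    """
    if model.cutoff is None:
        raise ValueError("model has no cutoff; call choose_cutoff first")
    mal = matrix.is_malignant
    if mal.all() or not mal.any():
        raise ValueError("evaluation needs both classes present")
    scored = score(model, matrix, assume_normalized=assume_normalized)
    s = scored["scms"].to_numpy()
    auc = gene_auc(s, mal)
    sens = float(np.mean(s[mal] >= model.cutoff))
    spec = float(np.mean(s[~mal] < model.cutoff))
    return auc, sens, spec


# Published seven-gene model: intercept, per-gene coefficients and the
# optimal cut-point as printed; scaling statistics were not published, so
# the instance ships without them and scoring requires attach_scaling.
REFERENCE_INTERCEPT = -4.7082
REFERENCE_COEFFICIENTS = {
    "KRT18": 0.8449,
    "IRX2": 0.7221,
    "NAPSA": 1.2584,
    "SPINK13": 2.3251,
    "KRT7": 1.5488,
    "CAPN8": 0.4969,
    "GPRC5A": 0.6344,
}
REFERENCE_CUTOFF = 0.046


def reference_model() -> ScoreModel:
    """The packaged seven-gene scMS model with published parameters."""
    return ScoreModel(
        intercept=REFERENCE_INTERCEPT,
        coefficients=dict(REFERENCE_COEFFICIENTS),
        scaling=None,
        cutoff=REFERENCE_CUTOFF,
        provenance="seven-gene reference scMS model (published parameters; "
                   "scaling statistics must be supplied from the scoring "
                   "population)",
    )


def attach_scaling(model: ScoreModel, population) -> ScoreModel:
    """Return a copy of ``model`` with scaling fit on a normalized population.

    ``population`` is either a normalized :class:`LabeledExpressionMatrix`
    containing the model's genes, or a :class:`ScalingStats` covering them.
    """
    if isinstance(population, ScalingStats):
        stats = population.subset(pd.Index(model.genes))
    else:
        if not population.normalized:
            raise ValueError("scaling population must be normalized expression")
        stats = fit_scaling(population.subset_genes(pd.Index(model.genes)),
                            source_population="attached")
    return replace(model, scaling=stats)
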