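"""L1-penalized binomial logistic regression over a penalty path, with CV.

The objective, per observation, is

    (1/n) * sum_i [ -y_i * eta_i + log(1 + exp(eta_i)) ] + lambda * sum_j |beta_j|

with an unpenalized intercept. It is solved by cyclic coordinate descent
on the iteratively reweighted least-squares quadratic approximation with
soft-thresholding, warm-started along a decreasing lambda grid. A
sequential strong rule proposes the working feature set at each lambda and
a full KKT sweep over all features certifies the solution before it is
accepted. The per-observation loss scale makes lambda values comparable
across sample sizes.

Cross-validation uses stratified folds and held-out mean binomial
deviance; selection rules are the deviance minimum (``cv_min``), the
one-standard-error rule (``cv_1se``) and ``target_support(k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PenalizedPath",
    "SelectionResult",
    "lambda_max",
    "default_lambda_grid",
    "fit_l1_logistic_path",
    "cross_validate",
    "select",
    "binomial_deviance",
]

_WEIGHT_FLOOR = 1e-5
_PROB_CLIP = 1e-9


@dataclass
class PenalizedPath:
    """Coefficients and (optionally) CV deviance along a decreasing grid."""

    genes: pd.Index
    lambdas: np.ndarray                 # strictly decreasing, positive
    coefficients: np.ndarray            # (n_genes, n_lambda)
    intercepts: np.ndarray              # (n_lambda,)
    nonzero_counts: np.ndarray          # (n_lambda,)
    cv_mean_deviance: np.ndarray | None = None
    cv_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
        if np.any(self.lambdas < 0):
            raise ValueError("lambdas must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        d = {
            "lambda": self.lambdas,
            "nonzero": self.nonzero_counts,
            "intercept": self.intercepts,
        }
        if self.cv_mean_deviance is not None:
            d["cv_mean_deviance"] = self.cv_mean_deviance
            d["cv_se"] = self.cv_se
        return pd.DataFrame(d)


@dataclass
class SelectionResult:
    chosen_lambda: float
    rule: str
    selected_genes: list
    coefficients_at_choice: dict


def binomial_deviance(y, p) -> float:
    """-2 x mean Bernoulli log-likelihood."""
    p = np.clip(np.asarray(p, dtype=float), _PROB_CLIP, 1 - _PROB_CLIP)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def lambda_max(X, y) -> float:
    """Smallest penalty zeroing every coefficient (KKT boundary).

    ``X`` is observations-by-features here (internal convention).
    """
    n = len(y)
    return float(np.abs(X.T @ (y - y.mean())).max() / n)


def default_lambda_grid(lmax: float, n_lambda: int = 100,
                        min_ratio: float = 1e-4) -> np.ndarray:
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


@njit(cache=True)
def _cd_sweeps(Xf, work, w, r, beta, b0, xv, lam, n, tol, max_sweeps):
    """Cyclic soft-thresholding sweeps on the weighted quadratic problem.

    ``Xf`` is Fortran-ordered observations-by-features; ``r`` holds the
    working residual ``z - eta`` and is updated in place, as is ``beta``.
    Returns the updated intercept.
    """
    wsum = 0.0
    for i in range(n):
        wsum += w[i]
    for _ in range(max_sweeps):
        delta = 0.0
        for k in range(work.size):
            j = work[k]
            gj = 0.0
            for i in range(n):
                gj += w[i] * Xf[i, j] * r[i]
            gj = gj / n + xv[k] * beta[j]
            if gj > lam:
                bj = (gj - lam) / xv[k]
            elif gj < -lam:
                bj = (gj + lam) / xv[k]
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * Xf[i, j]
                beta[j] = bj
                if abs(d) > delta:
                    delta = abs(d)
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d0 = num / wsum
        if d0 != 0.0:
            b0 += d0
            for i in range(n):
                r[i] -= d0
            if abs(d0) > delta:
                delta = abs(d0)
        if delta < tol:
            break
    return b0


def _irls_cd(X, y, lam, beta, b0, work, tol, max_irls=80, max_sweeps=1000):
    """Solve one lambda restricted to the feature index array ``work``.

    Outer loop: IRLS quadratic approximation; inner loop: compiled cyclic
    coordinate descent with soft-thresholding. Mutates and returns
    ``(beta, b0)``; convergence when the coefficients move less than
    ``tol`` across a full IRLS iteration.
    """
    n = X.shape[0]
    work = np.asarray(work, dtype=np.int64)
    for _ in range(max_irls):
        eta = b0 + X[:, work] @ beta[work] if len(work) else np.full(n, b0)
        p = np.clip(expit(eta), _PROB_CLIP, 1 - _PROB_CLIP)
        w = np.maximum(p * (1 - p), _WEIGHT_FLOOR)
        z = eta + (y - p) / w
        xv = np.einsum("i,ij,ij->j", w, X[:, work], X[:, work]) / n \
            if len(work) else np.empty(0)
        r = z - eta
        before = beta[work].copy()
        b0_before = b0
        b0 = _cd_sweeps(X, work, w, r, beta, b0, xv, lam, n,
                        0.1 * tol, max_sweeps)
        moved = abs(b0 - b0_before)
        if len(work):
            moved = max(moved, np.max(np.abs(beta[work] - before)))
        if moved < tol:
            break
    return beta, b0


def _fit_path_raw(X, y, lambdas, tol=1e-7):
    """Warm-started path fit; X is observations-by-features, y in {0,1}."""
    n, p = X.shape
    ybar = y.mean()
    beta = np.zeros(p)
    b0 = float(np.log(ybar / (1 - ybar)))
    coefs = np.empty((p, len(lambdas)))
    icpts = np.empty(len(lambdas))
    grad = np.abs(X.T @ (y - ybar)) / n  # gradient magnitudes at the null fit
    lam_prev = lambdas[0]
    for li, lam in enumerate(lambdas):
        # sequential strong rule + current active set, then KKT certification
        candidate = (grad >= 2 * lam - lam_prev) | (beta != 0)
        while True:
            work = np.flatnonzero(candidate)
            beta, b0 = _irls_cd(X, y, lam, beta, b0, work, tol)
            eta = b0 + X @ beta
            p_hat = np.clip(expit(eta), _PROB_CLIP, 1 - _PROB_CLIP)
            g = X.T @ (p_hat - y) / n
            grad = np.abs(g)
            violators = (~candidate) & (beta == 0) & (grad > lam + 1e-6)
            if not violators.any():
                break
            candidate |= violators
        coefs[:, li] = beta
        icpts[li] = b0
        lam_prev = lam
    return coefs, icpts


def _check_scaled(X, tol=0.05):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(np.abs(mean) > tol) or np.any(np.abs(sd - 1) > tol):
        raise ValueError(
            "X does not look scaled: per-gene means must be ~0 and sds ~1 "
            "(apply fit_scaling/apply_scaling first)"
        )


def _prepare(X, y, genes):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (genes by cells)")
    y = np.asarray(y)
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError(f"y must be binary 0/1; got values {sorted(uniq)}")
    y = y.astype(float)
    if genes is None:
        genes = pd.Index([f"g{i}" for i in range(X.shape[0])])
    genes = pd.Index(genes)
    if len(genes) != X.shape[0]:
        raise ValueError("genes length must equal number of rows of X")
    return np.asfortranarray(X.T), y, genes  # to observations-by-features


def fit_l1_logistic_path(X, y, genes=None, lambdas=None, n_lambda: int = 100,
                         lambda_min_ratio: float = 1e-4, tol: float = 1e-7,
                         check_scaling: bool = True) -> PenalizedPath:
    """Fit the L1 logistic path on scaled gene-by-cell values ``X``.

    ``X`` has genes in rows and cells in columns (the package-wide
    orientation); ``y`` is 0/1 with 1 = malignant. ``lambdas`` defaults to
    100 log-spaced values from lambda_max down to ``lambda_min_ratio``
    times it. A trailing ``lambda = 0`` entry is allowed and fits the
    unpenalized model.
    """
    Xn, y, genes = _prepare(X, y, genes)
    if check_scaling:
        _check_scaled(Xn)
    if lambdas is None:
        lambdas = default_lambda_grid(lambda_max(Xn, y), n_lambda,
                                      lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    coefs, icpts = _fit_path_raw(Xn, y, lambdas, tol=tol)
    return PenalizedPath(
        genes=genes,
        lambdas=lambdas,
        coefficients=coefs,
        intercepts=icpts,
        nonzero_counts=(coefs != 0).sum(axis=0),
    )


def cross_validate(X, y, genes=None, lambdas=None, n_folds: int = 10,
                   seed: int = 0, n_lambda: int = 100,
                   lambda_min_ratio: float = 1e-4, tol: float = 1e-7,
                   check_scaling: bool = True) -> PenalizedPath:
    """Full-data path plus per-lambda held-out mean deviance and SE.

    Folds are stratified so class proportions are preserved; the lambda
    grid is fixed on the full data and shared across folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    Xn, yv, genes = _prepare(X, y, genes)
    if check_scaling:
        _check_scaled(Xn)
    counts = np.bincount(yv.astype(int), minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratification impossible: minority class has {counts.min()} "
            f"cells, fewer than n_folds={n_folds}"
        )
    if lambdas is None:
        lambdas = default_lambda_grid(lambda_max(Xn, yv), n_lambda,
                                      lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)

    coefs, icpts = _fit_path_raw(Xn, yv, lambdas, tol=tol)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_dev = np.empty((n_folds, len(lambdas)))
    for fi, (tr, te) in enumerate(skf.split(Xn, yv)):
        c, b = _fit_path_raw(Xn[tr], yv[tr], lambdas, tol=tol)
        eta = Xn[te] @ c + b[None, :]
        p = np.clip(expit(eta), _PROB_CLIP, 1 - _PROB_CLIP)
        yt = yv[te][:, None]
        fold_dev[fi] = -2.0 * np.mean(yt * np.log(p) + (1 - yt) * np.log1p(-p),
                                      axis=0)
    return PenalizedPath(
        genes=genes,
        lambdas=lambdas,
        coefficients=coefs,
        intercepts=icpts,
        nonzero_counts=(coefs != 0).sum(axis=0),
        cv_mean_deviance=fold_dev.mean(axis=0),
        cv_se=fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds),
    )


def select(path: PenalizedPath, rule: str = "cv_min") -> SelectionResult:
    """Pick a lambda from a cross-validated path.

    ``rule`` is ``"cv_min"``, ``"cv_1se"`` or ``"support:k"`` (largest
    lambda with exactly k nonzero coefficients).
    """
    if rule.startswith("support:"):
        k = int(rule.split(":", 1)[1])
        hits = np.flatnonzero(path.nonzero_counts == k)
        if len(hits) == 0:
            attained = sorted(set(path.nonzero_counts.tolist()))
            raise ValueError(
                f"no lambda on the grid has support size {k}; attained sizes: "
                f"{attained}"
            )
        idx = hits[0]  # grid is decreasing, so first hit = largest lambda
    else:
        if path.cv_mean_deviance is None:
            raise ValueError(f"rule {rule!r} needs cross-validation results")
        i_min = int(np.argmin(path.cv_mean_deviance))
        if rule == "cv_min":
            idx = i_min
        elif rule == "cv_1se":
            bound = path.cv_mean_deviance[i_min] + path.cv_se[i_min]
            ok = np.flatnonzero(path.cv_mean_deviance <= bound)
            idx = int(ok.min())  # largest lambda within one SE
        else:
            raise ValueError(f"unknown selection rule {rule!r}")
    beta = path.coefficients[:, idx]
    nz = beta != 0
    return SelectionResult(
        chosen_lambda=float(path.lambdas[idx]),
        rule=rule,
        selected_genes=list(path.genes[nz]),
        coefficients_at_choice={g: float(b) for g, b in
                                zip(path.genes[nz], beta[nz])},
    )
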