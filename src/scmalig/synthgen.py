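"""Synthetic labeled single-cell expression matrices with calibrated per-gene AUC.

The generator emulates a tumor atlas with two labeled cell populations
(malignant and normal, malignant prevalence ~10% by default) in which a
small panel of informative genes separates the classes with prescribed
marginal ROC AUCs, embedded among many uninformative genes.

The discriminability model is a latent equal-variance Gaussian: for an
informative gene the malignant class is shifted by
``delta = sd * sqrt(2) * Phi^{-1}(target_auc)``, which gives theoretical
AUC ``Phi(delta / (sd * sqrt(2)))`` exactly. By default the emitted
expression is ``exp(latent)`` — a log-normal, counts-like scale on which
class fold changes ``e^delta`` have realistic magnitudes; because ``exp``
is strictly increasing, rank-based AUC is identical on either scale, so
the calibration is exact in both modes. ``value_scale="gaussian"`` emits
the latent Gaussian itself, truncated at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from ._matrix import MALIGNANT, NORMAL, LabeledExpressionMatrix

__all__ = [
    "InformativeGene",
    "GeneratorConfig",
    "DEFAULT_PANEL",
    "calibrate_shift",
    "generate",
    "inject_qc_failures",
    "read_config",
    "write_config",
]

# Seven-gene reference panel: the marginal AUCs the published model genes
# showed on the real atlas, used as the default simulation condition.
DEFAULT_PANEL = (
    ("KRT18", 0.927, "up"),
    ("NAPSA", 0.921, "up"),
    ("KRT7", 0.892, "up"),
    ("GPRC5A", 0.864, "up"),
    ("IRX2", 0.835, "up"),
    ("CAPN8", 0.806, "up"),
    ("SPINK13", 0.725, "up"),
)

_MAX_ENTRIES = 200_000_000  # refuse to allocate matrices beyond this


@dataclass(frozen=True)
class InformativeGene:
    """One class-separating gene: name, target marginal AUC, direction."""

    name: str
    target_auc: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if not 0.5 < self.target_auc < 1.0:
            raise ValueError(
                f"target_auc must lie strictly in (0.5, 1); got {self.target_auc}"
            )
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down'; got {self.direction!r}")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the package's reference scenario: 10% malignant
    prevalence over 10,000 cells, the seven-gene reference panel at its
    published marginal AUCs, and 500 uninformative genes. ``base_mean``
    and ``base_sd`` parameterize the latent Gaussian (log scale when
    ``value_scale="lognormal"``); the mitochondrial fraction is an
    independent Beta draw per cell.
    """

    n_malignant: int = 1000
    n_normal: int = 9000
    informative_genes: tuple = DEFAULT_PANEL
    n_noise_genes: int = 500
    zero_inflation_rate: float = 0.0
    base_mean: float = 3.0
    base_sd: float = 1.0
    mito_beta_a: float = 2.0
    mito_beta_b: float = 38.0
    value_scale: str = "lognormal"  # "lognormal" | "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 1 or self.n_normal < 1:
            raise ValueError("need at least one cell per class")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be >= 0")
        if not 0.0 <= self.zero_inflation_rate < 1.0:
            raise ValueError("zero_inflation_rate must lie in [0, 1)")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be positive")
        if self.base_mean < 0:
            raise ValueError("base_mean must be non-negative")
        if self.value_scale not in ("lognormal", "gaussian"):
            raise ValueError("value_scale must be 'lognormal' or 'gaussian'")
        if self.mito_beta_a <= 0 or self.mito_beta_b <= 0:
            raise ValueError("mito Beta parameters must be positive")
        self.informative_genes = tuple(
            g if isinstance(g, InformativeGene) else InformativeGene(*g)
            for g in self.informative_genes
        )
        names = [g.name for g in self.informative_genes]
        if len(set(names)) != len(names):
            raise ValueError("informative gene names must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.informative_genes) + self.n_noise_genes

    @property
    def n_cells(self) -> int:
        return self.n_malignant + self.n_normal

    def to_dict(self) -> dict:
        d = asdict(self)
        d["informative_genes"] = [
            {"name": g.name, "target_auc": g.target_auc, "direction": g.direction}
            for g in self.informative_genes
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        genes = d.pop("informative_genes", None)
        if genes is not None:
            d["informative_genes"] = tuple(
                InformativeGene(g["name"], g["target_auc"], g.get("direction", "up"))
                for g in genes
            )
        return cls(**d)


def calibrate_shift(target_auc: float, sd: float) -> float:
    """Mean shift between two equal-variance Gaussians giving a target AUC.

    Two Gaussians with common standard deviation ``sd`` and means
    separated by ``delta`` have ROC AUC ``Phi(delta / (sd * sqrt(2)))``;
    this returns the inverse, ``delta = sd * sqrt(2) * Phi^{-1}(target_auc)``.
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError(f"target_auc must lie strictly in (0.5, 1); got {target_auc}")
    if sd <= 0:
        raise ValueError(f"sd must be positive; got {sd}")
    return float(sd * math.sqrt(2.0) * norm.ppf(target_auc))


def generate(config: GeneratorConfig) -> LabeledExpressionMatrix:
    """Draw one labeled cohort under ``config``.

    Stochastic draw order is fixed (informative genes in listed order,
    then noise genes, then the zero-inflation mask, then mitochondrial
    fractions) so identical config + seed gives bit-identical output.
    """
    n_cells = config.n_cells
    if config.n_genes * n_cells > _MAX_ENTRIES:
        raise ValueError(
            f"requested matrix of {config.n_genes} x {n_cells} entries exceeds "
            f"the size guard ({_MAX_ENTRIES} entries)"
        )
    rng = np.random.default_rng(config.seed)

    labels = np.array([MALIGNANT] * config.n_malignant + [NORMAL] * config.n_normal,
                      dtype=object)
    is_mal = labels == MALIGNANT

    rows = []
    names = []
    for gene in config.informative_genes:
        delta = calibrate_shift(gene.target_auc, config.base_sd)
        if gene.direction == "down":
            delta = -delta
        mean = np.where(is_mal, config.base_mean + delta, config.base_mean)
        rows.append(rng.normal(mean, config.base_sd))
        names.append(gene.name)
    if config.n_noise_genes:
        noise = rng.normal(config.base_mean, config.base_sd,
                           size=(config.n_noise_genes, n_cells))
        rows.append(noise)
        names.extend(f"NOISE{i + 1:04d}" for i in range(config.n_noise_genes))

    latent = np.vstack([np.atleast_2d(r) for r in rows]) if rows else \
        np.empty((0, n_cells))
    if config.value_scale == "lognormal":
        values = np.exp(latent)
    else:
        values = np.clip(latent, 0.0, None)

    if config.zero_inflation_rate > 0:
        mask = rng.random(values.shape) < config.zero_inflation_rate
        values = np.where(mask, 0.0, values)

    mito = rng.beta(config.mito_beta_a, config.mito_beta_b, size=n_cells)

    return LabeledExpressionMatrix(
        values=values,
        gene_names=pd.Index(names),
        cell_ids=pd.Index([f"C{i + 1:06d}" for i in range(n_cells)]),
        labels=labels,
        mito_fraction=mito,
        normalized=False,
    )


def inject_qc_failures(
    matrix: LabeledExpressionMatrix,
    n_low_gene_cells: int = 0,
    n_high_gene_cells: int = 0,
    n_high_mito_cells: int = 0,
    *,
    low_detected: int = 100,
    high_detected: int = 7500,
    mito_value: float = 0.30,
):
    """Return a copy with designated cells each violating exactly one QC rule.

    Cells are taken in column order: the first ``n_low_gene_cells`` have all
    but ``low_detected`` entries zeroed, the next ``n_high_gene_cells`` gain
    padding gene rows until ``high_detected`` genes are detected, and the
    next ``n_high_mito_cells`` have their mitochondrial fraction set to
    ``mito_value``. Designations never overlap; requesting more cells than
    exist is an error. Returns ``(matrix, modified)`` where ``modified``
    maps reason -> list of cell ids.
    """
    for n in (n_low_gene_cells, n_high_gene_cells, n_high_mito_cells):
        if n < 0:
            raise ValueError("counts must be non-negative")
    total = n_low_gene_cells + n_high_gene_cells + n_high_mito_cells
    if total > matrix.n_cells:
        raise ValueError(
            f"designated {total} cells but matrix has only {matrix.n_cells}; "
            "designations would overlap"
        )
    out = matrix.copy()
    low_idx = np.arange(0, n_low_gene_cells)
    high_idx = np.arange(n_low_gene_cells, n_low_gene_cells + n_high_gene_cells)
    mito_idx = np.arange(n_low_gene_cells + n_high_gene_cells, total)

    values = out.values
    for i in low_idx:
        col = values[:, i]
        nz = np.flatnonzero(col > 0)
        if len(nz) > low_detected:
            col[nz[low_detected:]] = 0.0

    if len(high_idx):
        n_pad = max(high_detected - out.n_genes + 1, 0)
        if n_pad:
            pad = np.zeros((n_pad, out.n_cells))
            pad[:, high_idx] = 1.0
            values = np.vstack([values, pad])
            gene_names = out.gene_names.append(
                pd.Index([f"QCPAD{i + 1:05d}" for i in range(n_pad)])
            )
        else:
            gene_names = out.gene_names
    else:
        gene_names = out.gene_names

    mito = out.mito_fraction
    if len(mito_idx):
        if mito is None:
            mito = np.zeros(out.n_cells)
        mito[mito_idx] = mito_value

    result = LabeledExpressionMatrix(
        values=values,
        gene_names=gene_names,
        cell_ids=out.cell_ids,
        labels=out.labels,
        genes_detected=None,  # recompute from modified values
        mito_fraction=mito,
        normalized=out.normalized,
    )
    modified = {
        "low_genes": list(out.cell_ids[low_idx]),
        "high_genes": list(out.cell_ids[high_idx]),
        "high_mito": list(out.cell_ids[mito_idx]),
    }
    return result, modified


def write_config(config: GeneratorConfig, path) -> None:
    """Serialize a generator config as a flat YAML key-value file."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path) -> GeneratorConfig:
    with open(path) as fh:
        return GeneratorConfig.from_dict(yaml.safe_load(fh))
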