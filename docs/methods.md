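# Methods

This note documents the statistical model behind `scmalig`, the design
choices that were genuinely open, the defaults and their rationale, and
what the synthetic benchmark does and does not demonstrate.

## The classification model

Per cell, the single-cell malignant score is the fitted probability of a
binomial logistic model over a small set of selected genes:

    x = β₀ + Σ_g β_g · z_g ,   scMS = 1 / (1 + e^(−x)) ,

where `z_g` is the per-gene z-score of log-normalized expression,
standardized with the *training population's* mean and SD. The scaling
statistics are part of the serialized model: a shipped model is only
well-defined together with the population statistics used to standardize
its inputs, so `score()` refuses to run without them. Classification uses
the inclusive rule `scMS ≥ cutoff`.

The packaged seven-gene reference instance reproduces a published
lung-adenocarcinoma model (intercept −4.7082; KRT18 0.8449, IRX2 0.7221,
NAPSA 1.2584, SPINK13 2.3251, KRT7 1.5488, CAPN8 0.4969, GPRC5A 0.6344;
cutoff 0.046). Two printed ambiguities were resolved as follows:

* The source prints the score as "1 + 1/(1 + e^−x)", which would put it
  in (1, 2) and contradict the 0.046 cutoff; the leading "1 +" is treated
  as a typesetting artifact and the standard logistic is implemented.
* The published parameters come with no scaling statistics, so the
  reference instance ships without them and the API forces the user to
  attach a scaling population explicitly (`attach_scaling`), preventing
  silent misuse on un-standardized data.

## Screening stages

**QC.** Cells are removed when detected genes < `min_genes` (200),
detected genes > `max_genes` (7000), or mitochondrial fraction >
`max_mito_fraction` (0.20). All three comparisons are strict on the
violating side — a cell at exactly 200 genes or exactly 20% mitochondrial
counts is retained. Mitochondrial fraction means fraction of *counts* in
genes matching a configurable name prefix (default `MT-`), the usual
convention; it is computed from the matrix only when per-cell metadata is
absent.

**Normalization.** The source workflow does not state its normalization;
we use the de-facto convention of that workflow: per-cell depth
normalization to `target_sum` (default 10,000) followed by log(1+x).
Scaled values are not clipped (some workflows clip at ±10); clipping is
deliberately off because the score formula gives no hint of it.

**DEG screen.** Two-sided Wilcoxon/Mann–Whitney rank-sum per gene on
normalized values (midranks for ties; tie-corrected normal approximation
for large samples, exact enumeration below a configurable class size;
all-constant genes get p = 1), Benjamini–Hochberg FDR, and a fold-change
filter. Records pass when `fdr < fdr_max` (strict) and `|log2fc| ≥
min_abs_log2fc` (inclusive). The threshold default is 0.5 — the value
attached to the published 1655-DEG funnel — with 1.0 (the stated Methods
value in the source) one flag away. Two fold-change conventions are
implemented: `simple` (pseudocounted ratio of class means of the values
as given) and `seurat` (class means of expm1 of the values, i.e. the
linear scale). The standalone function defaults to `simple` for
auditability; the *pipeline* defaults to `seurat` because its input at
that stage is log1p-transformed, and the published fold-change bounds
(1.41 / 0.70 for |log2FC| = 0.5) are linear-scale ratios.

**ROC screen.** Per-gene AUC is the Mann–Whitney statistic (malignant
positive, expression as score, ties counted half); screening uses the
oriented AUC max(AUC, 1−AUC) with a strict `> 0.60` rule, so
down-regulated discriminators are retained with their direction recorded.
The per-gene operating point is the Youden-optimal threshold (maximizing
sensitivity + specificity − 1) over midpoints of adjacent distinct scores
plus ±∞, ties broken toward higher sensitivity and then lower threshold.
Youden's J is the cut-point criterion throughout (it is the "best"
convention of the standard ROC tooling; the source does not state one).
Because rank-based AUC is invariant under strictly monotone transforms,
the choice of normalization does not affect the screen — asserted by
test.

**Secreted/membrane annotation.** A gene is flagged when any of its
subcellular-location terms falls in a configured set (default: secreted,
plasma membrane, membrane, cell membrane, cell junctions). The packaged
table `data/subcellular_fixture_synthetic.tsv` is a small synthetic
stand-in covering the reference-model genes and common lung epithelial
markers: its flags reproduce the published per-gene annotations, but its
location terms are invented, since the source does not state which terms
define the flag. A full Human Protein Atlas export can be supplied
instead. The flag is reported, not used as a hard filter, since the
published selection ran on the full prediction gene set.

## Sparse selection

The L1-penalized binomial objective, per observation, is

    (1/n) Σ_i [ −y_i η_i + log(1 + e^{η_i}) ] + λ Σ_j |β_j| ,

with an unpenalized intercept and features standardized to mean 0, SD 1
(enforced at the interface). The per-observation loss scale is fixed and
stated because λ values are otherwise not comparable across sample sizes.
The solver is cyclic coordinate descent with soft-thresholding on the
IRLS quadratic approximation, warm-started along a decreasing grid of 100
log-spaced λ from λ_max = max_j |⟨x_j, y−ȳ⟩|/n down to 10⁻⁴·λ_max
(configurable). A sequential strong rule proposes the working set at each
λ and a full KKT sweep over all features certifies each solution; the
inner loop is numba-compiled. Probabilities are clipped at 10⁻⁹ and IRLS
weights floored at 10⁻⁵ for stability; convergence is max coefficient
change < `tol` (default 10⁻⁷) across an IRLS iteration. The path is
deterministic bit-for-bit for fixed inputs.

Cross-validation uses stratified folds (class proportions preserved,
shuffled with a caller-supplied seed) and held-out mean binomial
deviance, with the λ grid fixed on the full data. Selection rules:
`cv_min` (deviance minimum — the default, matching the source's
"optimally minimized" language), `cv_1se` (largest λ within one SE of the
minimum), and `support:k` (largest λ with exactly k nonzero coefficients,
provided to reproduce the seven-gene outcome structurally).

The source describes this step as LASSO "in Cox's proportional hazard
model", yet the outcome is per-cell malignancy with no time-to-event
variable; the family implemented is binomial logistic, and the Cox
phrasing is treated as a misnomer.

## Final fit and cut-point

The selected genes are refit by unpenalized maximum likelihood
(Newton/IRLS, tolerance 10⁻¹⁰ on the step, at most 100 iterations).
Perfect separation is detected (coefficient norm exceeding 30 or
non-convergence) and raised as an error with an optional ridge fallback.
The cutoff is the Youden-optimal threshold on training scMS values. With
10% malignant prevalence the fitted probabilities concentrate near the
prevalence, so the optimal cutoff lands well below 0.5 — the same
mechanism that produces the reference model's 0.046.

## The synthetic-data generator

The generator emulates a two-population tumor atlas: ~10% malignant
prevalence by default (1,000 + 9,000 cells), a small panel of informative
genes among many nulls, optional dropout and per-cell QC metadata. Its
defaults are the package's reference scenario: the seven reference genes
at their published marginal AUCs (0.927, 0.921, 0.892, 0.864, 0.835,
0.806, 0.725) plus 500 null genes.

Discriminability is controlled through a latent equal-variance Gaussian:
an informative gene's malignant class is shifted by Δ = sd·√2·Φ⁻¹(AUC),
giving theoretical AUC Φ(Δ/(sd·√2)) exactly (negative shift for
down-regulated genes). Two output scales are provided:

* `lognormal` (default): expression = exp(latent). Because exp is
  strictly increasing, rank-based AUC is identical to the latent scale,
  so the calibration is exact; and linear-scale fold changes e^Δ fall in
  the published magnitude range (log2FC ≈ 1.2–3.0 for the panel), so the
  planted genes behave like real markers under the DEG fold-change
  filter. This is the reason lognormal is the default: a *linear*-scale
  Gaussian with mean ≥ 3·sd (needed to keep truncation negligible) caps
  the weakest planted gene's log2FC at ~0.36, below the 0.5 default
  threshold, making the default screen impossible to pass by
  construction.
* `gaussian`: the latent Gaussian itself, truncated at zero (truncation
  mass is negligible at the default base_mean = 3·sd; calibration is
  verified empirically).

Dropout is independent Bernoulli masking per entry
(`zero_inflation_rate`, default 0 — calibration targets refer to the
un-inflated model; masking provably shrinks |AUC − 0.5|, and tests check
this monotonically). The mitochondrial fraction is an independent
Beta(2, 38) draw per cell (mean 5%, rarely above 20%) — QC testing needs
the metadata, not a biological model of mitochondrial content. A single
seed governs all draws in a fixed order (informative genes in listed
order, noise genes, dropout mask, mitochondrial fractions), so identical
config + seed gives bit-identical output; oversized requests fail
explicitly rather than truncating.

What the generator does **not** emulate: UMI count noise, gene–gene
correlation beyond depth normalization, batch structure, multi-subtype
tumor heterogeneity, or the mean–variance relation of real scRNA-seq.
Passing benchmarks on it therefore demonstrates the pipeline's
correctness and calibration under the stated model, not performance on
real atlases.

## Benchmark problem sizes

The packaged benchmarks run at desk scale: marginal-AUC calibration at
5,000+5,000 cells (Monte-Carlo tolerance ±0.01, about 3 standard errors),
the end-to-end benchmark on the seven-gene scenario with 500 null genes
and a 70/30 split, and support-recovery at 1,000+9,000 cells. On the
end-to-end benchmark the held-out scMS AUC is ≈ 0.998 — comfortably above
the published 0.961, as expected for independent Gaussian genes, whose
combined d′ is the root-sum-of-squares of the panel (≈ 4.2, theoretical
AUC ≈ 0.999).

One measured caveat: with the 1-SE rule applied to *all* 507 genes
(no DEG/AUC pre-screen), cross-validated deviance keeps improving until
~140 genes are active and the 1-SE λ still carries ~50, so selection
returns a superset of the planted genes. Exact recovery of the planted
support holds for the pipeline (screens first, then LASSO) and for the
`support:7` rule; the package documents rather than hides this behaviour
of the 1-SE rule under many weakly-correlated nulls.

## Known limitations

* Labels are taken as ground truth; label noise is neither modeled nor
  simulated.
* The Wilcoxon screen assumes exchangeability within class; no covariate
  or batch adjustment is provided (batch integration is out of scope).
* The reference model can only be applied meaningfully after attaching
  scaling statistics from a population comparable to its training data;
  the package cannot validate that comparability.
* AUC confidence intervals and per-cell score uncertainty are not
  computed.
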