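# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and the known limitations of `tumorhet`.

## The nested mixed model

For one gene, log2 expression of sample *i* is modelled as

    y_i = x_i' beta + a_{p(i)} + b_{f(i)} + e_i

with patient random intercepts `a ~ N(0, sigma_P^2)`, focus random
intercepts `b ~ N(0, sigma_F^2)` nested in patients, and residual
(punch-level) noise `e ~ N(0, sigma_IT^2)`.  Fixed effects are an
intercept plus, depending on the analysis, a tumor/normal indicator
(differential expression) or tumor grade as an unordered category
(heterogeneity analysis; grades can differ between a patient's foci, so
grade is a punch-level covariate).

Estimation maximizes the Gaussian likelihood (ML) or restricted
likelihood (REML); REML is the default because the variance components —
not beta — are the quantities of interest, and REML corrects the
downward bias from estimating the fixed effects.  The REML criterion is

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X' V^-1 X| + r' V^-1 r ],

with `V = sigma_P^2 Z_P Z_P' + sigma_F^2 Z_F Z_F' + sigma_IT^2 I`, beta
profiled out by GLS and `r` the GLS residual.  `NestedLMM.loglike`
evaluates this exactly by Cholesky factorization of the dense n-by-n
covariance (n is at most ~90 here, so dense algebra is both simplest and
fast); `reml_criterion` exposes it as a free function and is used as an
optimizer-independent oracle in the tests.

### Optimization

`fit()` profiles out both beta and the residual variance, leaving a 2-D
problem in the variance ratios `gamma_P = sigma_P^2 / sigma_IT^2` and
`gamma_F = sigma_F^2 / sigma_IT^2`.  These are optimized by L-BFGS-B with
bound constraints `gamma >= 0` from a fixed 3x3 multi-start grid
`{0, 1, 4}^2` that includes the boundary, so fits with `sigma_hat = 0` —
common in practice for the patient component of strongly focus-variable
genes — are reached deterministically, with no random initialization.
Convergence tolerance is 1e-8 on the criterion gradient with at most 500
iterations per start; the best start wins, and variance shares below
1e-10 of the total are snapped exactly to zero.  A constant response
yields a degenerate fit (all sigmas 0, beta from OLS) with the residual
variance floored at 1e-30 to keep the criterion finite.

Designs in which components are not separately identifiable (every focus
with a single punch, or every patient with a single focus) trigger an
`AliasingWarning` rather than silently returning an arbitrary split.

### Boundary likelihood-ratio tests

`H0: sigma_F = 0` is tested by refitting with the focus component removed
(same fixed design, same REML criterion — valid because the mean model is
unchanged) and referring `Lambda = 2 (l_full - l_reduced)`, clipped at 0,
to either

* `chisq1` — the naive chi-square(1) tail (the default; conservative,
  since under the boundary null the statistic is a 50:50 mixture of a
  point mass at zero and chi-square(1)), or
* `mixture_half` — half the chi-square(1) tail, with p = 1 at Lambda = 0.

The same machinery tests `H0: sigma_P = 0`.  The default is the
conservative convention; the calibration suite verifies empirically that
`mixture_half` rejects at most 5% of nulls at the study design and that
`chisq1` rejects fewer.

### Heterogeneity percentages

`HET.P : HET.F : HET.IT = sigma_P^2 : sigma_F^2 : sigma_IT^2`, normalized
to sum to 100.  When all three estimates are zero the record is flagged
degenerate (NaNs) rather than forced.  Holm and Benjamini-Hochberg
adjustments are applied across genes separately for the focus-variance
and patient-variance test families, since each family asks a distinct
question of all genes.

## Differential expression

Tumor vs adjacent-normal contrasts use the same model with a tissue fixed
effect; `FC = 2^beta_tissue`, p-values from a Wald test with a normal
reference (a t reference with a residual-df proxy is available via
`use_t=True`).  The normal reference was chosen as the default because it
is deterministic and simple, and the empirical calibration of the whole
pipeline is checked by simulation rather than assumed.  Adjacent-normal
samples carry no focus, so each receives its own singleton focus level;
its extra variability then loads consistently onto the focus + residual
components.  Grade is not included in the DE model by default (it is a
tumor attribute); a flag adds it.  Zero-variance genes are reported as
null records (FC = 1, p = 1) instead of being dropped.  Filtering uses
strict inequalities: FC exactly at a threshold is excluded.

## Normalization

geNorm stability: `M_j` is the mean over other candidates `k` of the SD
across samples of `log2(x_j / x_k)`.  The default is the full iterative
procedure — repeatedly remove the candidate with the largest M and
recompute — because that is the published algorithm; a one-shot
`single_pass` ranking is available.  Ties break on the gene identifier so
selection is deterministic and order-independent.  The most stable 36 of
40 candidates (configurable) are kept, and per-sample scale factors
equalize the geometric mean of the kept references across samples,
centred on the grand mean so normalized counts stay commensurate with raw
counts.  Zeros among reference genes are replaced by the pseudocount
(default 1.0, applied before geometric means) with a warning; log2
transformation adds the same pseudocount.

## Pathway scores

Within a pathway, each gene is centred at its adjacent-normal baseline
mean and divided by `max(SD, 0.05)`; the SD is taken across all samples
by default (a `baseline`-only option exists) and the floor stops
near-constant genes from dominating.  The per-sample score is the first
principal component of this scaled matrix, computed by SVD *without*
additional centering — the baseline subtraction is the only centering, so
a sample equal to the average normal scores near zero.  The sign is
oriented so the mean tumor score is at least the mean baseline score
(first-gene-positive as the deterministic tie-break).  Pathway-level
p-values reuse the DE regression with the score as response; the
"global significance" of a pathway is `sqrt(mean(t^2))` over its genes'
Wald statistics.  No pathway fold-change statistic is computed.

## Copy number

Samples are first depth-normalized by equalizing the geometric mean of
the invariant control probes (arithmetic-mean option available).  Copy
number of gene g in sample s is `2 * mean(g's probes in s) / mean(g's
probes across the adjacent-normal reference samples)`.  Estimates are
produced per punch (the finest grain, so per-focus min/max/mean ranges
exist) with per-focus and per-patient summaries on top.  Calls use an
exclusive deletion bound (CN < 1.5) and an inclusive amplification bound
(CN >= 3.0).  The reference sample set is always user input, never
hard-coded.  qPCR copy number is `2 * 2^-ddCT` with
`ddCT = (CT_target - CT_control)_sample - (CT_target - CT_control)_normal`.
CN-expression association uses Spearman correlation with average ranks
and the large-sample p-value.  No GC/length bias correction and no
segmentation are applied: the panel is 80 discrete genes.

## Synthetic data

The generator emulates the study design: 11 patients with 2-3 foci each
(default pattern `(3,2,2,2,2,2,2,2,2,3,2)`, giving 24 foci), 3 punches
per focus, 7 adjacent-normal punches attached to the first 7 patients,
730 endogenous genes and 40 candidate references.  Per gene, latent log2
expression follows exactly the mixed model above (baseline means uniform
on log2 5-11, grade effects N(0, 0.2) per grade step), observed counts
are `round(2^x * depth)` with per-sample depth `2^N(0, 0.4)`, and an
optional Poisson layer can be switched on to stress robustness (off by
default so calibration tests are interpretable).  Defaults: 60% of genes
carry real focus variance (`sigma_F` uniform 0.5-1.2, chosen so the
detectable fraction at study scale is around 60%, matching the regime the
design was built for), `sigma_P` uniform 0.2-0.8, `sigma_IT` uniform
0.3-0.6; 30% of genes carry a tumor shift of magnitude uniform 0.5-2.5
log2 units with random sign.  Reference genes have near-zero biological
variance (residual SD 0.05) except four deliberately unstable ones
(SD 0.6) that exercise the 36-of-40 selection.  Copy-number simulation
plants integer states per (patient, focus, gene) — clonal when the event
spans all foci, private otherwise — on 80 genes with 2-3 probes each, 54
invariant probes, and 10% multiplicative probe noise; qPCR CTs encode
`-log2(CN/2)` plus 0.1-cycle noise.  Everything is driven by one seed and
the full latent state is returned, so every estimator can be checked
against its generating truth.

What the generator does **not** emulate: FFPE degradation, probe-sequence
effects, stromal contamination mixtures, count overdispersion beyond the
lognormal punch term (unless the Poisson layer is enabled), and any
spatial structure between foci.  Passing recovery tests therefore show
that the estimators are correct under the model's own assumptions at the
study's size — not that real FFPE NanoString data meet those assumptions.

## Problem sizes used in the checks

The acceptance script runs the full pipeline at the study scale (730 + 40
genes, 79 samples), a 500-gene recovery simulation with sigma triples
drawn uniformly from (0, 1.5)^3 (residual SD floored at 0.05 to avoid
noiseless degeneracy), a 1000-replicate null calibration of the focus
LRT, and 8 replicate copy-number datasets for the planted-event closed
loop; these sizes give stable summaries while keeping a single-CPU run in
the minutes range.

## Known limitations

* Wald p-values use a normal reference by default; with 7 normal samples
  the tumor-vs-normal test is approximate (the t option is a partial
  remedy, and calibration is verified only by simulation).
* The LRT conventions bracket, but do not exactly match, the unknown
  finite-sample null distribution of boundary variance tests in
  unbalanced designs.
* Patients with a single focus cannot inform `sigma_F` on their own; they
  are retained (the mixed model handles unbalance) and listed by
  `validate_design`.
* The RCC container format is not parsed; only tabular CSV exports are
  read.
* Exact reproduction of a vendor pipeline's normalized counts may require
  matching that pipeline's exact normalization convention; the geometric
  mean-of-geometric-means convention implemented here is the documented
  default behaviour of the platform software.
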