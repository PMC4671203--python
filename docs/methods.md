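# Methods

## The admixture model

A bulk tumour sample is modelled as a two-compartment mixture: cancer cells
with fraction `p` (the tumour purity) and an aggregate microenvironment
compartment with fraction `1 − p`. The package treats the microenvironment
as a single profile rather than resolving immune subtypes; this is the
minimal structure needed to produce, and then remove, purity confounding.

### Synthetic cohorts

`simulate_cohort` draws, per sample `s` and gene `g`:

- purity `p_s ~ Beta(α, β)`. Defaults match a mean of 0.753 and s.d. of
  0.189 (α ≈ 3.17, β ≈ 1.04), the spread reported for consensus purity in
  large multi-cancer cohorts. Tumour-adjacent normal samples draw their
  non-immune fraction from a tighter, higher prior (mean 0.85, s.d. 0.08)
  because adjacent tissue also carries an immune infiltrate.
- expression `counts_gs ~ NB(μ_gs, φ_g)` with
  `μ_gs = L_s (p_s T_g f_g(cond_s) + (1 − p_s) E_g)`. Library sizes `L_s`
  are log-normal around 1e5 (log-s.d. 0.25) to exercise size-factor
  estimation. `T_g` is a normalized log-normal baseline (log-s.d. 1);
  dispersions `φ_g` are log-normal with median 0.1 (log-s.d. 0.5), typical
  of bulk RNA-seq. `f_g` multiplies tumour-intrinsic DE genes by
  `2^±log2fc` (default magnitude 1) in tumour samples only.
- purity loading through the environment/tumour ratio `E_g/T_g`:
  environment-driven genes have `E_g = 10 T_g` (strong negative loading);
  tumour-intrinsic genes have `E_g = intrinsic_env_ratio · T_g`
  (default 0.5); all other genes draw `log(E_g/T_g) ~ N(0, 0.8)`, which
  produces the continuous spread of positive and negative purity
  correlations the co-expression analysis needs. Default DE fractions are
  5% tumour-intrinsic (half up, half down) and 10% environment-driven.
- methylation at informative site `i`:
  `β_is = clamp01(p_s M_i + (1 − p_s) λ + ε)`, `M_i ~ N(0.85, 0.05)`
  truncated to [0, 1], leukocyte level `λ = 0.02`, noise
  `ε ~ N(0, 0.05)`. With the site spread, noise and λ all set to zero the
  betas equal `0.85 p_s` exactly (the λ term otherwise contributes
  `0.02 (1 − p_s)`).
- surrogate purity methods: truth plus per-method bias/noise/missingness
  (ESTIMATE-like 0/0.05/0%, ABSOLUTE-like −0.02/0.07/10%,
  IHC-like +0.05/0.12/30%), clamped to [0, 1].
- clinical features: `subtype` is a median split of purity plus calibrated
  noise so its two groups differ by ~1 purity s.d. (a positive control for
  association testing); `batch` and `age` are independent negative
  controls.

All randomness flows from one `numpy` Generator seeded by `config.seed`;
identical configs give bit-identical cohorts. Counts are sampled
Gamma–Poisson so the variance is exactly `μ + φμ²`.

`masked_cohort_config` encodes the adversarial scenario used to
demonstrate recovery of diluted effects: all intrinsic genes up-regulated
but absent from the microenvironment (`E_g = 0`), tumour purity lowered to
mean ≈ 0.55, and a 15% environment-driven fraction that crowds the top of
the unadjusted DE ranking.

**What the generator does not emulate:** correlated gene modules beyond the
shared purity factor, copy-number or mutation signal, immune-subtype
structure, batch effects in expression, probe-level artefacts, or
non-linear mixture effects (e.g. cell-size/RNA-content differences between
compartments). Passing tests therefore show that each algorithm does what
it claims under the stated mixture model, not that real-cohort effect
sizes will match.

## Purity estimation

**Site selection** keeps probes whose beta is below the leukocyte threshold
(default 0.05) in *every* reference leukocyte sample — a max-based reading
of "consistently unmethylated", stricter than a mean-based one — and whose
per-cancer-type mean beta exceeds the tumour threshold (default 0.30) in
*every* type. Missing reference values are ignored rather than failing the
probe. An empty selection raises an error reporting how many probes passed
each criterion separately.

**LUMP** is the mean informative-site beta divided by 0.85, floored at 0
and capped at 1: purity is a proportion and a fixed divisor can push the
raw ratio above 1. Samples with fewer than `min_sites` (default 10)
non-missing informative probes return NaN rather than a noisy estimate; the
default tolerates missingness against a full panel of ~44 sites.

**CPE** standardizes each method column to the target mean/s.d. and takes
the per-sample median over available methods (≥ 2 required; even counts use
the midpoint convention). The default targets 0.753/0.189 are fixed
constants so that estimates are comparable across cohorts;
`recompute_targets=True` instead uses the pooled mean/s.d. of the supplied
table, appropriate when a new cohort's scale is of interest. Zero-variance
columns cannot be standardized and are dropped with a warning. The
standardization makes CPE exactly invariant to positive affine
transformations of any single method's column.

## Co-expression deconfounding

Expression is log2(size-factor-normalized counts + 1); the gene subset is
the top-N by log-scale s.d. (default 1000 for the pair analysis), ties
broken lexicographically by gene ID for reproducibility. Pairwise and
gene-purity correlations are Spearman; partial correlations rank-transform
first and then apply the Pearson first-order identity, which equals
correlating the residuals of each rank vector regressed on the rank of
purity (the test suite asserts this to 1e−10). Inputs with |r| = 1 against
purity are rejected — the identity degenerates.

The confounding summary retains pairs with |r_raw| above the pair threshold
(default 0.5) and regresses `decrease = r_raw − r_partial` on the product
`r_xp · r_yp` with a Nadaraya–Watson (Gaussian-kernel) local mean,
bandwidth 0.05 in product units; the slope is the mean finite-difference
derivative over the central 80% of the product range (trimming the sparse
tails) and is reported per 0.1 of product. For pairs correlated only
through purity, `r_raw ≈ r_xp · r_yp` and `r_partial ≈ 0`, so the decrease
tracks the product one-to-one and the reported slope sits near 0.1.

## Purity-adjusted differential expression

Size factors are median-of-ratios (reference genes = nonzero in all
samples; total-count fallback with a warning), rescaled to geometric mean 1.
Dispersions are method-of-moments on normalized counts,
`φ = (s² − μ)/μ²` with df-corrected within-condition variances averaged
across groups and floored at 1e−8. This deliberately omits the Cox–Reid /
empirical-Bayes shrinkage of production DE packages: it is unbiased enough
at the simulated depths and keeps the model self-contained; at very small
n it is noisier than shrunk estimators and the Wald test can be mildly
anticonservative.

Each gene is fitted as `log μ = log sf + β0 + β1·[tumour] (+ β2·purity)`
by IRLS with the NB variance function and fixed `φ_g` (statsmodels GLM
backend); `β1/SE` is the Wald statistic, two-sided normal p, BH-adjusted.
The purity covariate enters untransformed as a fraction. Genes with total
count below 10 are excluded before testing; non-converged fits are flagged
with missing p. Ranks (1 = smallest p) break ties by descending |statistic|
then gene ID, over all tested genes (not just significant ones).

The rank-change classifier takes significance at BH-adjusted p < α
(default 0.05 — the conventional choice; it is configurable because no
single cutoff is canonical) and requires a rank improvement by a factor
≥ 2 *and* ≥ 200 positions for `newly_discovered`, with `lost` as the exact
mirror. Remaining significant-after-adjustment genes are `stable_up/down`
by fold-change sign.

## Clinical association

Categorical features: one-way ANOVA of purity across levels with ≥ 2
samples (Mann–Whitney available as an option for two-level features);
continuous features: Spearman test. BH across all tested features,
significance at 1% FDR. Signature enrichment compares the |r|-with-purity
distribution of the set against its complement (two-sided two-sample KS) —
the complement rather than all genes keeps the two samples independent; a
`background="all"` mode reproduces the overlapping comparison.

## Problem sizes and numerical choices

The shipped analyses and tests run at desk scale: cohorts of 90–400
samples and 120–2000 genes, chosen so the full suite completes in well
under a minute of statistics plus a few seconds of GLM fitting per
2000-gene design. The headline slope measurement uses three cohorts of 200
tumour samples × 1000 genes. Tolerances: partial-correlation identity
1e−10; CPE affine invariance 1e−10; GLM coefficients vs direct likelihood
maximization 1e−4 (optimizer-limited); Monte-Carlo assertions use 3
standard-error bands or the documented acceptance bands.

## Known limitations

- Dispersion estimation is unshrunken; very small groups (< 5 per arm)
  give noisy φ and optimistic standard errors.
- LUMP assumes the informative sites' tumour methylation averages 0.85 in
  every cancer type; systematic deviation biases the estimate
  multiplicatively.
- CPE with fixed targets inherits any shared bias of the contributing
  methods; the median protects only against minority outliers.
- The kernel-smoothed slope is undefined when fewer than three retained
  pairs span a nonzero product range (reported as NaN).
- The pipeline's simulated mode skips reference-panel site selection (the
  simulator emits informative sites only); `select_informative_sites` is
  exercised through the API/CLI with real or constructed panels.
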