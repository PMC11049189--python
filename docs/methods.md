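# Methods

`dualeb` implements an empirical-Bayes prediction rule for two-group
expression studies and two strategies for integrating a pair of tissues
measured on the same samples. This note documents the model, the
numerical choices, the synthetic-data generator, and the places where the
design was genuinely open.

## The single-dataset rule

For each gene *i* of a log2 expression matrix with `n1` normal and `n2`
disease samples (`n = n1 + n2`), the two-sample statistic is

    t_i = d0 * (x̄_{i,disease} − x̄_{i,normal}) / s_i,
    d0  = sqrt(n1 n2 / n),
    s_i = sqrt(((n1−1) s²_{i,1} + (n2−1) s²_{i,2}) / (n−2)),

so that `t_i ~ t_{n−2}(δ_i)` where `δ_i` is the standardized effect. The
quantile map `z_i = Φ⁻¹(F_t(t_i; n−2))` converts `t_i` to a normal score
with `z_i ≈ N(δ_i, 1)`; tail probabilities are clipped to
`[1e−12, 1−1e−12]` so `z` stays finite.

The effect estimates are shrunk by Tweedie's formula,

    δ̂_i = z_i + s² · d/dz log f̂(z_i),

which is the posterior mean `E[δ | z]` for *any* prior on δ, requiring
only the marginal density `f` of the observed scores. `f̂` is estimated by
Lindsey's method: the z scores are histogrammed into 120 equal-width bins
spanning the data range padded by 10% on each side, the counts are fitted
by a Poisson GLM on a cubic B-spline basis with 7 degrees of freedom, and
the exponentiated linear predictor is normalized to integrate to one.
The derivative `lf̂′` is evaluated analytically from the spline
coefficients (no finite differences); outside the fitted grid the
log-density is continued linearly from the boundary derivative, up to
half the data range, and errors beyond that. A cubic spline basis
contains every quadratic, so the exactly-Gaussian case (log-density
`−z²/2 + const`, hence `lf′(z) = −z`) is representable up to sampling
noise; this is what the null-shrinkage and conjugate-posterior tests
exercise.

`s²` defaults to 1 ("unit" mode), the nominal variance of the normal
scores. A "central" mode estimates it instead as the squared normalized
interquartile spread of z — a robust null-variance estimate that ignores
the tails — for data whose null scale is visibly off 1.

The classifier selects the `k` genes with largest `|δ̂|` (default
`k = 100`, matching the top-100 focus of the evaluation; ties break by
input order) and scores a sample as

    score = Σ_{i ∈ I} δ̂_i · Ŵ_i,   Ŵ_i = (x_i − (x̄_{i,1}+x̄_{i,2})/2) / s_i,

declaring disease when the score is strictly positive. Centering and
scale always come from the training fit, never from evaluation data. The
zero threshold is justified by the balanced design (`n1 = n2`); a score
of exactly 0 falls to the normal class (conservative tie rule).

## Integrating two tissues

Both integration methods compute a per-gene weight in [0, 1] measuring
how much of the evidence comes from the first tissue.

**Weighted gene.** `w_i = −log p_{i,1} / (−log p_{i,1} − log p_{i,2})`,
where the p-values come from per-gene logistic regressions of disease
status on expression (1-df likelihood-ratio test; the LRT is preferred to
a Wald test because Wald p-values are unstable near separation at
n = 16). Expression itself is combined,
`X*_i = w_i X_{i,1} + (1−w_i) X_{i,2}`, and the single-dataset rule is
fitted to `X*`. When both p-values are exactly 1 the 0/0 weight is set to
0.5 (equal evidence); the weight is invariant to the logarithm base.
Complete separation in a logistic fit sets that p-value to the clip
floor 1e−300 with a warning.

**Weighted Z.** `zw_i = |Z_{i,1}| / (|Z_{i,1}| + |Z_{i,2}|)` (0/0 → 0.5)
and the scores combine as `Z^w_i = zw_i Z_{i,1} + (1−zw_i) Z_{i,2}`.
Treating the weight as fixed, `Z^w` has standard deviation
`s_{Z^w} = sqrt(zw² + (1−zw)² + 2 zw (1−zw) ρ)` with ρ the correlation of
the two score vectors across genes; `s_{Z^w} = 1` exactly when ρ = 1 or
the weight is degenerate. By default the combined score is divided by
`s_{Z^w}` before shrinkage — with weakly correlated tissues the combined
score's variance is well below 1, and shrinking it with `s² = 1` would
otherwise flip the sign of every estimate
(`δ̂ ≈ z (1 − 1/Var)` with Var < 1). A `standardize_combined=False`
switch restores the literal unstandardized pipeline.

Because the fitted gene set comes from the combined score but no
combined expression matrix exists for weighted Z, its rule is applied to
each tissue's standardized expression separately; cross-validation
averages the two tissues' test errors and AUCs, and the estimator's
`decision_function` returns the mean of the two tissue scores.

### Permutation-null calibration

Both weights lean toward whichever tissue makes a gene look more
associated *in the same data*. For pure-noise genes this acts as a soft
maximum of two statistics: the combined score's null distribution is
wider than N(0, 1) (empirically, SD ≈ 1.2 at ρ ≈ 0) and
short-tailed (excess kurtosis ≈ −0.7). Tweedie's formula assumes
`z ~ N(δ, 1)`; applied to such a statistic it produces non-monotone,
even sign-flipped estimates, and the gene ranking collapses.

The integration classifiers therefore calibrate the combined statistic
against its label-permutation null before shrinkage: the labels are
permuted `n_permutations` times (default 20), the full combined statistic
— weights included — is recomputed per permutation, and the pooled null
values define a monotone map onto standard-normal scores (piecewise
linear between null order statistics and the matching normal quantiles,
continued linearly beyond the pooled range so very strong genes keep
distinct scores). The observed statistics pass through this map and the
usual density fit and shrinkage follow. Calibration is monotone, so it
never changes the raw ranking of the combined statistic; it only restores
the sampling model the shrinkage step assumes. With 20 permutations of a
3000-gene panel the pooled null holds 60,000 draws, resolving tail
quantiles to about |z| ≈ 4. Calibration can be disabled
(`null_calibration=False`) to study the uncorrected behaviour.

## Cross-validation protocol

Samples are split 50/50 with stratification (4/4 per class per half at
n = 16); unstratified splits would invalidate the zero decision
threshold. Each repeat (default 5) refits everything — statistics,
density, shrinkage, weights, gene selection, standardization — on the
training half only. Reported are per-repeat misclassification errors,
their mean and sample SD, and the ROC/AUC of test scores pooled across
repeats (per-repeat AUC averaging is available as a flag; pooling is the
default because 8 test samples per repeat give a very coarse ROC). A
`paper_mode` flag computes integration weights once from all samples
instead of per fold, mirroring protocols that treat weighting as
preprocessing; the default is leakage-safe. AUC uses the rank
(Mann–Whitney) formulation with ties counting one half.

With 16 samples the five 50/50 splits share many samples between
training sets, so per-repeat errors are strongly correlated and the
reported SD understates the true replication variability; this is a
property of the protocol itself, not of the implementation.

## Gene cleaning

Before analysis, genes with both `|log2 fold change| < min_abs_lfc`
(default 0.05) and pooled standard error `< min_se` (default 1e−4) are
removed: near-constant genes with tiny spread produce spuriously large t
statistics. The conjunction is deliberate — a small fold change with
ordinary spread is an ordinary null gene and is kept. Both thresholds are
exposed because no canonical values exist; the defaults are conservative
and remove nothing from the synthetic generator's output.

## The synthetic generator

`simulate_tissue_pair` emulates the statistical features the methods
exploit, directly on the log2 scale: per-gene baselines
`~ N(6, 2²)` shared by both tissues; within-gene Gaussian noise of SD 1
(`dispersion`), block-equicorrelated between genes (blocks of 20
consecutive genes at pairwise correlation 0.3), independent between
tissues; and 65 differential genes among 3000 (≈2%), each shifting the
disease class by a signed effect jittered ±25% around the tissue mean.
Defaults: 16 samples split 8/8, effect 1.5 SD in the first tissue and
0.75 SD in the second (the first tissue carries the stronger signal, as
in a spinal-cord vs. neocortex comparison), and a DE partition of 30%
first-only / 10% second-only / 60% shared.

The shared-majority partition is a deliberate design point. With
independent cross-tissue noise, a convex combination strictly dilutes a
tissue-exclusive signal, so if most differential genes were exclusive to
one tissue no weighting scheme could beat the better single-tissue
analysis. Integration pays off through genes differential in both
tissues: their aligned signals average coherently while independent
noise cancels (weighted gene), and the combined score's null contracts
(weighted Z). The 60% shared component puts the generator in the regime
the methods are designed for, while the 3:1 exclusive asymmetry
preserves the first-tissue advantage.

What the generator does **not** model: count-level sampling (library
sizes, sequencing depth, overdispersion on the count scale),
heavy-tailed or skewed expression, cross-tissue noise correlation from
shared animals, and realistic gene-gene correlation structure beyond
equicorrelated blocks. Tests passing on this generator therefore
demonstrate the statistical machinery — calibration of the null,
shrinkage behaviour, ordering of the methods when shared signal exists —
not performance on any particular real dataset.

## Numerical and degenerate-input policy

- Constant genes (zero pooled variance) raise an error naming the gene;
  run the cleaning filter first.
- Density fits require ≥ 200 scores and non-constant z.
- Logistic fits use damped Newton steps; non-convergence or |slope| > 25
  is treated as separation.
- `estimate_rho` requires ≥ 3 genes and non-constant score vectors.
- All randomness (generator, CV splits, permutations) flows from
  explicit integer seeds; identical seeds give bit-identical results.

## Problem sizes used in checks

The shrinkage diagnostics use 50,000 synthetic scores; null CV
calibration uses 200 repeated splits of one pure-noise draw; the
method-comparison experiments average 20 replicate draws of the default
design with 5-repeat CV each. These sizes keep the full verification run
in the minutes range on a single core while leaving Monte-Carlo error
well below the margins being checked.

## Known limitations

- Tweedie estimates from an unpenalized Lindsey fit can be non-monotone
  in sparse tails; the calibration step removes the dominant cause for
  the integration statistics, but extreme single-dataset tails with very
  few genes can still wobble.
- The prediction-error experiments at n = 16 sit close to the
  no-information rate unless effects are large; rankings are far more
  stable than error rates at this sample size.
- `s_{Z^w}` treats the weight as fixed; it under-states the true null
  spread of the combined score (which is why the calibration step exists)
  and is reported as a diagnostic.
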