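# Methods

This note documents the statistical models implemented in `teqtl`, the
choices made where the design was genuinely open, and what the synthetic
data used to validate the package does and does not show about real data.

## Setting

The package targets time-course expression genetics: a panel of `N`
genotyped strains (haploid 0/1 codes by default, diploid 0/1/2
supported), each with expression trajectories over `m` ordered
timepoints (default `m = 6`, encoded as `t = 1..m`). The questions are
(1) which loci shape a trajectory (temporal eQTL mapping), and (2) for
two traits linked to the same locus, which causal wiring connects them.

## Temporal association: the MPTGA model

For genotype group `j`, a strain's trajectory is multivariate normal
with a cubic polynomial mean

    g_j(t) = beta_0j + beta_1j t + beta_2j t^2 + beta_3j t^3

and covariance `sigma_e^2 R(rho)` where `R(rho)[s,t] = rho^|s-t|` is the
AR(1) correlation matrix. A cubic is the lowest degree able to represent
the non-monotone, multi-fluctuation trajectories seen in short
time-course expression data while remaining identifiable from 6 points;
`m >= 4` is required.

Fitting profiles the likelihood over `rho`: at fixed `rho` the
coefficient MLEs per group solve a 4x4 linear system built from the
quadratic form `Q(rho, U, V) = U R(rho)^{-1} V'` (computed in closed
form from the tridiagonal AR(1) inverse), and `sigma_e^2` is the
residual quadratic form divided by `mN`. Note the residual form is
`sum_i Q(y_i, y_i) - sum_g beta_g' b_g`; this is the stationary point of
the log-likelihood and is verified in the tests against a dense
multivariate-normal log-density evaluated at the fitted parameters. The
one-dimensional profile over `rho` is maximized on a grid over
[-0.99, 0.99] with step 0.01, refined by bounded scalar optimization in
the best bracket. `sigma_e^2` is floored at 1e-12 so noiseless
(interpolating) fits keep a defined log-likelihood.

The eQTL test is a likelihood ratio of the per-genotype fit against a
pooled single-curve fit. The statistic is referred to chi-square with
`4 (G - 1)` degrees of freedom (the tested mean-coefficient equalities;
`G` = number of genotype groups). This reference is advisory: the
profile construction makes the nominal p-values mildly anti-conservative
(simulated-null inflation factor ~1.03 in our checks), so genome-wide
error control uses permutation FDR, which is the authoritative
calibration. With `rho` constrained to 0 the test is monotone-equivalent
to the stacked cubic regression F-test, which the suite asserts as an
exact rank identity.

## Comparator association tests

* **static** — Wilcoxon rank-sum at one timepoint (default the first);
  exact enumeration when both groups have <= 25 strains and no ties,
  tie-corrected normal approximation otherwise.
* **union** — minimum over per-timepoint Wilcoxon p-values.
* **fisher** — the plain product of per-timepoint p-values, reported
  verbatim. It is a ranking score, not a calibrated tail probability;
  permutation FDR calibrates it. (The `-2 sum log p` chi-square
  combination orders datasets identically; the suite asserts this.)
* **manova** — one-way MANOVA of the m-vector on genotype, Pillai's
  trace with the standard F approximation (exact for two groups, where
  all four classical statistics coincide). Implemented directly for
  simulation throughput and verified against statsmodels in the tests.
* **regression** — all strains' timepoints stacked (`mN` observations),
  F-test of one shared cubic (4 parameters) against per-genotype cubics.
* **ar** — lag-one autoregression `Y_t ~ Y_{t-1}` stacked over strains,
  F-test of pooled vs per-genotype intercept/slope. This doubles as the
  independent-model Y-equation of the causality test.

### Missing data

Two policies, following how each method uses the data. The curve-fitting
methods (mptga, regression, ar) fit their per-genotype model on complete
strains, fill each missing cell from the fit (for the AR model,
chaining each strain's own lagged values forward; a missing first
timepoint falls back to the group mean), and run on the completed
matrix. The remaining methods (static, union, fisher, manova) drop
strains with any missing timepoint. This reproduces the qualitative
robustness result the package asserts: imputing methods lose <= 0.02
AUC at 10% missing cells, strain-dropping methods decay strictly with
the missing rate.

## Temporal genetic causality test (TGCT)

For traits X (cis at the locus) and Y (trans), five lag-one
autoregressive wirings are possible: causal (M1: X -> Y), reactive
(M2: Y -> X), independent (M3), and partial causal/reactive (M4/M5).
Each model is a pair of OLS regressions stacking `t = 2..m` over
strains (`n_obs = N (m - 1)` rows). The Gaussian log-likelihood with
the residual variance profiled out is

    ln L = -(n/2) ln(2 pi) - (n/2) ln(RSS) + (n/2) ln(n) - n/2 ,

where `n` counts **stacked observations**, not strains — the choice is
isolated in one function (`causality._profile_loglik`) and makes the
likelihood the exact profile likelihood of the regression it scores.
BIC is `ln(n) k - 2 ln L` with `k` counting regression coefficients
only: the profiled variance appears identically in every model, so
including it would shift all BICs equally.

Two modes:

* **Direction (M1 vs M2)** — joint log-likelihood `ln L(X) + ln L(Y)`
  under each wiring; equal parameter counts make the likelihood and BIC
  comparisons coincide. The call is antisymmetric under swapping the
  traits (asserted).
* **cis-trans selection (M1/M3/M4)** — with X cis-regulated, M2/M5 are
  excluded and the three remaining models share the X equation, so only
  the Y regressions enter: k = 3 (shared AR + causal lag), 4
  (per-genotype AR), 5 (per-genotype AR + causal lag). Smallest BIC
  wins; exact ties break toward the simpler model.

Both modes require the association filter: each trait linked at the
locus with MPTGA p < 1e-6 (configurable). Regulator ranking counts, per
cis gene at a hotspot, the trans partners whose best model is M1
(optionally also M4), and flags counts reaching the hotspot threshold.
Two cis genes with identical profiles tie and are both reported — the
test cannot distinguish them.

## Genome-scan utilities

* **Permutation FDR** — strain labels of the genotype matrix are
  permuted (expression untouched, preserving temporal correlation;
  marker LD intact); `FDR(p) = mean permuted hits / real hits`, the
  curve made monotone by a cumulative-minimum sweep before the cutoff
  lookup (raw values also reported). Default 10 permutations.
* **Hotspots** — the genome is cut into 20 kb bins; each significant
  trait contributes its peak marker per chromosome. The hotspot
  threshold `N0` is the smallest count whose binomial tail
  `P(Binom(n_total, 1/B) >= N0)` falls below `0.05/B` (`B` = number of
  bins); adjacent significant bins are merged.
* **Location confidence intervals** — `R(d) = 2 [ll(eQTL at d) -
  ll(no eQTL)]` profiles the MPTGA likelihood along a chromosome;
  `T(d0) = max R - R(d0)` is referred to the upper-alpha chi-square
  quantile (df exposed, default 1). The literal lower-alpha quantile
  would make intervals nearly empty; the upper quantile reproduces
  ~(1 - alpha) empirical coverage in the coverage study.
* **Validity and overfitting** — QQ summaries with a genomic-control
  style inflation factor; and a peak-vs-LD-neighbor consistency check:
  for significant peaks, the correlation of `-log10 p` with flanking
  markers of genotype concordance >= 0.9 within +/-2 positions. Models
  fitted to genuine signal transfer to near-identical genotypes; models
  fitted to noise do not.
* **Enrichment** — one-sided hypergeometric test plus fold enrichment,
  for user-supplied gene sets.

## Synthetic data

The generator produces exactly the structures the analyses assume:

* **Patterns** — 8 named cubic trajectories on `t = 1..6` with
  amplitude ~[-1, 1]: flat, linear up/down, peak, dip, two two-turn
  shapes, and a saturating rise. They span the qualitative shapes of
  short expression time courses (non-monotone, up to two fluctuations).
* **Traits** — MVN draws around the genotype group's pattern with
  `sigma_e^2 AR1(rho)` covariance; `rho` is drawn once per dataset from
  `N(rho_mean, rho_sd)` truncated to [0, 0.99] (defaults
  `N(0.9, 0.02)` high-correlation, `N(0.1, 0.02)` low). `noise_sd`
  defaults to 0.5, about half the pattern amplitude. An `effect_scale`
  knob shrinks the group-1 pattern toward group 0 (0 = no eQTL).
* **Genotypes** — iid Bernoulli(0.5) markers, or an LD chain where each
  marker copies its neighbor and flips with a given probability
  (adjacent concordance `1 - p`).
* **Trait pairs** — X as above with `rho ~ N(0.8, 0.1)`; Y generated
  from the chosen model's recursion with iid noise (sd 0.5), started at
  the stationary marginal of Y's own recursion (causal inputs held at
  their genotype-group mean at t = 1). The coefficient grid for the
  evaluation studies is `beta1 in {0.2, 0.4, 0.6, 0.8}`, `beta2 in
  {0.3, 0.5, 0.8, 1.0}`, genotype intercept offsets in {0.5, 1.0}, one
  cell drawn uniformly per replicate.
* **Missing data** — iid cell masking at rates 0.02-0.1 (higher rates
  warn); values are preserved under the mask so imputation can be
  checked against truth.

What the synthetic data does **not** emulate: count-based measurement
noise (traits are Gaussian), realistic recombination maps and LD decay
(the chain model has geometric decay only), polygenic or multi-locus
architecture, and feedback loops between traits. Passing tests
demonstrate correctness of the inference machinery under the stated
models, not robustness to those real-data complications.

## Study conditions and problem sizes

The evaluation studies fix their conditions once:

* Method-comparison and robustness sweeps: N = 30 strains,
  `effect_scale = 0.35`, chosen so the operating point sits in the
  informative mid-range of the ROC rather than at saturation; 2,000
  datasets per regime (AUC Monte-Carlo SE ~0.01).
* Causality-test accuracy: 2,000 retained pairs per panel size
  N in {20, 50, 100, 150}, the association filter applied throughout.
* CI coverage: 500 replicates, 15-marker LD chain (flip probability
  0.02), `effect_scale = 0.3` — weak enough that location uncertainty
  is real and the interval is non-degenerate.

## Known limitations

* The nominal MPTGA p-value is mildly anti-conservative; use the
  permutation FDR for error control (the package's defaults do).
* The Fisher product is a score, not a p-value; compare only within a
  scan calibrated by the same permutation scheme.
* TGCT assumes lag-one dynamics on the measurement grid; causal effects
  faster than the sampling interval masquerade as contemporaneous
  correlation and can be mis-oriented. Feedback loops are outside the
  model family.
* With two cis candidates of near-identical trajectories the regulator
  ranking ties by construction.
* MANOVA requires `N > m + G` complete strains; short panels with heavy
  missingness can make it inapplicable while the imputing methods still
  run.
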