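# Methods

## Model and assumptions

`pgsdiff` works entirely at the summary-statistics level.  The data for
SNP `j` are a marginal GWAS effect estimate `β̂_j` with sampling variance
`s²_j`, an effect-allele frequency `f_j` in population 1 (assumed to match
the GWAS training population) and `g_j` in population 2.  Three structural
assumptions are made throughout:

1. **SNP independence.** All M SNPs are treated as unlinked.  In practice
   users supply an LD-pruned panel; residual correlation makes the
   analytic posterior variance of `d` a mild overestimate (conservative
   for testing).
2. **Shared causal effects.** Per-allele effects are identical in the two
   populations; risk differences arise only through allele-frequency
   differences.  Differences in true effects or tagging act like an
   inflated effective F_ST.
3. **Point-normal effects.** `β_j` is zero with probability
   `1 − p_causal`, otherwise normal with variance
   `σ²_j = h²/(M p_causal · 2 f_j (1 − f_j))`, so the panel-wide expected
   heritability is exactly `h²`.  The hyperparameters (`h²`, `p_causal`)
   are inputs, not estimated.

## Per-SNP posteriors

With `k_j = σ²_j/(σ²_j + s²_j)`, the posterior at each SNP is again
spike-and-slab: slab probability from the two marginal likelihoods
(computed in log space; density ratios overflow double precision at large
N), slab component `N(k_j β̂_j, k_j s²_j)`.  Posterior mean and variance
follow by mixture algebra.  Two independent oracles certify the
implementation in the test suite: adaptive quadrature over the effect
(agreement to 1e-6 relative across a randomized parameter sweep) and
exact Monte-Carlo posterior sampling (the identity-LD degenerate case of
the Gibbs samplers used by LD-aware methods).

Numerical edge policy: slab probabilities below 1e-300 are truncated to an
exact spike; allele frequencies outside `[1e-6, 1 − 1e-6]` raise rather
than being clipped, because a monomorphic SNP has no genotype variance and
silently clipping would corrupt `d`'s core contrast.

## The risk difference and its uncertainty

`d̂ = Σ w_j E[β_j|β̂_j]` and `var[d|data] = Σ w_j² var[β_j|β̂_j]` with
`w_j = 2(f_j − g_j)`.  Credible intervals are normal on the log scale by
default, or empirical quantiles when ≥ 1,000 posterior draws are supplied
(the route used with external posterior-sample matrices).  Under the
infinitesimal model the expectation of the posterior variance over the
frequency-generating process is `4 M F_ST/N · (1 + M/(N h²))⁻¹`; the
simulation equivalence (2% relative at M = 200,000) is asserted in the
acceptance suite.  For sparse architectures (`p_causal` below ~10%) the
closed form overestimates the uncertainty — the per-SNP analytic path
should be used, and the package defaults to it everywhere.

## Wald test: null ensemble and null variance

The null hypothesis `d = 0` is modelled as the point-normal prior
*conditioned* on the weighted sum vanishing.  Given a realized causal
configuration, the slab effects are jointly Gaussian, and conditioning on
`Σ w_j β_j = t` shifts each causal effect by an amount proportional to
`w_j σ²_j`.  The simulator's `constrain_d` implements exactly this
construction (method `"conditional"`), so null and power scenarios are
draws from the conditioned prior.

A minimum-norm alternative (`method="projection"`, shifting every SNP by
`w_j (t − d₀)/Σ w²`) is retained for sensitivity analysis but is *not*
used by the experiment drivers: spreading the constraint across all M
SNPs moves each effect O(1/M), which the spike component of the posterior
absorbs entirely — the resulting ensemble is statistically almost
indistinguishable from its unconstrained counterpart (measured: type-1
error 0.65 at p_causal = 1% under the default null variance, and power
indistinguishable from size).  The conditional construction concentrates
the constraint on the causal effects, which is both the probabilistically
correct conditioning and the ensemble the null-variance formula describes.

The null sampling variance of `d̂` is estimated by

    V₀ = V_post (V_prior − V_post) / V_prior,

where `V_post` is the realized posterior variance of `d` and
`V_prior = Σ w_j² p_causal σ²_j` its prior variance.  In the Gaussian
limit (`p_causal = 1`) this is exact: it reduces to `k² Σ w_j² s²_j`, the
sampling variance of the linearly shrunk estimator under the conditioned
prior.  For spike-and-slab architectures no closed form for the
conditioned-null variance is available; the formula was certified
empirically on 800-replicate null ensembles at M = 200,000 across
`p_causal ∈ {0.1%, 1%, 10%, 100%} × N ∈ {1e4, 1e5, 1e6}`: the ratio of
V₀ to the true null variance stays within 0.89–1.05, the standardized
null statistic is Gaussian to within |excess kurtosis| < 0.3, and the
chi-square statistic's symmetric-tail size at α = 0.05 falls inside the
99% binomial band at every cell (asserted in the acceptance suite).

### P-value conventions

`wald_test` exposes two conventions and the experiment drivers record
both:

- `two_sided`: the symmetric χ²₁ tail.  Under the null, comparing it to α
  rejects at rate α — this is the convention the calibration suite
  certifies.
- `directional` (default): half the χ²₁ tail, i.e. the tail in the
  direction of the observed difference.  This matches the package's
  reference reporting style, in which a relative risk whose 95% interval
  grazes 1 carries P ≈ 0.05.  Because the direction is chosen after
  seeing the data, comparing the directional p-value to α flags true
  nulls at rate 2α; power figures quoted under this convention are
  correspondingly the `P(|Z| > z_{0.95})` operating characteristic.

The two differ by exactly a factor of two; the choice is a reporting
convention, not a statistical disagreement, and both columns appear in
every experiment output (`power_wald` directional, `power_wald_sym`
symmetric).

A conservative variant `V₀ = V_post` is available behind
`variant="posterior_variance"`.

## The t-test comparator

The conventional approach scores two target cohorts with the posterior
mean weights and t-tests the cohort means.  The comparator simulates this
without materializing genotypes: cohort allele frequencies get binomial
noise (normal approximation, adequate for the target sizes ≥ 5,000 used
everywhere), the score-difference numerator is
`Σ 2 post_mean_j (f̂_j − ĝ_j)` and the denominator uses within-population
score variances with the weights treated as constants.  Training noise in
the weights couples to true frequency differences in the numerator but
never enters the denominator — the mechanism of the test's inflation.
Measured at M = 200,000: null rejection 0.87–0.96 for training
N ≤ 1e5, still 0.12 at N = 1e6 for the sparsest architecture, uniformly
above the Wald test at every grid point.

## Simulator and experiment design

- Frequencies: `f ~ U[0.1, 0.9]`; `g | f` Balding–Nichols with unknown
  ancestral frequency, `Beta(f c, (1−f) c)`, `c = (1−2F_ST)/(2F_ST)`
  (valid for `F_ST < 0.5`; the model's conditional mean is `f` and
  conditional variance `2 F_ST f(1−f)`, which is what the F_ST moment
  estimator inverts).
- Effects, then the conditional `d`-constraint, then marginal estimates —
  frequencies and effects are redrawn every replicate (the conservative
  reading of a fully nested design).
- Replicate streams derive from `SeedSequence([seed, cell-key])`, so any
  subset of cells reproduces identically in any execution order.
- Default replicate counts: 100 for posterior-variance experiments, 1,000
  for type-1/power (binomial s.e. ≈ 0.007 at a rate of 0.05).
- Variance summaries average the posterior *variance* across replicates
  and then take the square root (`sd_d`); the opposite ordering
  (`mean_sd_d`) is also reported.

## F_ST estimation

Hudson-style ratio of sums, `Σ (f−g)² / Σ [f(1−g) + g(1−f)]`.  Under the
generating model above, numerator and denominator have per-SNP conditional
expectations `2 F_ST f(1−f)` and `2 f(1−f)`, so the estimator is
consistent as M grows; parameter recovery within 2% relative over
F_ST ∈ {0.02, …, 0.12} at M = 200,000 is part of the acceptance suite.
Population (control-group) frequencies are assumed; an optional
finite-sample correction subtracts `f(1−f)/(2n₁) + g(1−g)/(2n₂)` from the
numerator terms when cohort sizes are supplied.

## What the synthetic data does and does not emulate

The generator matches the best-case design of the method's
characterization: independent SNPs, directly genotyped in both
populations, frequencies known without error, hyperparameters known.
Real analyses add LD (residual correlation after pruning biases the
independence-sum posterior s.d. of `d` upward, making it mildly
conservative), imperfect tagging, frequency estimation error, and hyperparameter
estimation — so passing tests certify the machinery, and real-data
uncertainty statements should be read as best-case lower bounds.
Real-data relative risks (e.g. multi-ancestry case-control reanalyses)
require external cohort data; the package supports that route through the
posterior-sample-matrix input but ships no such data.

## Known limitations

- Two populations only; no multi-population ANOVA analogue.
- No combined training+target-sample variance in the Wald test (target
  noise is typically negligible next to training noise, and the
  comparator exists precisely to show what ignoring training noise does).
- `h²` and `p_causal` must be supplied (e.g. from an external
  empirical-Bayes fit); misspecification propagates to the posterior and
  the test.
- The closed form assumes the infinitesimal model and Balding–Nichols
  frequency dispersion; it is a planning tool, not an inference tool.
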