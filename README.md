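# pgsdiff

Bayesian estimation and testing of **population differences in polygenic
risk** from GWAS summary statistics.

## The problem

Comparing mean polygenic scores between two populations is a common way to
ask whether disease-risk differences have a genetic basis.  The standard
t-test/ANOVA approach treats the score weights as noise-free, but they come
from a finite GWAS training sample; ignoring that noise inflates type-1
error catastrophically — a true null is rejected most of the time at
realistic training sizes.  `pgsdiff` implements a summary-statistics
Bayesian framework that accounts for training-sample uncertainty, for
statistical geneticists working with LD-pruned variant panels and
per-population allele frequencies.

## The model

For M approximately independent SNPs with effect-allele frequencies `f_j`
(population 1) and `g_j` (population 2), and per-allele effects `β_j`, the
difference in mean genetic value on the log-risk scale is

    d = Σ_j 2 (f_j − g_j) β_j,      RR = exp(d).

Effects carry a point-normal (spike-and-slab) prior,
`β_j ~ p_causal · N(0, h²/(M p_causal · 2 f_j(1−f_j))) + (1−p_causal) · δ₀`,
and marginal GWAS estimates are `β̂_j ~ N(β_j, 1/(2N f_j(1−f_j)))`.  The
per-SNP posteriors are conjugate spike-and-slab mixtures with closed-form
moments, giving

    d̂ = Σ_j w_j E[β_j | β̂_j],      var[d | data] = Σ_j w_j² var[β_j | β̂_j],

with `w_j = 2(f_j − g_j)`.  Under the infinitesimal model (`p_causal = 1`)
the expected posterior variance has the closed form
`4 M F_ST / N · (1 + M/(N h²))⁻¹`.  A Wald test of `d = 0` divides `d̂²` by
an estimate of its null sampling variance (see `docs/methods.md`); a
Hudson-style ratio-of-sums moment estimator provides `F_ST`; and a built-in
summary-statistics simulator reproduces the full operating-characteristics
study (posterior uncertainty, calibration, power, bias/MSE).

## Worked example

```bash
python examples/01_risk_difference_from_sumstats.py
```

```
posterior mean d      = 0.3196  (truth: 0.4055)
posterior s.d. of d   = 0.0686
relative risk         = 1.38  (95% CrI 1.20-1.57)
Wald chi2 = 22.25, p = 1.20e-06
```

A true relative risk of 1.5 between the populations is recovered as a
posterior mean RR of 1.38 (shrinkage pulls `d̂` toward zero at finite
training N) with a credible interval that honestly reflects the
training-sample noise; the Wald test rejects the null of equal genetic
risk.  `examples/02_...` shows how posterior uncertainty scales with
polygenicity, and `examples/03_...` demonstrates the t-test's inflation
against the Wald test's calibration.

The same analyses run from the shell:

```bash
pgsdiff simulate --m 50000 --h2 0.5 --p-causal 0.01 --fst 0.1 \
    --n-eff 100000 --rr 1.5 --seed 42 --out sim
pgsdiff sd --sumstats sim.sumstats.tsv --freq1 sim.freq1.tsv \
    --freq2 sim.freq2.tsv --h2 0.5 --p-causal 0.01 --out result.tsv
pgsdiff fst --freq1 sim.freq1.tsv --freq2 sim.freq2.tsv
```

Real GWAS inputs (tab-separated summary statistics with auto-detected
column headers, per-population frequency tables, or an exported
posterior-sample matrix from an LD-aware sampler) go through the same
`sd` command; alleles are harmonized, strand-ambiguous SNPs dropped.

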