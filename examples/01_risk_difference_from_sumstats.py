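"""Estimate the genetic relative risk between two populations.

Simulates a small GWAS summary-statistics panel with a true log relative
risk of log(1.5) between populations, then runs the full analytic
pipeline: per-SNP spike-and-slab posteriors, the posterior mean and
variance of d, the relative risk with its credible interval, and the Wald
test against d = 0.
"""

import numpy as np

from pgsdiff import (
    ArchitectureConfig,
    constrain_d,
    d_point,
    d_posterior_variance,
    posterior_moments_panel,
    simulate_effects,
    simulate_frequencies,
    simulate_sumstats,
    summarize,
    wald_test,
)

M = 50_000           # LD-pruned SNP panel size
arch = ArchitectureConfig(h2=0.5, p_causal=0.01, M=M)
rng = np.random.default_rng(42)

panel = simulate_frequencies(M, fst=0.1, seed=rng)       # two populations
beta = simulate_effects(panel, arch, seed=rng)           # true effects
beta = constrain_d(beta, panel, np.log(1.5), arch=arch)  # true RR = 1.5
stats = simulate_sumstats(beta, panel, N_eff=100_000, seed=rng)

post = posterior_moments_panel(stats, panel, arch)
d_hat = d_point(post, panel)
d_var = d_posterior_variance(post, panel)
res = summarize(d_hat, d_var)
test = wald_test(d_hat, post, panel, arch)

print(f"posterior mean d      = {d_hat:.4f}  (truth: {np.log(1.5):.4f})")
print(f"posterior s.d. of d   = {res.d_sd:.4f}")
print(f"relative risk         = {res.rr:.2f}  (95% CrI {res.ci_low:.2f}-{res.ci_high:.2f})")
print(f"Wald chi2 = {test.statistic:.2f}, p = {test.p_value:.2e}")
print()
print("The posterior mean is shrunk toward zero relative to the truth; the")
print("credible interval quantifies training-sample uncertainty that a naive")
print("polygenic-score comparison would ignore entirely.")
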