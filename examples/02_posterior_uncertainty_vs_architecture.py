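"""How uncertainty in the risk difference depends on the architecture.

Sweeps polygenicity at a fixed training sample size and compares the
simulated posterior s.d. of d with the closed-form infinitesimal
approximation.  Uses a reduced panel (M = 20,000) so it runs in seconds;
the qualitative pattern matches the full-scale study.
"""

import numpy as np

from pgsdiff import ArchitectureConfig, ExperimentGrid, closed_form_variance, run_sd_experiment

M = 20_000
grid = ExperimentGrid(
    h2=(0.5,), p_causal=(0.001, 0.01, 0.1, 1.0), fst=(0.1,),
    n_eff=(100_000,), n_reps=20, seed=1,
)
df = run_sd_experiment(grid, M=M)

cf = np.sqrt(closed_form_variance(
    ArchitectureConfig(h2=0.5, p_causal=1.0, M=M), fst=0.1, N_eff=100_000
))

print(df[["p_causal", "sd_d"]].to_string(index=False))
print(f"\nclosed-form (infinitesimal) s.d.: {cf:.3f}")
print()
print("Posterior uncertainty grows steeply with polygenicity: sparse")
print("architectures concentrate the signal in few, well-estimated SNPs.")
print("The closed form is accurate only near p_causal = 1; below ~10% it")
print("overstates the uncertainty and the per-SNP analytic path should be used.")
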