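"""Type-1 error of the Wald test versus the naive polygenic-score t-test.

Simulates null scenarios (no true risk difference) and counts how often
each test rejects at alpha = 0.05.  The t-test compares mean scores in
two target cohorts while treating the score weights as noise-free, so
training-sample error masquerades as population differences.  Reduced
panel and replicate count for speed.
"""

from pgsdiff import ExperimentGrid, run_frequentist_experiment

grid = ExperimentGrid(
    h2=(0.5,), p_causal=(0.1,), fst=(0.1,),
    n_eff=(10_000, 100_000, 1_000_000), rr=(1.0,),  # rr=1: null
    n_reps=100, alpha=0.05, seed=2,
)
df = run_frequentist_experiment(grid, M=20_000, target_n=5000)

print(df[["n_eff", "power_wald_sym", "power_wald", "power_t"]]
      .rename(columns={"power_wald_sym": "wald_symmetric",
                       "power_wald": "wald_directional",
                       "power_t": "t_test"})
      .to_string(index=False))
print()
print("The Wald chi-square statistic rejects near its nominal 5% rate")
print("(the directional convention, which halves p-values, flags nulls at")
print("about twice that by construction).  The t-test rejects the true null")
print("most of the time at realistic training sizes - the central warning")
print("of this package.")
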