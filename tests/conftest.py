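import numpy as np
import pytest

from pgsdiff import (
    ArchitectureConfig,
    PopulationPanel,
    simulate_effects,
    simulate_frequencies,
    simulate_sumstats,
)


@pytest.fixture
def small_panel() -> PopulationPanel:
    rng = np.random.default_rng(42)
    f = rng.uniform(0.1, 0.9, 50)
    g = np.clip(f + rng.normal(0, 0.05, 50), 0.05, 0.95)
    return PopulationPanel(f=f, g=g)


@pytest.fixture
def arch() -> ArchitectureConfig:
    return ArchitectureConfig(h2=0.5, p_causal=0.01, M=50)


@pytest.fixture
def simulated_dataset():
    """A mid-size simulated dataset: panel, effects, summary stats."""
    arch = ArchitectureConfig(h2=0.5, p_causal=0.1, M=2000)
    rng = np.random.default_rng(7)
    panel = simulate_frequencies(arch.M, 0.1, rng)
    beta = simulate_effects(panel, arch, rng)
    stats = simulate_sumstats(beta, panel, 100_000, rng)
    return arch, panel, beta, stats
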