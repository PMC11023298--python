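"""Per-SNP posterior moments against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import norm

from pgsdiff import (
    ArchitectureConfig,
    PopulationPanel,
    SummaryStats,
    posterior_moments,
    posterior_moments_panel,
    prior_slab_variance,
    sample_posterior,
    sampling_variance,
)


def quadrature_moments(beta_hat, s2, sigma2, p_causal):
    """Brute-force posterior moments by numerical integration over beta.

    The posterior is a point mass at zero plus a continuous part
    proportional to p * N(beta; 0, sigma2) * N(beta_hat; beta, s2); every
    normalizing constant and moment is computed by adaptive quadrature so
    the oracle shares no algebra with the implementation under test.  The
    problem is rescaled to unit marginal variance first (posterior moments
    scale linearly/quadratically), keeping densities away from underflow.
    """
    c = np.sqrt(sigma2 + s2)
    beta_hat, s2, sigma2 = beta_hat / c, s2 / c**2, sigma2 / c**2
    s = np.sqrt(s2)
    sig = np.sqrt(sigma2)

    def cont(b):
        return p_causal * norm.pdf(b, 0, sig) * norm.pdf(beta_hat, b, s)

    lim = 10 * max(sig, s) + abs(beta_hat)
    # the integrand peaks near the (possibly very narrow) likelihood mode;
    # hand the quadrature explicit breakpoints so it cannot miss it
    pts = sorted({-abs(beta_hat), 0.0, abs(beta_hat)})
    kw = dict(limit=800, points=pts, epsabs=0.0, epsrel=1e-11)
    z_cont, _ = integrate.quad(cont, -lim, lim, **kw)
    z_spike = (1 - p_causal) * norm.pdf(beta_hat, 0, s)
    z = z_cont + z_spike
    m1, _ = integrate.quad(lambda b: b * cont(b), -lim, lim, **kw)
    m2, _ = integrate.quad(lambda b: b * b * cont(b), -lim, lim, **kw)
    slab_prob = z_cont / z
    mean = m1 / z
    var = m2 / z - mean**2
    return slab_prob, mean * c, var * c**2


class TestScalarMoments:
    def test_pure_gaussian_limit(self):
        """p_causal=1 collapses to plain Gaussian shrinkage."""
        s2, sigma2, bh = 1e-5, 4e-5, 0.01
        k = sigma2 / (sigma2 + s2)
        sp, pm, pv = posterior_moments(bh, s2, sigma2, 1.0)
        assert sp[0] == 1.0
        assert pm[0] == pytest.approx(k * bh, rel=1e-12)
        assert pv[0] == pytest.approx(k * s2, rel=1e-12)

    def test_zero_estimate_gives_zero_mean(self):
        for p in (0.01, 0.5, 1.0):
            _, pm, _ = posterior_moments(0.0, 1e-5, 1e-4, p)
            assert pm[0] == 0.0

    def test_matches_quadrature_at_reference_point(self):
        """The motivating parameter point: f=0.5, N=1e4, h2=0.5, M=2e5, p=1%."""
        f, N, h2, M, p = 0.5, 10_000, 0.5, 200_000, 0.01
        s2 = 1 / (2 * N * f * (1 - f))
        sigma2 = h2 / (M * p * 2 * f * (1 - f))
        bh = 0.01
        sp, pm, pv = posterior_moments(bh, s2, sigma2, p)
        qsp, qpm, qpv = quadrature_moments(bh, s2, sigma2, p)
        assert sp[0] == pytest.approx(qsp, rel=1e-8)
        assert pm[0] == pytest.approx(qpm, rel=1e-8)
        assert pv[0] == pytest.approx(qpv, rel=1e-8)

    def test_matches_quadrature_over_random_grid(self):
        """Randomized sweep of (f, N, h2, p, beta_hat) vs the oracle."""
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(60):
            f = rng.uniform(0.05, 0.95)
            N = 10 ** rng.uniform(3, 6.5)
            h2 = rng.uniform(0.05, 0.8)
            p = 10 ** rng.uniform(-3, 0)
            M = 10 ** rng.uniform(3, 5.5)
            s2 = 1 / (2 * N * f * (1 - f))
            sigma2 = h2 / (M * p * 2 * f * (1 - f))
            bh = rng.normal(0, np.sqrt(sigma2 + s2))
            sp, pm, pv = posterior_moments(bh, s2, sigma2, p)
            qsp, qpm, qpv = quadrature_moments(bh, s2, sigma2, p)
            # floor the scale: when the posterior is an exact spike both
            # paths return 0 and the comparison is vacuous
            scale = max(abs(qpm), np.sqrt(qpv), 1e-9 * np.sqrt(sigma2 + s2))
            worst = max(worst, abs(pm[0] - qpm) / scale, abs(pv[0] - qpv) / scale**2)
        assert worst < 1e-6

    def test_extreme_inputs_do_not_overflow(self):
        """Huge density ratios must resolve to exact spike/slab limits."""
        sp, pm, pv = posterior_moments(5.0, 1e-10, 1e-4, 0.5)
        assert sp[0] == 1.0  # overwhelming evidence for the slab
        sp, pm, pv = posterior_moments(0.0, 1e-10, 1.0, 1e-10)
        assert sp[0] < 1e-4
        assert np.isfinite(pv).all()

    def test_nonpositive_variances_raise(self):
        with pytest.raises(ValueError):
            posterior_moments(0.1, 0.0, 1e-4, 0.5)
        with pytest.raises(ValueError):
            posterior_moments(0.1, 1e-5, -1.0, 0.5)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    bh=st.floats(-1.0, 1.0),
    log_s2=st.floats(-12, 1),
    log_sigma2=st.floats(-12, 1),
    p=st.floats(1e-6, 1.0),
)
def test_posterior_variance_never_negative(bh, log_s2, log_sigma2, p):
    _, _, pv = posterior_moments(bh, 10**log_s2, 10**log_sigma2, p)
    assert pv[0] >= 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(bh=st.floats(-0.5, 0.5), log_ratio=st.floats(-4, 4))
def test_gaussian_shrinkage_contracts(bh, log_ratio):
    """|post_mean| <= |beta_hat| when p_causal = 1."""
    s2 = 1e-4
    sigma2 = s2 * 10**log_ratio
    _, pm, _ = posterior_moments(bh, s2, sigma2, 1.0)
    assert abs(pm[0]) <= abs(bh) + 1e-15


def test_consistency_as_n_grows():
    """With beta_hat fixed at the truth, the posterior concentrates there."""
    beta = 0.004
    sigma2 = 1e-4
    for p in (0.05, 1.0):
        for N in (1e8, 1e10):
            s2 = 1 / (2 * N * 0.25)
            _, pm, pv = posterior_moments(beta, s2, sigma2, p)
        assert pm[0] == pytest.approx(beta, rel=1e-3)
        assert pv[0] < 1e-9


class TestPanelMoments:
    def test_single_snp_panel_matches_scalar(self):
        panel = PopulationPanel(f=np.array([0.4]), g=np.array([0.3]))
        arch = ArchitectureConfig(h2=0.3, p_causal=0.2, M=1)
        stats = SummaryStats.from_n_eff(np.array([0.02]), panel.f, 5000)
        post = posterior_moments_panel(stats, panel, arch)
        sigma2 = prior_slab_variance(panel.f, arch)
        sp, pm, pv = posterior_moments(0.02, stats.s2, sigma2, 0.2)
        assert post.post_mean[0] == pytest.approx(pm[0], rel=1e-14)
        assert post.post_var[0] == pytest.approx(pv[0], rel=1e-14)

    def test_infinitesimal_null_shrinkage_constant(self):
        """With p=1 and beta_hat=0, post_var = k s2 and k = Nh2/(Nh2+M).

        The 2f(1-f) factor cancels between slab and sampling variances, so
        the shrinkage factor is the same for every SNP.
        """
        M, N, h2 = 100, 1000, 0.5
        rng = np.random.default_rng(3)
        f = rng.uniform(0.1, 0.9, M)
        panel = PopulationPanel(f=f, g=f)
        arch = ArchitectureConfig(h2=h2, p_causal=1.0, M=M)
        stats = SummaryStats.from_n_eff(np.zeros(M), f, N)
        post = posterior_moments_panel(stats, panel, arch)
        k = N * h2 / (N * h2 + M)
        np.testing.assert_allclose(post.post_var, k * stats.s2, rtol=1e-12)

    def test_alignment_error(self, small_panel):
        arch = ArchitectureConfig(h2=0.5, p_causal=0.1, M=10)
        stats = SummaryStats(beta_hat=np.zeros(10), s2=np.full(10, 1e-5))
        with pytest.raises(ValueError, match="aligned"):
            posterior_moments_panel(stats, small_panel, arch)

    def test_mean_posterior_variance_matches_sampling(self, simulated_dataset):
        """Panel posterior variance agrees with exact posterior sampling."""
        arch, panel, beta, stats = simulated_dataset
        post = posterior_moments_panel(stats, panel, arch)
        draws = sample_posterior(stats, panel, arch, n_iter=1100, burn_in=100, seed=5)
        mc_var = draws.var(axis=1).mean()
        an_var = post.post_var.mean()
        # MC s.e. of a mean of 2000 per-SNP variances at 1000 draws
        assert mc_var == pytest.approx(an_var, rel=0.05)


class TestPosteriorSampler:
    def test_gaussian_case_sample_mean(self):
        M, N = 300, 10_000
        rng = np.random.default_rng(8)
        f = rng.uniform(0.2, 0.8, M)
        panel = PopulationPanel(f=f, g=f)
        arch = ArchitectureConfig(h2=0.5, p_causal=1.0, M=M)
        bh = rng.normal(0, 0.01, M)
        stats = SummaryStats.from_n_eff(bh, f, N)
        sigma2 = prior_slab_variance(f, arch)
        k = sigma2 / (sigma2 + stats.s2)
        draws = sample_posterior(stats, panel, arch, n_iter=2100, burn_in=100, seed=1)
        se = np.sqrt(k * stats.s2 / draws.shape[1])
        z = (draws.mean(axis=1) - k * bh) / se
        assert np.abs(z.mean()) < 3 / np.sqrt(M)
        assert np.abs(z).max() < 5

    def test_deterministic_under_seed(self, simulated_dataset):
        arch, panel, beta, stats = simulated_dataset
        a = sample_posterior(stats, panel, arch, n_iter=60, burn_in=10, seed=9)
        b = sample_posterior(stats, panel, arch, n_iter=60, burn_in=10, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_iteration_counts(self, simulated_dataset):
        arch, panel, beta, stats = simulated_dataset
        with pytest.raises(ValueError):
            sample_posterior(stats, panel, arch, n_iter=10, burn_in=10)
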