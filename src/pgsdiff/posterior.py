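"""Analytic per-SNP posterior moments under the point-normal prior.

With a spike-and-slab prior ``beta ~ p N(0, sigma2) + (1-p) delta_0`` and a
Gaussian likelihood ``beta_hat | beta ~ N(beta, s2)``, the posterior at each
SNP is again a spike-and-slab mixture.  Writing ``k = sigma2/(sigma2+s2)``
for the shrinkage factor, the slab component of the posterior is
``N(k beta_hat, k s2)`` and the posterior slab probability is the Bayes
factor combination of the two marginal likelihoods

    slab_prob = p phi(beta_hat; 0, sigma2+s2)
                / [p phi(beta_hat; 0, sigma2+s2) + (1-p) phi(beta_hat; 0, s2)]

computed in log space (the density ratio overflows for large training
sample sizes).  The first two posterior moments follow:

    post_mean = slab_prob * k * beta_hat
    post_var  = slab_prob * (k s2 + (k beta_hat)^2) - post_mean^2

``sample_posterior`` draws exact independent samples from these per-SNP
posteriors; because the SNPs are modelled as independent, this is the
degenerate (identity-LD) case of the Gibbs samplers used by LD-aware
methods, and serves as a Monte-Carlo cross-check on every analytic
expression in the package.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model import ArchitectureConfig, PopulationPanel, PosteriorSummary, SummaryStats
from .model import prior_slab_variance

__all__ = ["posterior_moments", "posterior_moments_panel", "sample_posterior"]

#: Posterior slab probabilities below this threshold are truncated to an
#: exact spike (mean and variance zero); the mixture weight has underflowed
#: past any meaningful precision.
_SLAB_PROB_FLOOR = 1e-300


def posterior_moments(
    beta_hat: ArrayLike,
    s2: ArrayLike,
    sigma2: ArrayLike,
    p_causal: float,
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Posterior slab probability, mean and variance at each SNP.

    Parameters
    ----------
    beta_hat : array_like
        Marginal GWAS effect estimates.
    s2 : array_like
        Sampling variances of ``beta_hat``, strictly positive.
    sigma2 : array_like
        Prior slab variances, strictly positive.
    p_causal : float
        Prior probability of a nonzero effect, in (0, 1].

    Returns
    -------
    slab_prob, post_mean, post_var : ndarray
        Elementwise posterior summaries.  ``post_var`` is non-negative.
    """
    beta_hat = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    s2 = np.broadcast_to(np.asarray(s2, dtype=float), beta_hat.shape)
    sigma2 = np.broadcast_to(np.asarray(sigma2, dtype=float), beta_hat.shape)
    if np.any(s2 <= 0):
        raise ValueError("sampling variances s2 must be strictly positive")
    if np.any(sigma2 <= 0):
        raise ValueError("prior slab variances sigma2 must be strictly positive")
    if not 0.0 < p_causal <= 1.0:
        raise ValueError(f"p_causal must be in (0, 1], got {p_causal}")

    k = sigma2 / (sigma2 + s2)
    if p_causal == 1.0:
        slab_prob = np.ones_like(beta_hat)
    else:
        # log marginal densities under slab and spike; the 2*pi constant cancels
        log_slab = (
            np.log(p_causal)
            - 0.5 * np.log(sigma2 + s2)
            - 0.5 * beta_hat**2 / (sigma2 + s2)
        )
        log_spike = np.log1p(-p_causal) - 0.5 * np.log(s2) - 0.5 * beta_hat**2 / s2
        # slab_prob = 1 / (1 + exp(log_spike - log_slab)), stable in both tails
        slab_prob = 1.0 / (1.0 + np.exp(np.clip(log_spike - log_slab, -745, 745)))
        slab_prob = np.where(slab_prob < _SLAB_PROB_FLOOR, 0.0, slab_prob)

    cond_mean = k * beta_hat  # slab-conditional posterior mean
    post_mean = slab_prob * cond_mean
    post_var = slab_prob * (k * s2 + cond_mean**2) - post_mean**2
    # exact algebra guarantees non-negativity; clip floating-point dust
    return slab_prob, post_mean, np.maximum(post_var, 0.0)


def posterior_moments_panel(
    stats: SummaryStats,
    panel: PopulationPanel,
    arch: ArchitectureConfig,
    *,
    slab_freqs: NDArray[np.float64] | None = None,
) -> PosteriorSummary:
    """Posterior summaries for a whole panel.

    Prior slab variances are computed from the population-1 frequencies of
    ``panel`` by default; pass ``slab_freqs`` (e.g. the training-sample
    frequency column of a summary-statistics file) to override.
    """
    if stats.M != panel.M:
        raise ValueError(
            f"summary statistics ({stats.M} SNPs) and panel ({panel.M} SNPs) "
            "are not aligned"
        )
    freqs = panel.f if slab_freqs is None else np.asarray(slab_freqs, dtype=float)
    sigma2 = prior_slab_variance(freqs, arch)
    slab_prob, post_mean, post_var = posterior_moments(
        stats.beta_hat, stats.s2, sigma2, arch.p_causal
    )
    return PosteriorSummary(slab_prob=slab_prob, post_mean=post_mean, post_var=post_var)


def sample_posterior(
    stats: SummaryStats,
    panel: PopulationPanel,
    arch: ArchitectureConfig,
    n_iter: int = 1100,
    burn_in: int = 100,
    seed: int | np.random.Generator = 0,
    *,
    slab_freqs: NDArray[np.float64] | None = None,
) -> NDArray[np.float64]:
    """Exact Monte-Carlo samples from the per-SNP posteriors.

    Each retained iteration draws, independently per SNP, a slab indicator
    with the posterior slab probability and then, if in the slab, an effect
    from ``N(k beta_hat, k s2)``.  Under SNP independence this is an exact
    (zero-autocorrelation) version of a single-site Gibbs sweep, so the
    matrix of draws can validate any posterior functional.

    Returns
    -------
    ndarray of shape (M, n_iter - burn_in)
        One column per retained sample.
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    post = posterior_moments_panel(stats, panel, arch, slab_freqs=slab_freqs)
    freqs = panel.f if slab_freqs is None else np.asarray(slab_freqs, dtype=float)
    sigma2 = prior_slab_variance(freqs, arch)
    k = sigma2 / (sigma2 + stats.s2)
    n_keep = n_iter - burn_in
    M = stats.M

    cond_mean = (k * stats.beta_hat)[:, None]
    cond_sd = np.sqrt(k * stats.s2)[:, None]
    # burn-in draws are consumed to keep the stream layout of a true sampler
    for _ in range(burn_in):
        rng.random(M)
        rng.standard_normal(M)
    indic = rng.random((M, n_keep)) < post.slab_prob[:, None]
    draws = cond_mean + cond_sd * rng.standard_normal((M, n_keep))
    return np.where(indic, draws, 0.0)
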