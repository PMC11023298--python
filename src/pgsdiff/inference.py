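"""Hypothesis tests on the posterior-mean risk difference.

``wald_test`` tests H0: d = 0 using the posterior mean ``d_hat`` and an
estimate of its sampling variance under the null ensemble in which true
effects are drawn from the point-normal prior conditioned on ``d = 0``.
Because ``d_hat`` is a shrinkage estimator, its null sampling variance is
neither the posterior variance of ``d`` (too large) nor the
naive marginal-estimate variance; see ``null_variance`` for the default
estimator and the module notes in ``docs/methods.md`` for its derivation
and empirical certification.

``t_test_comparator`` reproduces the conventional polygenic-score t-test
that compares mean scores between two target cohorts while ignoring
training-sample noise; its type-1 error is badly inflated unless the
training GWAS is enormous, which is the central cautionary result this
package demonstrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import ArchitectureConfig, PopulationPanel, PosteriorSummary, SummaryStats
from .model import prior_slab_variance

__all__ = ["TestResult", "wald_test", "t_test_comparator", "null_variance"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a test on the between-population risk difference."""

    statistic: float
    df: int
    p_value: float
    method: str
    null_variance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def null_variance(
    post: PosteriorSummary,
    panel: PopulationPanel,
    arch: ArchitectureConfig,
    stats: SummaryStats | None = None,
    variant: str = "null_variance",
) -> float:
    """Estimate of var[d_hat] under the conditional-prior null ensemble.

    Writing ``V_post`` for the posterior variance of ``d`` under SNP independence and
    ``V_prior = sum_j w_j^2 p_causal sigma2_j`` for its prior variance, the
    default estimator is the conjugate-shrinkage form

        V0 = V_post (V_prior - V_post) / V_prior

    which is exact for the all-causal (Gaussian) model -- where it reduces
    to ``k^2 sum w_j^2 s_j^2``, the textbook sampling variance of a
    linearly shrunk estimator -- and tracks the simulated null variance of
    ``d_hat`` closely across spike-and-slab architectures (see the
    calibration study in the test-suite).  ``variant="posterior_variance"``
    returns ``V_post`` itself, a deliberately conservative choice.
    """
    V_post = float(panel.w**2 @ post.post_var)
    if variant == "posterior_variance":
        return V_post
    if variant != "null_variance":
        raise ValueError(f"unknown variant {variant!r}")
    sigma2 = prior_slab_variance(panel.f, arch)
    V_prior = float(panel.w**2 @ (arch.p_causal * sigma2))
    if V_prior <= 0:
        raise ValueError("prior variance of d is zero; test is degenerate")
    V0 = V_post * (V_prior - V_post) / V_prior
    if V0 <= 0:
        raise ValueError(
            "degenerate null variance (posterior variance not below prior "
            "variance); the data carry no information about d"
        )
    return V0


def wald_test(
    d_hat: float,
    post: PosteriorSummary,
    panel: PopulationPanel,
    arch: ArchitectureConfig,
    stats: SummaryStats | None = None,
    variant: str = "null_variance",
    alternative: str = "directional",
) -> TestResult:
    """Wald test of H0: d = 0.

    The statistic ``W = d_hat^2 / V0`` is reported on the chi-square(1)
    scale; under the null it follows chi2_1 closely (certified by the
    calibration suite).  Two p-value conventions are offered:

    ``alternative="directional"`` (default)
        Tail probability in the direction of the observed difference,
        ``P(Z > |d_hat|/sqrt(V0)) = chi2_1 tail / 2``.  This is the
        convention of the package's reference reporting style (a RR whose
        95% interval grazes 1 is reported with P close to 0.05).  Because
        the direction is chosen after seeing the data, comparing this
        p-value to ``alpha`` flags true nulls at rate ``2 alpha``.

    ``alternative="two_sided"``
        The symmetric chi-square tail.  Under the null this rejects at the
        nominal rate.

    The difference is exactly a factor of two in p-value; both are exposed
    so that power studies and strict size-alpha testing can each use the
    appropriate one, and the experiment drivers record both.
    """
    if post.M != panel.M:
        raise ValueError("posterior summary and panel are not aligned")
    V0 = null_variance(post, panel, arch, stats, variant)
    W = float(d_hat) ** 2 / V0
    tail = float(sps.chi2.sf(W, df=1))
    if alternative == "directional":
        p = tail / 2.0
    elif alternative == "two_sided":
        p = tail
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(
        statistic=W, df=1, p_value=p, method=f"wald_{alternative}", null_variance=V0
    )


def t_test_comparator(
    post_mean: np.ndarray,
    panel: PopulationPanel,
    n1: int,
    n2: int,
    seed: int | np.random.Generator = 0,
) -> TestResult:
    """Naive two-cohort polygenic-score t-test (the flawed comparator).

    Simulates one target-sample comparison without materializing
    individual genotypes: observed cohort allele frequencies are drawn
    with binomial sampling noise (normal approximation),

        f_hat_j ~ N(f_j, f_j (1-f_j) / (2 n1)),   g_hat_j likewise,

    the mean polygenic-score difference is
    ``D = sum_j 2 post_mean_j (f_hat_j - g_hat_j)`` and the denominator
    uses the within-population score variances
    ``V_i = sum_j post_mean_j^2 2 freq_j (1-freq_j)``.  The test treats
    the score weights as fixed constants, which is exactly the mistake it
    exists to demonstrate: weight noise from the finite training sample
    shifts ``D`` systematically but appears nowhere in the denominator.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("target cohort sizes must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pm = np.asarray(post_mean, dtype=float)
    if pm.shape[0] != panel.M:
        raise ValueError("post_mean and panel are not aligned")
    f, g = panel.f, panel.g
    f_hat = f + rng.normal(0.0, np.sqrt(f * (1 - f) / (2 * n1)))
    g_hat = g + rng.normal(0.0, np.sqrt(g * (1 - g) / (2 * n2)))
    D = float(2.0 * pm @ (f_hat - g_hat))
    V1 = float(pm**2 @ (2 * f * (1 - f)))
    V2 = float(pm**2 @ (2 * g * (1 - g)))
    denom = V1 / n1 + V2 / n2
    if denom == 0.0:
        # all-zero score weights: no test possible
        return TestResult(statistic=0.0, df=n1 + n2 - 2, p_value=1.0,
                          method="t_test_degenerate", null_variance=0.0)
    t = D / np.sqrt(denom)
    # target n >= ~5000 in every intended use: normal approximation
    p = 2.0 * float(sps.norm.sf(abs(t)))
    return TestResult(
        statistic=float(t), df=n1 + n2 - 2, p_value=p, method="t_test",
        null_variance=denom,
    )
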