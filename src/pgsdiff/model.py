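"""Core domain types and variance algebra.

The model underlying the whole package is the standard summary-statistic
view of a GWAS of a quantitative (or liability-scale) trait on ``M``
approximately independent SNPs.  Per-allele effects ``beta_j`` follow a
point-normal ("spike and slab") prior

    beta_j = 0                          with probability 1 - p_causal
    beta_j ~ N(0, sigma2_j)             with probability p_causal

with the slab variance scaled so that the expected SNP-heritability over
the panel equals ``h2``:

    sigma2_j = h2 / (M * p_causal * 2 f_j (1 - f_j))

Marginal GWAS estimates are unbiased with sampling variance determined by
the training sample size ``N_eff`` and the training-sample allele
frequency:

    beta_hat_j | beta_j ~ N(beta_j, 1 / (2 N_eff f_j (1 - f_j)))

Everything downstream (posterior moments, the between-population risk
difference ``d``, the Wald test, the simulation drivers) is written in
terms of these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "ArchitectureConfig",
    "PopulationPanel",
    "SummaryStats",
    "PosteriorSummary",
    "prior_slab_variance",
    "sampling_variance",
    "effective_n",
    "FREQ_TOL",
]

#: Allele frequencies must lie in [FREQ_TOL, 1 - FREQ_TOL].  Values outside
#: raise rather than being clipped: a frequency at 0 or 1 makes the genotype
#: variance 2f(1-f) vanish and every variance formula ill-defined.
FREQ_TOL = 1e-6


def _as_freq_array(x: ArrayLike, name: str) -> NDArray[np.float64]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all((arr >= FREQ_TOL) & (arr <= 1.0 - FREQ_TOL)):
        bad = arr[(arr < FREQ_TOL) | (arr > 1.0 - FREQ_TOL)]
        raise ValueError(
            f"{name} contains frequencies outside [{FREQ_TOL}, {1 - FREQ_TOL}]: "
            f"e.g. {bad[:3]}; monomorphic or near-monomorphic variants must be "
            "removed before analysis"
        )
    return arr


@dataclass(frozen=True)
class ArchitectureConfig:
    """Genetic architecture: SNP-heritability, polygenicity and panel size.

    Parameters
    ----------
    h2 : float
        SNP-heritability of the trait on the standardized scale, in (0, 1].
    p_causal : float
        Proportion of variants with a nonzero causal effect, in (0, 1].
        ``p_causal = 1`` is the infinitesimal model.
    M : int
        Number of (approximately independent) SNPs in the panel.
    """

    h2: float
    p_causal: float
    M: int

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if not 0.0 < self.p_causal <= 1.0:
            raise ValueError(f"p_causal must be in (0, 1], got {self.p_causal}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")


@dataclass(frozen=True)
class PopulationPanel:
    """Aligned per-SNP effect-allele frequencies for two populations.

    ``f`` is population 1, ``g`` is population 2.  The derived contrast
    weights ``w = 2 (f - g)`` are the per-SNP multipliers in the mean
    genetic difference ``d = sum_j w_j beta_j``.
    """

    f: NDArray[np.float64]
    g: NDArray[np.float64]
    w: NDArray[np.float64] = field(init=False)

    def __post_init__(self) -> None:
        f = _as_freq_array(self.f, "f")
        g = _as_freq_array(self.g, "g")
        if f.shape != g.shape:
            raise ValueError(
                f"frequency vectors differ in length: {f.shape[0]} vs {g.shape[0]}"
            )
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "w", 2.0 * (f - g))

    @property
    def M(self) -> int:
        return self.f.shape[0]

    def swapped(self) -> "PopulationPanel":
        """Panel with the two populations exchanged (``d`` changes sign)."""
        return PopulationPanel(f=self.g.copy(), g=self.f.copy())


@dataclass(frozen=True)
class SummaryStats:
    """Per-SNP marginal GWAS effect estimates with sampling variances."""

    beta_hat: NDArray[np.float64]
    s2: NDArray[np.float64]
    N_eff: int | None = None

    def __post_init__(self) -> None:
        beta_hat = np.atleast_1d(np.asarray(self.beta_hat, dtype=float))
        s2 = np.atleast_1d(np.asarray(self.s2, dtype=float))
        if beta_hat.shape != s2.shape:
            raise ValueError("beta_hat and s2 must have the same length")
        if not np.all(s2 > 0):
            raise ValueError("all sampling variances s2 must be strictly positive")
        object.__setattr__(self, "beta_hat", beta_hat)
        object.__setattr__(self, "s2", s2)

    @property
    def M(self) -> int:
        return self.beta_hat.shape[0]

    @classmethod
    def from_n_eff(
        cls, beta_hat: ArrayLike, f: ArrayLike, N_eff: int
    ) -> "SummaryStats":
        """Build summary statistics with ``s2 = 1/(2 N_eff f (1-f))``."""
        f = _as_freq_array(f, "f")
        return cls(
            beta_hat=np.asarray(beta_hat, dtype=float),
            s2=sampling_variance(f, N_eff),
            N_eff=int(N_eff),
        )


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-SNP posterior summaries under the point-normal prior.

    Attributes
    ----------
    slab_prob : ndarray
        Posterior probability that the SNP has a nonzero effect.
    post_mean : ndarray
        Posterior mean effect E[beta_j | beta_hat_j].
    post_var : ndarray
        Posterior variance var[beta_j | beta_hat_j].
    """

    slab_prob: NDArray[np.float64]
    post_mean: NDArray[np.float64]
    post_var: NDArray[np.float64]

    def __post_init__(self) -> None:
        sp = np.atleast_1d(np.asarray(self.slab_prob, dtype=float))
        pm = np.atleast_1d(np.asarray(self.post_mean, dtype=float))
        pv = np.atleast_1d(np.asarray(self.post_var, dtype=float))
        if not (sp.shape == pm.shape == pv.shape):
            raise ValueError("posterior summary vectors must share a length")
        if np.any((sp < 0) | (sp > 1)):
            raise ValueError("slab_prob must lie in [0, 1]")
        if np.any(pv < -1e-15):
            raise ValueError("post_var must be non-negative")
        object.__setattr__(self, "slab_prob", sp)
        object.__setattr__(self, "post_mean", pm)
        object.__setattr__(self, "post_var", np.maximum(pv, 0.0))

    @property
    def M(self) -> int:
        return self.post_mean.shape[0]


def prior_slab_variance(
    f: ArrayLike, arch: ArchitectureConfig
) -> NDArray[np.float64]:
    """Slab variance ``sigma2_j = h2 / (M p_causal 2 f_j (1 - f_j))``.

    Scaled so that summing ``p_causal * sigma2_j * 2 f_j (1 - f_j)`` over
    the M panel SNPs returns ``h2`` exactly (the heritability partition).

    Parameters
    ----------
    f : array_like
        Effect-allele frequencies (population 1 / training sample).
    arch : ArchitectureConfig

    Returns
    -------
    ndarray
        Per-SNP prior slab variances, strictly positive.
    """
    f = _as_freq_array(f, "f")
    return arch.h2 / (arch.M * arch.p_causal * 2.0 * f * (1.0 - f))


def sampling_variance(f: ArrayLike, N_eff: int) -> NDArray[np.float64]:
    """Sampling variance of the marginal estimate, ``1/(2 N_eff f (1-f))``."""
    f = _as_freq_array(f, "f")
    if N_eff < 1:
        raise ValueError(f"N_eff must be >= 1, got {N_eff}")
    return 1.0 / (2.0 * float(N_eff) * f * (1.0 - f))


def effective_n(cases: int, controls: int) -> int:
    """Effective sample size of a case-control GWAS.

    Uses the harmonic form ``4 / (1/cases + 1/controls)``, which equals
    ``2 n`` for a balanced design of ``n`` cases and ``n`` controls, and is
    rounded to the nearest integer.
    """
    if cases <= 0 or controls <= 0:
        raise ValueError("cases and controls must both be positive")
    return int(round(4.0 / (1.0 / cases + 1.0 / controls)))
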