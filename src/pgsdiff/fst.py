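"""Moment estimation of F_ST from two allele-frequency vectors.

The estimator is the Hudson-style ratio of sums

    F_hat = sum_j (f_j - g_j)^2 / sum_j [f_j (1 - g_j) + g_j (1 - f_j)]

Under the Balding-Nichols generating model with unknown ancestral
frequency used throughout this package -- population 2 frequencies drawn
around population 1 frequencies with Beta dispersion controlled by F_ST --
the numerator has conditional expectation ``2 F_ST f (1 - f)`` per SNP and
the denominator ``2 f (1 - f)``, so the ratio of expectations is exactly
F_ST and the ratio of sums is consistent as the panel grows.  The
ratio-of-sums (rather than mean-of-ratios) form is numerically stable at
extreme frequencies.
"""

from __future__ import annotations

import numpy as np

from .model import PopulationPanel

__all__ = ["estimate_fst"]


def estimate_fst(
    panel: PopulationPanel,
    *,
    n1: int | None = None,
    n2: int | None = None,
) -> float:
    """Estimate F_ST between the two populations of ``panel``.

    Parameters
    ----------
    panel : PopulationPanel
        Aligned frequency vectors.  Frequencies are treated as population
        (not small-sample) values.
    n1, n2 : int, optional
        Diploid sample sizes behind the frequency estimates.  When both are
        given, the finite-sample bias of the squared difference is removed
        by subtracting ``f(1-f)/(2 n1) + g(1-g)/(2 n2)`` from each
        numerator term.  Off by default because typical inputs are large
        control-group frequencies.

    Returns
    -------
    float
        The estimate; 0.0 when the two populations have identical
        frequencies at every SNP.
    """
    f, g = panel.f, panel.g
    num = (f - g) ** 2
    if n1 is not None and n2 is not None:
        if n1 < 1 or n2 < 1:
            raise ValueError("sample sizes must be positive")
        num = num - f * (1 - f) / (2 * n1) - g * (1 - g) / (2 * n2)
    denom = f * (1 - g) + g * (1 - f)
    total = float(denom.sum())
    if total == 0.0:
        return 0.0
    return float(num.sum() / total)
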