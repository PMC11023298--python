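"""Plot helpers for the simulation-study outputs.

Each function takes the long-format DataFrame produced by the experiment
drivers and renders a multi-panel matplotlib figure in the style of the
package's reference simulation study: posterior s.d. curves against
training sample size, and rejection-rate curves for the Wald and t tests.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_sd_curves", "plot_rejection_curves"]


def plot_sd_curves(df: pd.DataFrame, out_path: str, x: str = "n_eff") -> None:
    """Posterior s.d. of d against ``x``, one line per polygenicity."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for p, sub in df.groupby("p_causal"):
        sub = sub.sort_values(x)
        ax.plot(sub[x], sub["sd_d"], marker="o", label=f"p_causal={p:g}")
    ax.set_xscale("log")
    ax.set_xlabel("training sample size N" if x == "n_eff" else x)
    ax.set_ylabel("posterior s.d. of d")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_rejection_curves(
    df: pd.DataFrame, out_path: str, metric: str = "power_wald", alpha: float = 0.05
) -> None:
    """Rejection rate against training N, one line per polygenicity.

    For null grids (``rr == 1``) this is the type-1 error plot; the grey
    horizontal line marks the nominal test size.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for p, sub in df.groupby("p_causal"):
        sub = sub.sort_values("n_eff")
        ax.plot(sub["n_eff"], sub[metric], marker="o", label=f"p_causal={p:g}")
    ax.axhline(alpha, color="grey", lw=1, ls="--")
    ax.set_xscale("log")
    ax.set_xlabel("training sample size N")
    ax.set_ylabel(metric.replace("_", " "))
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
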