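"""Standard figures: tornado diagram, cost-effectiveness plane, CEAC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_tornado", "plot_ce_plane", "plot_ceac"]


def plot_tornado(tornado: pd.DataFrame, base_icer: float, path, top_n: int = 12):
    """Horizontal bars of the ICER swing for the most influential parameters."""
    df = tornado.dropna(subset=["icer_at_low", "icer_at_high"]).head(top_n).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.2))
    lo = np.minimum(df["icer_at_low"], df["icer_at_high"])
    hi = np.maximum(df["icer_at_low"], df["icer_at_high"])
    ax.barh(df["param"], hi - lo, left=lo, color="#4878b0")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base case")
    ax.set_xlabel("ICER ($/QALY)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(draws: pd.DataFrame, wtp: float, path):
    """Incremental cost vs incremental QALYs, with the WTP threshold line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(draws["delta_qaly"], draws["delta_cost"], s=4, alpha=0.25, lw=0)
    q = np.linspace(*ax.get_xlim(), 10)
    ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.7)
    ax.axvline(0, color="grey", lw=0.7)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost ($)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: pd.DataFrame, wtp: float, path):
    """Probability of cost-effectiveness along the willingness-to-pay grid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["prob_cost_effective"], lw=1.5)
    ax.axvline(wtp, color="k", lw=1, ls="--", label=f"WTP ${wtp:,.0f}/QALY")
    ax.set_xlabel("willingness to pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
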