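"""Static renderings of the two main report surfaces.

Matplotlib is imported lazily so headless pipelines that never plot pay
no import cost.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def plot_composition_profile(profile_table: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of fractional differences on the order→disorder axis.

    Expects the per-residue table from ``bootstrap_composition_test``
    (index: residue, columns fractional_difference / bootstrap_sd /
    significant).  Undefined residues are skipped.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = profile_table[~profile_table.get("undefined", False)]
    fig, ax = plt.subplots(figsize=(8, 3.5))
    colors = ["tab:red" if s else "tab:gray" for s in t["significant"]]
    ax.bar(t.index, t["fractional_difference"], yerr=t["bootstrap_sd"],
           color=colors, capsize=2)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("residue (order-promoting → disorder-promoting)")
    ax.set_ylabel("fractional difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ch_cdf(points: pd.DataFrame, path: str | Path) -> None:
    """CH-CDF scatter, one color per group, quadrant axes at zero.

    Expects columns group / delta_ch / delta_cdf.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, sub in points.groupby("group"):
        ax.scatter(sub["delta_cdf"], sub["delta_ch"], s=8, alpha=0.6, label=name)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("ΔCDF (positive = ordered)")
    ax.set_ylabel("ΔCH (positive = disordered)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
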