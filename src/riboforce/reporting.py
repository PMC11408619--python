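"""Figure-style summaries: force histograms, dose-response curves, survival.

Plots are optional artifacts for human inspection; nothing downstream
depends on rendered images.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dose_response import CURVES
from .trace_model import DoseResponseFit

__all__ = ["plot_force_distributions", "plot_dose_response", "plot_dwell_survival"]


def plot_force_distributions(
    norm_cycles_df: pd.DataFrame, out: str | Path, column: str = "norm_unfold_force"
) -> Path:
    """Overlaid normalized rupture-force histograms, one per condition."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (lig, conc), g in norm_cycles_df.groupby(["ligand", "concentration"]):
        vals = g[column].dropna()
        if vals.empty:
            continue
        ax.hist(vals, bins=30, density=True, histtype="step",
                label=f"{lig} {conc * 1e6:g} uM" if conc else lig)
    ax.set_xlabel("normalized rupture force")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def plot_dose_response(
    concentrations, responses, fit: DoseResponseFit | None, out: str | Path
) -> Path:
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(x, y, "o", ms=5)
    if fit is not None:
        pos = x[x > 0]
        grid = np.concatenate([[0], np.geomspace(pos.min() / 3, pos.max() * 3, 200)])
        ax.plot(grid, CURVES[fit.model](grid, **fit.params), "-", lw=1)
        ax.axvline(fit.half_saturation, ls=":", lw=1)
    ax.set_xscale("symlog", linthresh=max(x[x > 0].min() / 2, 1e-12) if (x > 0).any() else 1.0)
    ax.set_xlabel("concentration (M)")
    ax.set_ylabel("response")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def plot_dwell_survival(durations_by_label: dict[str, np.ndarray], out: str | Path) -> Path:
    """Empirical survival curves of dwell durations, log-y."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for label, dur in durations_by_label.items():
        d = np.sort(np.asarray(dur, dtype=float))
        surv = 1.0 - np.arange(1, d.size + 1) / d.size
        ax.step(d, np.clip(surv, 1e-6, None), where="post", label=label)
    ax.set_yscale("log")
    ax.set_xlabel("dwell duration (s)")
    ax.set_ylabel("survival")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)
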