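"""Display helpers: spacing violins per Δt and the coupling density plot."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np

from .coupling import CouplingProfile, TransitionFit
from .spacing import NNDTable


def plot_spacing_violins(tables: Sequence[NNDTable], ax=None, clip_nm: float = 1000.0):
    """Violin plot of cross-channel NND distributions per Δt.

    Distances beyond ``clip_nm`` are hidden from the display (they remain
    in every quantile the analysis reports).
    """
    if ax is None:
        _, ax = plt.subplots()
    tables = sorted(tables, key=lambda t: t.delta_t)
    data = [t.nnd[t.nnd <= clip_nm] for t in tables]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(tables) + 1),
                  [f"{t.delta_t:g}" for t in tables])
    ax.set_xlabel("Δt (min)")
    ax.set_ylabel("NND (nm)")
    return ax


def plot_coupling_profile(profile: CouplingProfile, fit: TransitionFit | None = None,
                          ax=None):
    """Pair density with the binned <α>(d) curve and the two regression lines."""
    if ax is None:
        _, ax = plt.subplots()
    ax.hexbin(profile.mean_distance_nm, profile.mean_alpha_deg,
              gridsize=60, cmap="Greys", mincnt=1)
    ax.plot(profile.bin_centers_nm, profile.bin_mean_deg, color="C0", lw=2,
            label="binned ⟨α⟩")
    ax.fill_between(profile.bin_centers_nm,
                    profile.bin_mean_deg - profile.bin_sd_deg,
                    profile.bin_mean_deg + profile.bin_sd_deg,
                    color="C0", alpha=0.2)
    if fit is not None and fit.found:
        d = np.linspace(0, profile.mean_distance_nm.max(), 50)
        ax.plot(d, fit.near_slope * d + fit.near_intercept, "r--", lw=1)
        ax.plot(d, fit.far_slope * d + fit.far_intercept, "r--", lw=1)
        ax.axvline(fit.d_star_nm, color="gray", ls=":")
        ax.axhline(fit.alpha_star_deg, color="gray", ls=":")
    ax.set_xlabel("pair distance (nm)")
    ax.set_ylabel("mean correlation angle ⟨α⟩ (deg)")
    ax.set_ylim(0, 180)
    return ax
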