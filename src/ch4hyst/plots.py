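"""Loop plots and distribution figures for the hysteresis analysis."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .hysteresis import HysteresisResult, eval_curve, fit_branch


def plot_loop(result: HysteresisResult, day_table=None, ax=None):
    """Flux-temperature loop for one site-year.

    Earlier-branch curve in red, later in blue, full-season fit in black;
    daily points (when the day table is given) as dots.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    t_grid = np.linspace(0.0, result.fit_earlier.t_max, 200)
    ax.plot(t_grid, eval_curve(result.fit_earlier, t_grid), color="tab:red",
            label="earlier")
    ax.plot(t_grid, eval_curve(result.fit_later, t_grid), color="tab:blue",
            label="later")
    if day_table is not None:
        sub = day_table[
            (day_table["site_id"] == result.site_id)
            & (day_table["season_year"] == result.season_year)
        ]
        if len(sub):
            colors = sub["branch"].map({"earlier": "tab:red", "later": "tab:blue"})
            ax.scatter(sub["t"], sub["f"], s=8, c=colors, alpha=0.5)
            full = fit_branch(
                sub["t"].to_numpy(float), sub["f"].to_numpy(float),
                result.fit_earlier.t_max, result.fit_earlier.f_at_tmax, branch="full",
            )
            ax.plot(t_grid, eval_curve(full, t_grid), color="black", lw=1.2,
                    label="full season")
    ax.set_xlabel("air temperature (°C)")
    ax.set_ylabel("CH$_4$ flux (mg C m$^{-2}$ d$^{-1}$)")
    ax.set_title(
        f"{result.site_id} {result.season_year}  "
        f"$H_A$={result.h_area:.3f}, $H_\\mu$={result.h_mu:.1f}"
    )
    ax.legend(fontsize=8)
    return ax


def plot_hysteresis_distributions(frame, axes=None):
    """Histograms of H_A and H_mu across site-years."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    axes[0].hist(frame["h_area"], bins=30, color="tab:blue")
    axes[0].axvline(0.0, color="red", ls="--")
    axes[0].set_xlabel("$H_A$ (-)")
    axes[1].hist(frame["h_mu"], bins=30, color="tab:blue")
    axes[1].axvline(0.0, color="red", ls="--")
    axes[1].set_xlabel("$H_\\mu$ (mg C m$^{-2}$ d$^{-1}$)")
    for ax in axes:
        ax.set_ylabel("site-years")
    return axes
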