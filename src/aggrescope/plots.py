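"""Figure mirrors of the standard analysis panels.

Each helper draws one panel type onto a fresh Axes and returns it; callers
compose or save as they wish.  Kept deliberately plain — these are QC /
publication starting points, not a plotting framework.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np               # noqa: E402
import pandas as pd              # noqa: E402

from .dynamics import DepthTranslation, GrowthPhases  # noqa: E402
from .spatial_stats import ExpressionProfile, RadialProfile  # noqa: E402


def plot_radial_biomass(profile: RadialProfile, ax=None):
    """Mean colony size and count vs distance from the particle edge."""
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    tab = profile.table
    centers = 0.5 * (tab["bin_left_um"] + tab["bin_right_um"])
    ax.bar(centers, tab["total_area_um2"],
           width=0.9 * (tab["bin_right_um"] - tab["bin_left_um"]),
           color="#4878a8", label="total colony area")
    ax.set_xlabel("distance from edge (µm)")
    ax.set_ylabel("colony area (µm²)")
    ax.legend(frameon=False)
    return ax


def plot_colony_pdf(profile: RadialProfile, ax=None, label=None):
    """Probability density of colony position along the radius."""
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    ax.plot(profile.table["distance_um"], profile.table["density"],
            label=label)
    ax.set_xlabel("distance from edge (µm)")
    ax.set_ylabel("probability density (µm⁻¹)")
    return ax


def plot_expression_profiles(profiles: list[ExpressionProfile], ax=None):
    """Reporter-expression densities vs distance from edge, peaks marked."""
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    colors = {"NarK": "#2ca6a4", "NirS": "#c0392b"}
    for prof in profiles:
        color = colors.get(prof.channel)
        ax.plot(prof.distance_um, prof.density, color=color,
                label=f"{prof.channel} (peak {prof.peak_mean_um:.0f} µm)")
        ax.axvline(prof.peak_mean_um, color=color, ls="--", lw=0.8)
    ax.set_xlabel("distance from edge (µm)")
    ax.set_ylabel("expression density (µm⁻¹)")
    ax.legend(frameon=False)
    return ax


def plot_exposure_fractions(exposure: pd.DataFrame, ax=None):
    """Fraction of colony area below each oxygen threshold vs depth."""
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    for col in [c for c in exposure.columns if c.startswith("frac_below_")]:
        thr = col.removeprefix("frac_below_")
        ax.plot(exposure["depth_m"], exposure[col],
                label=f"O₂ < {thr} µmol L⁻¹")
    ax.set_xlabel("translated depth (m)")
    ax.set_ylabel("fraction of colony area")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_lag_histogram(phase_list: list[GrowthPhases],
                       translation: DepthTranslation | None = None, ax=None):
    """Distribution of depth-translated intermediate lag durations."""
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    lags = [p.lag_duration_m for p in phase_list if p.has_lag]
    ax.hist(lags, bins="auto", color="#7a6fb0")
    ax.set_xlabel("lag duration (m of sinking)")
    ax.set_ylabel("colonies")
    return ax


def plot_chemistry_profile(profile: pd.DataFrame, column: str, ax=None):
    """One chemistry variable vs translated depth, depth on the y axis."""
    ax = ax or plt.figure(figsize=(3.2, 4.5)).add_subplot()
    cols = [c for c in (column, f"{column}_mean") if c in profile.columns]
    if not cols:
        raise ValueError(f"column {column!r} not in profile")
    ax.plot(profile[cols[0]], profile["depth_m"])
    if f"{column}_std" in profile.columns:
        ax.fill_betweenx(profile["depth_m"],
                         profile[cols[0]] - profile[f"{column}_std"],
                         profile[cols[0]] + profile[f"{column}_std"],
                         alpha=0.25)
    ax.invert_yaxis()
    ax.set_xlabel(column)
    ax.set_ylabel("translated depth (m)")
    return ax


def save(ax, path, dpi=150):
    """Save the figure owning ``ax`` and close it."""
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
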