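"""Radial spatial statistics and depth-translated bulk chemistry profiles.

All radial statistics are taken against distance from the particle *edge*
(not the center): oxidants diffuse in from the boundary, so the edge is the
physically meaningful origin.  Densities are reflected at the edge (distance
0) where the biological signal concentrates, and always integrate to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import DepthTranslation
from .geometry import ParticleGeometry
from .tracking import ColonyTrack


@dataclass
class RadialProfile:
    """A statistic binned by distance-from-edge."""

    bin_edges_um: np.ndarray
    table: pd.DataFrame
    normalized: bool = False


@dataclass
class ExpressionProfile:
    """Radial density of a fluorescent transcriptional reporter signal."""

    channel: str                  # "NarK" | "NirS" | free-form
    distance_um: np.ndarray
    density: np.ndarray           # integrates to 1 over distance
    peak_mean_um: float
    peak_std_um: float
    peak_median_um: float


@dataclass
class CompareResult:
    t: float
    df: float
    p: float


def radial_biomass_profile(
    tracks: list[ColonyTrack],
    geometry: ParticleGeometry,
    bins: int | np.ndarray = 15,
) -> RadialProfile:
    """Final-frame biomass statistics per distance-from-edge bin.

    Per bin: cumulative colony area, mean colony size, and colony count, using
    each track's last observation.  Empty bins hold NaN mean size (missing),
    zero area and zero count.
    """
    if not tracks:
        raise ValueError("at least one track is required")
    dist = np.array([tr.observations[-1].distance_to_edge_um for tr in tracks])
    area = np.array([tr.observations[-1].area_um2 for tr in tracks])
    if np.isscalar(bins) or np.ndim(bins) == 0:
        edges = np.linspace(0.0, geometry.equivalent_radius_um, int(bins) + 1)
    else:
        edges = np.asarray(bins, float)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        rows.append({
            "bin_left_um": edges[b], "bin_right_um": edges[b + 1],
            "total_area_um2": float(area[sel].sum()),
            "mean_area_um2": float(area[sel].mean()) if n else np.nan,
            "count": n,
        })
    return RadialProfile(bin_edges_um=edges, table=pd.DataFrame(rows))


def colony_radial_pdf(
    tracks: list[ColonyTrack],
    geometry: ParticleGeometry,
    bandwidth: float | str | None = None,
    grid_n: int = 512,
) -> RadialProfile:
    """Probability density of colony distance-to-edge, reflected at 0.

    Gaussian KDE with boundary reflection at the particle edge (distance 0) so
    edge-concentrated distributions are not biased low there; numerically
    renormalized to integrate to one over [0, R].  A single colony is a
    degenerate density and raises.
    """
    dist = np.array([tr.observations[-1].distance_to_edge_um for tr in tracks])
    if dist.size < 2:
        raise ValueError("density estimate needs at least two colonies")
    if np.ptp(dist) < 1e-12:
        raise ValueError("degenerate density: all colonies at one distance")
    kde = stats.gaussian_kde(dist, bw_method=bandwidth)
    r_max = max(geometry.equivalent_radius_um, float(dist.max()))
    x = np.linspace(0.0, r_max, grid_n)
    dens = kde(x) + kde(-x)           # reflect at the edge
    integral = np.trapezoid(dens, x)
    dens = dens / integral
    table = pd.DataFrame({"distance_um": x, "density": dens})
    return RadialProfile(bin_edges_um=x, table=table, normalized=True)


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cum = np.cumsum(w)
    cum = cum / cum[-1]
    return float(np.interp(0.5, cum, x))


def expression_radial_profile(
    expression_image: np.ndarray,
    geometry: ParticleGeometry,
    diatom_mask: np.ndarray | None = None,
    channel: str = "NarK",
    bin_width_um: float = 10.0,
    weighting: str = "intensity",
    noise_floor_sigma: float = 2.0,
) -> ExpressionProfile:
    """Radial expression density and peak localization of a reporter channel.

    The median intensity outside the particle is subtracted as background and
    diatom pixels are excluded (chlorophyll bleeds into the red channel).  The
    per-bin statistic is the *mean* background-subtracted intensity at each
    distance (the radial sampling of the signal), normalized to a density;
    peak statistics are the intensity-weighted mean, std, and median distance.
    Bins whose mean does not exceed ``noise_floor_sigma`` standard errors of
    the in-bin scatter are zeroed: rectified sensor noise in empty bins would
    otherwise drag the peak statistics toward the particle interior.  With
    ``weighting="count"`` the raw per-bin intensity sum is used instead.
    """
    img = np.asarray(expression_image, float)
    if img.shape != geometry.particle_mask.shape:
        raise ValueError("expression image must be co-registered with geometry")
    outside = ~geometry.particle_mask
    bg = float(np.median(img[outside])) if outside.any() else 0.0
    valid = geometry.particle_mask.copy()
    if diatom_mask is not None:
        valid &= ~np.asarray(diatom_mask, bool)
    # Background is subtracted without clipping: clipping individual pixels
    # rectifies the noise into a spurious signal floor across the whole disk;
    # averaging within a bin lets the noise cancel first.
    signal = img - bg
    if signal[valid].max() <= 0:
        raise ValueError("expression channel is empty after background subtraction")

    d = geometry.distance_to_edge_um[valid]
    s = signal[valid]
    d_max = max(float(d.max()), geometry.equivalent_radius_um)
    edges = np.arange(0.0, d_max + bin_width_um, bin_width_um)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=s, minlength=len(edges) - 1)
    sumsq = np.bincount(idx, weights=s * s, minlength=len(edges) - 1)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    if weighting == "intensity":
        w = np.zeros_like(sums)
        w[occupied] = sums[occupied] / counts[occupied]   # mean intensity per bin
    elif weighting == "count":
        w = sums
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = np.clip(w, 0.0, None)
    if noise_floor_sigma > 0:
        mean = np.zeros_like(sums)
        mean[occupied] = sums[occupied] / counts[occupied]
        var = np.zeros_like(sums)
        var[occupied] = np.maximum(
            sumsq[occupied] / counts[occupied] - mean[occupied] ** 2, 0.0)
        se = np.zeros_like(sums)
        se[occupied] = np.sqrt(var[occupied] / counts[occupied])
        w[w <= noise_floor_sigma * se] = 0.0
    if w.sum() <= 0:
        raise ValueError("expression channel has no signal above the noise floor")
    total = w.sum()
    density = w / (total * bin_width_um)
    mean = float(np.sum(w * centers) / total)
    std = float(np.sqrt(np.sum(w * (centers - mean) ** 2) / total))
    median = _weighted_median(centers[occupied], w[occupied])
    return ExpressionProfile(
        channel=channel, distance_um=centers, density=density,
        peak_mean_um=mean, peak_std_um=std, peak_median_um=median,
    )


def chemistry_depth_profile(
    series: pd.DataFrame,
    translation: DepthTranslation | None = None,
) -> pd.DataFrame:
    """Translate a bulk chemistry time series to a depth profile.

    Input columns: ``time_h`` plus any concentration columns, optionally a
    ``replicate`` column; output has ``depth_m`` and, with replicates, the
    per-depth mean and standard deviation of each concentration.  Times must
    be strictly increasing within a replicate.
    """
    translation = translation or DepthTranslation()
    df = series.copy()
    if "time_h" not in df.columns:
        raise ValueError("series must have a time_h column")
    conc_cols = [c for c in df.columns if c not in ("time_h", "replicate")]
    if (df[conc_cols] < 0).any().any():
        raise ValueError("concentrations must be non-negative")
    groups = df.groupby("replicate") if "replicate" in df.columns else [(None, df)]
    for _, g in groups:
        t = g["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("time axis must be strictly increasing")
    df["depth_m"] = translation.depth_m(df["time_h"].to_numpy())
    if "replicate" in df.columns:
        agg = {c: ["mean", "std"] for c in conc_cols}
        out = df.groupby("depth_m").agg(agg)
        out.columns = [f"{c}_{s}" for c, s in out.columns]
        return out.reset_index()
    return df[["depth_m", *conc_cols]]


def compare_conditions(a, b) -> CompareResult:
    """Welch two-sample t-test between two condition samples.

    A supporting routine statistic (e.g., initial DOC or lag duration between
    broken- and intact-diatom scenarios), not a novel computation.  Requires
    at least two values per condition.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per condition")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # Degenerate but well-defined limits scipy reports as NaN.
        if np.isclose(a.mean(), b.mean()):
            return CompareResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return CompareResult(t=t, df=float(a.size + b.size - 2), p=0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        dof = a.size + b.size - 2.0
    else:
        dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return CompareResult(t=float(res.statistic), df=float(dof),
                         p=float(res.pvalue))
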