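"""Per-track and per-particle temporal analysis.

A particle held in the millifluidic device with seawater flowing past at the
imposed sinking speed experiences time as an analog of ocean depth, so every
time axis here can be translated linearly to meters.  Colony growth on log
area is decomposed into the diauxic sequence observed for facultative
denitrifiers — an aerobic exponential phase, an intermediate lag while the
denitrification machinery is synthesized, and a second (anaerobic) exponential
phase — by penalized piecewise-linear changepoint fitting.  Oxygen exposure of
the community is summarized as the fraction of total colony area below each
category threshold (40 / 10 / 5 / 1 µmol L⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import OXYGEN_THRESHOLDS_UMOL_L
from .tracking import ColonyTrack

DEFAULT_SINKING_SPEED_M_PER_D = 4.8
DEFAULT_EXPOSURE_THRESHOLDS = (40.0, 10.0, 5.0, 1.0)


@dataclass
class DepthTranslation:
    """Linear time -> depth mapping via the imposed sinking speed."""

    sinking_speed_m_per_d: float = DEFAULT_SINKING_SPEED_M_PER_D

    def depth_m(self, t_h):
        return depth_from_time(t_h, self.sinking_speed_m_per_d)


def depth_from_time(t_h, speed_m_per_d: float = DEFAULT_SINKING_SPEED_M_PER_D):
    """Depth (m) reached after ``t_h`` hours sinking at ``speed_m_per_d``.

    Linear, no compaction or acceleration: 100 h at 4.8 m d⁻¹ is 20 m.
    """
    t = np.asarray(t_h, float)
    if np.any(t < 0):
        raise ValueError("negative time has no depth translation")
    if speed_m_per_d <= 0:
        raise ValueError("sinking speed must be positive")
    out = speed_m_per_d * t / 24.0
    return float(out) if np.isscalar(t_h) else out


# ---------------------------------------------------------------------------
# Piecewise-linear growth-phase decomposition
# ---------------------------------------------------------------------------

@dataclass
class PhaseSegment:
    name: str                 # "exp1" | "lag" | "exp2" | "stationary" | "segment"
    t_start_h: float
    t_end_h: float
    slope_per_h: float


@dataclass
class GrowthPhases:
    track_id: int
    segments: list[PhaseSegment]
    lag_start_h: float | None = None
    lag_duration_h: float | None = None
    lag_duration_m: float | None = None
    mu1_per_h: float | None = None
    mu2_per_h: float | None = None
    flagged_short: bool = False

    @property
    def has_lag(self) -> bool:
        return self.lag_duration_h is not None


def _segment_cost_factory(t: np.ndarray, y: np.ndarray):
    """O(1) RSS of a least-squares line on y[i:j] via prefix sums."""
    one = np.concatenate([[0.0], np.cumsum(np.ones_like(t))])
    st = np.concatenate([[0.0], np.cumsum(t)])
    stt = np.concatenate([[0.0], np.cumsum(t * t)])
    sy = np.concatenate([[0.0], np.cumsum(y)])
    sty = np.concatenate([[0.0], np.cumsum(t * y)])
    syy = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(i: int, j: int) -> tuple[float, float, float]:
        """(RSS, slope, intercept) of the fit on points i..j-1."""
        n = one[j] - one[i]
        Sx, Sxx = st[j] - st[i], stt[j] - stt[i]
        Sy, Sxy, Syy = sy[j] - sy[i], sty[j] - sty[i], syy[j] - syy[i]
        det = n * Sxx - Sx * Sx
        if det <= 1e-12:
            return Syy - Sy * Sy / max(n, 1.0), 0.0, Sy / max(n, 1.0)
        b = (n * Sxy - Sx * Sy) / det
        a = (Sy - b * Sx) / n
        rss = Syy - a * Sy - b * Sxy
        return max(rss, 0.0), b, a

    return cost


def segmented_least_squares(
    t: np.ndarray,
    y: np.ndarray,
    max_changepoints: int = 3,
    min_seg_len: int = 3,
) -> list[tuple[int, int, float]]:
    """Optimal piecewise-linear fit of y(t) with BIC model selection.

    Dynamic programming over all changepoint placements for each candidate
    number of segments; the segment count is then chosen by BIC
    ``n ln(RSS/n) + p ln n`` with ``p = 2 * n_segments + n_changepoints``.
    Returns ``[(i, j, slope), ...]`` half-open index segments.
    """
    n = len(t)
    cost = _segment_cost_factory(np.asarray(t, float), np.asarray(y, float))
    max_k = min(max_changepoints, n // min_seg_len - 1)
    max_k = max(max_k, 0)

    # D[k][j]: best RSS of fitting y[0:j] with k+1 segments.
    INF = np.inf
    D = np.full((max_k + 1, n + 1), INF)
    parent = np.full((max_k + 1, n + 1), -1, dtype=int)
    for j in range(min_seg_len, n + 1):
        D[0][j], _, _ = cost(0, j)
    for k in range(1, max_k + 1):
        for j in range((k + 1) * min_seg_len, n + 1):
            best, arg = INF, -1
            for i in range(k * min_seg_len, j - min_seg_len + 1):
                if D[k - 1][i] == INF:
                    continue
                c, _, _ = cost(i, j)
                v = D[k - 1][i] + c
                if v < best:
                    best, arg = v, i
            D[k][j], parent[k][j] = best, arg

    best_bic, best_k = INF, 0
    for k in range(max_k + 1):
        if D[k][n] == INF:
            continue
        rss = max(D[k][n], n * 1e-12)
        p = 2 * (k + 1) + k
        bic = n * np.log(rss / n) + p * np.log(n)
        if bic < best_bic - 1e-9:
            best_bic, best_k = bic, k

    bounds = [n]
    k, j = best_k, n
    while k > 0:
        j = parent[k][j]
        bounds.append(j)
        k -= 1
    bounds.append(0)
    bounds = bounds[::-1]
    return [(bounds[i], bounds[i + 1], cost(bounds[i], bounds[i + 1])[1])
            for i in range(len(bounds) - 1)]


def fit_growth_phases(
    track: ColonyTrack,
    translation: DepthTranslation | None = None,
    min_track_len: int = 12,
    max_changepoints: int = 3,
    lag_slope_fraction: float = 0.1,
    min_seg_len: int = 3,
) -> GrowthPhases:
    """Decompose a colony track's log-area trajectory into growth phases.

    The lag is the maximal *interior* fitted segment whose slope is below
    ``lag_slope_fraction`` of the initial exponential rate ``mu1``; a trailing
    slow segment is stationary, not lag.  Tracks shorter than
    ``min_track_len`` observations (or with too few positive areas) are
    flagged and excluded from lag statistics by the caller.
    """
    translation = translation or DepthTranslation()
    t = track.times_h
    a = track.areas_um2
    keep = np.isfinite(a) & (a > 0)           # zero/missing areas are dropped, not log(0)
    t, a = t[keep], a[keep]
    phases = GrowthPhases(track_id=track.track_id, segments=[])
    if len(t) < min_track_len:
        phases.flagged_short = True
        return phases

    y = np.log(a)
    segs = segmented_least_squares(y=y, t=t, max_changepoints=max_changepoints,
                                   min_seg_len=min_seg_len)
    phases.mu1_per_h = segs[0][2]
    slope_thr = abs(phases.mu1_per_h) * lag_slope_fraction

    named: list[PhaseSegment] = []
    lag_idx = None
    for si, (i, j, slope) in enumerate(segs):
        name = "segment"
        if si == 0:
            name = "exp1"
        elif abs(slope) < slope_thr:
            if si == len(segs) - 1:
                name = "stationary"
            else:
                name = "lag"
                if lag_idx is None or (t[j - 1] - t[i]) > (
                    named[lag_idx].t_end_h - named[lag_idx].t_start_h
                ):
                    lag_idx = si
        else:
            name = "exp2"
        named.append(PhaseSegment(name, float(t[i]), float(t[j - 1]), float(slope)))
    # Only the maximal interior slow segment keeps the "lag" name.
    for si, seg in enumerate(named):
        if seg.name == "lag" and si != lag_idx:
            seg.name = "segment"
    phases.segments = named
    if lag_idx is not None:
        lag = named[lag_idx]
        phases.lag_start_h = lag.t_start_h
        phases.lag_duration_h = lag.t_end_h - lag.t_start_h
        phases.lag_duration_m = translation.depth_m(phases.lag_duration_h)
        for seg in named[lag_idx + 1:]:
            if seg.name not in ("lag", "stationary"):
                phases.mu2_per_h = seg.slope_per_h
                seg.name = "exp2"
                break
    return phases


def lag_statistics(
    phase_list: list[GrowthPhases],
    translation: DepthTranslation | None = None,
) -> dict:
    """Mean ± std and median of depth-translated lag durations.

    Reports both hours and meters; short-flagged tracks and tracks without a
    detected lag are excluded (their counts are reported).
    """
    translation = translation or DepthTranslation()
    lags_h = np.array([p.lag_duration_h for p in phase_list if p.has_lag])
    out = {
        "n_tracks": len(phase_list),
        "n_with_lag": int(lags_h.size),
        "n_flagged_short": sum(p.flagged_short for p in phase_list),
    }
    if lags_h.size:
        lags_m = translation.depth_m(lags_h)
        out.update(
            lag_mean_h=float(lags_h.mean()), lag_std_h=float(lags_h.std(ddof=0)),
            lag_median_h=float(np.median(lags_h)),
            lag_mean_m=float(lags_m.mean()), lag_std_m=float(lags_m.std(ddof=0)),
            lag_median_m=float(np.median(lags_m)),
        )
    return out


# ---------------------------------------------------------------------------
# Oxygen exposure
# ---------------------------------------------------------------------------

def oxygen_exposure_fractions(
    label_map: np.ndarray,
    o2_field: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_EXPOSURE_THRESHOLDS,
) -> dict[float, float] | None:
    """Fraction of total colony area with oxygen strictly below each threshold.

    Area-weighted over colony pixels; nested by construction (a pixel below 1
    is also below 5, 10, 40).  A frame with no colony pixels has no defined
    fraction and returns ``None`` (missing), never zero.
    """
    lab = np.asarray(label_map)
    o2 = np.asarray(o2_field, float)
    sel = (lab > 0) & ~np.isnan(o2)
    total = int(sel.sum())
    if total == 0:
        return None
    vals = o2[sel]
    return {float(thr): float((vals < thr).sum() / total) for thr in thresholds}


def exposure_series(
    label_stack,
    o2_stack,
    times_h: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_EXPOSURE_THRESHOLDS,
    translation: DepthTranslation | None = None,
) -> pd.DataFrame:
    """Per-frame exposure fractions as a tidy table (NaN where undefined)."""
    translation = translation or DepthTranslation()
    rows = []
    for i, t in enumerate(times_h):
        frac = oxygen_exposure_fractions(label_stack[i], o2_stack[i], thresholds)
        row = {"frame_index": i, "time_h": float(t),
               "depth_m": translation.depth_m(float(t))}
        for thr in thresholds:
            row[f"frac_below_{thr:g}"] = np.nan if frac is None else frac[float(thr)]
        rows.append(row)
    return pd.DataFrame(rows)


def particle_mean_o2_series(
    tracks: list[ColonyTrack],
    translation: DepthTranslation | None = None,
) -> pd.DataFrame:
    """Per-frame mean of per-colony median oxygen across all tracks."""
    if not tracks:
        raise ValueError("at least one track is required")
    translation = translation or DepthTranslation()
    rows: dict[int, list] = {}
    times: dict[int, float] = {}
    for tr in tracks:
        for o in tr.observations:
            if np.isfinite(o.median_o2_umol_L):
                rows.setdefault(o.frame_index, []).append(o.median_o2_umol_L)
                times[o.frame_index] = o.time_h
    data = [
        {"frame_index": f, "time_h": times[f],
         "depth_m": translation.depth_m(times[f]),
         "mean_o2_umol_L": float(np.mean(v)), "n_colonies": len(v)}
        for f, v in sorted(rows.items())
    ]
    return pd.DataFrame(data)


def replicate_mean_o2_series(
    replicates: dict[str, list[ColonyTrack]],
    translation: DepthTranslation | None = None,
) -> pd.DataFrame:
    """Per-replicate mean-oxygen series plus the across-replicate mean.

    Mirrors reporting where a thick mean line overlays the individual
    particle replicates.
    """
    frames = []
    for name, tracks in replicates.items():
        df = particle_mean_o2_series(tracks, translation)
        df["replicate"] = name
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    mean = (
        long.groupby("frame_index")
        .agg(time_h=("time_h", "first"), depth_m=("depth_m", "first"),
             mean_o2_umol_L=("mean_o2_umol_L", "mean"))
        .reset_index()
    )
    mean["replicate"] = "mean"
    return pd.concat([long, mean], ignore_index=True)
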