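"""Per-particle, radially zoned two-endmember oxygen nanosensor calibration.

The sensor is a quenching-type oxygen nanoprobe: fluorescence is maximal under
anoxia and is progressively quenched as oxygen rises, following Stern–Volmer
kinetics ``F = F0 / (1 + Ksv * C)``.  Each particle carries its own pair of
calibration endmember frames — one acquired after nitrogen sparging (full
anoxia, ``C = 0``) and one under air-equilibrated flow (``C = saturation``) —
so nanoparticle-distribution heterogeneity is absorbed into a local, radially
zoned calibration: the particle is divided into annular zones by distance from
the edge and the median endmember fluorescence per zone anchors the inversion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import ParticleGeometry

logger = logging.getLogger(__name__)

#: Oxygen category thresholds, µmol L⁻¹, strict upper bounds.
OXYGEN_THRESHOLDS_UMOL_L: dict[str, float] = {
    "nanoxic": 1.0,
    "suboxic": 5.0,
    "microoxic": 10.0,
    "hypoxic": 40.0,
}

OXYGEN_CATEGORIES = ("nanoxic", "suboxic", "microoxic", "hypoxic", "oxic")


class CalibrationError(RuntimeError):
    """Raised when endmember frames cannot yield a usable calibration."""


@dataclass
class CalibrationModel:
    """Radially zoned two-endmember Stern–Volmer calibration.

    ``zone_edges_um`` partitions distance-from-edge into ``n_zones`` annuli;
    per zone the model stores the median anoxic and air-equilibrated
    fluorescence and the derived quenching constant
    ``Ksv = (F_anoxic / F_air - 1) / o2_saturation``.
    """

    zone_edges_um: np.ndarray       # (n_zones + 1,)
    f_anoxic: np.ndarray            # (n_zones,)
    f_air: np.ndarray               # (n_zones,)
    ksv: np.ndarray                 # (n_zones,), 1/(µmol L⁻¹)
    o2_saturation_umol_L: float
    zone_valid: np.ndarray          # (n_zones,), bool
    meta: dict = field(default_factory=dict)

    @property
    def n_zones(self) -> int:
        return len(self.ksv)

    def zone_of(self, distance_um: np.ndarray) -> np.ndarray:
        """Zone index for each distance-from-edge value (clipped to range)."""
        idx = np.digitize(distance_um, self.zone_edges_um) - 1
        return np.clip(idx, 0, self.n_zones - 1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "stern-volmer-two-endmember",
                "zone_edges_um": self.zone_edges_um.tolist(),
                "f_anoxic": self.f_anoxic.tolist(),
                "f_air": self.f_air.tolist(),
                "ksv_per_umol_L": self.ksv.tolist(),
                "o2_saturation_umol_L": self.o2_saturation_umol_L,
                "zone_valid": self.zone_valid.astype(int).tolist(),
                "meta": self.meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            zone_edges_um=np.asarray(d["zone_edges_um"], float),
            f_anoxic=np.asarray(d["f_anoxic"], float),
            f_air=np.asarray(d["f_air"], float),
            ksv=np.asarray(d["ksv_per_umol_L"], float),
            o2_saturation_umol_L=float(d["o2_saturation_umol_L"]),
            zone_valid=np.asarray(d["zone_valid"], bool),
            meta=d.get("meta", {}),
        )


def fit_calibration(
    anoxic_frame: np.ndarray,
    air_frame: np.ndarray,
    geometry: ParticleGeometry,
    n_zones: int = 20,
    o2_saturation_umol_L: float = 210.0,
    endmember_source: str = "own-particle",
) -> CalibrationModel:
    """Fit the zoned calibration from the two endmember frames.

    Zones are equal-width annuli of distance-from-edge covering the full
    particle.  A zone where ``F_anoxic <= F_air`` (no quenching contrast) is
    flagged invalid rather than silently interpolated; if *every* zone is
    invalid a :class:`CalibrationError` is raised.  A zone containing no
    particle pixels is an error outright.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if o2_saturation_umol_L <= 0:
        raise ValueError("o2_saturation must be positive")
    anoxic = np.asarray(anoxic_frame, float)
    air = np.asarray(air_frame, float)
    if anoxic.shape != geometry.particle_mask.shape or air.shape != anoxic.shape:
        raise ValueError("endmember frames must be co-registered with the geometry")

    mask = geometry.particle_mask
    dist = geometry.distance_to_edge_um
    d_max = float(max(dist[mask].max(), geometry.equivalent_radius_um))
    edges = np.linspace(0.0, d_max, n_zones + 1)
    # Right-closed top bin so the deepest pixel belongs to the last zone.
    idx = np.clip(np.digitize(dist, edges) - 1, 0, n_zones - 1)

    f_an = np.empty(n_zones)
    f_air = np.empty(n_zones)
    for z in range(n_zones):
        sel = mask & (idx == z)
        if not sel.any():
            raise CalibrationError(f"calibration zone {z} contains no particle pixels")
        f_an[z] = np.median(anoxic[sel])
        f_air[z] = np.median(air[sel])

    valid = (f_an > f_air) & (f_air > 0)
    if not valid.any():
        raise CalibrationError(
            "no valid calibration zone: anoxic endmember does not exceed "
            "air endmember anywhere (degenerate endmembers?)"
        )
    if not valid.all():
        logger.warning("calibration: %d/%d zones flagged invalid",
                       int((~valid).sum()), n_zones)
    ksv = np.full(n_zones, np.nan)
    ksv[valid] = (f_an[valid] / f_air[valid] - 1.0) / o2_saturation_umol_L
    return CalibrationModel(
        zone_edges_um=edges,
        f_anoxic=f_an,
        f_air=f_air,
        ksv=ksv,
        o2_saturation_umol_L=float(o2_saturation_umol_L),
        zone_valid=valid,
        meta={"inversion": "stern-volmer", "n_zones": n_zones,
              "endmember_source": endmember_source},
    )


def fluorescence_to_oxygen(
    frame: np.ndarray,
    model: CalibrationModel,
    geometry: ParticleGeometry,
) -> np.ndarray:
    """Invert sensor fluorescence to oxygen, µmol L⁻¹, pixel by pixel.

    ``C = (F_anoxic / F - 1) / Ksv`` with the zone-local ``F_anoxic`` and
    ``Ksv``; clipped to ``[0, saturation]``.  Pixels outside the particle,
    in invalid zones, or with non-positive fluorescence are returned as NaN
    (the non-positive ones are counted and logged).
    """
    f = np.asarray(frame, float)
    if f.shape != geometry.particle_mask.shape:
        raise ValueError("frame must be co-registered with the geometry")
    mask = geometry.particle_mask
    zone = model.zone_of(geometry.distance_to_edge_um)
    f_an = model.f_anoxic[zone]
    ksv = model.ksv[zone]
    valid_zone = model.zone_valid[zone]

    out = np.full(f.shape, np.nan)
    ok = mask & valid_zone & (f > 0)
    n_bad = int((mask & valid_zone & (f <= 0)).sum())
    if n_bad:
        logger.warning("fluorescence_to_oxygen: %d non-positive pixels masked", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (f_an / f - 1.0) / ksv
    out[ok] = np.clip(c[ok], 0.0, model.o2_saturation_umol_L)
    return out


def classify_oxygen(c: float) -> str:
    """Oxygen category of a concentration, µmol L⁻¹.

    Returns the most extreme category whose strict upper bound exceeds ``c``:
    nanoxic (<1), suboxic (<5), microoxic (<10), hypoxic (<40), else oxic.
    Boundaries are exclusive, so ``c = 40`` is oxic.  Negative values raise.
    """
    if np.isnan(c):
        raise ValueError("cannot classify NaN oxygen concentration")
    if c < 0:
        raise ValueError(f"negative oxygen concentration: {c}")
    for name, bound in OXYGEN_THRESHOLDS_UMOL_L.items():
        if c < bound:
            return name
    return "oxic"


def classify_oxygen_array(c: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_oxygen`; NaN pixels map to ``''``."""
    c = np.asarray(c, float)
    if np.nanmin(c) < 0:
        raise ValueError("negative oxygen concentration in array")
    out = np.full(c.shape, "", dtype=object)
    finite = ~np.isnan(c)
    out[finite] = "oxic"
    for name in ("hypoxic", "microoxic", "suboxic", "nanoxic"):
        out[finite & (c < OXYGEN_THRESHOLDS_UMOL_L[name])] = name
    return out
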