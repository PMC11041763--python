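"""Reading and writing of stacks, geometry, calibration, observations, tracks."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import ColonyObservation
from .synthetic_scene import (CalibrationFrames, DiauxicGrowthParams,
                              GroundTruth, ImageStack, SceneConfig)
from .tracking import ColonyTrack

OBSERVATION_COLUMNS = [
    "frame_index", "time_h", "label", "area_um2", "centroid_row_px",
    "centroid_col_px", "distance_to_edge_um", "median_o2_umol_L", "o2_category",
]


def write_stack(stack: ImageStack, out_dir: str | Path) -> None:
    """Multi-page TIFF per channel plus a timestamps sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "brightfield.tif", stack.brightfield.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(out / "sensor.tif", stack.sensor.astype(np.float32), photometric="minisblack")
    (out / "stack.json").write_text(json.dumps({
        "times_h": stack.times_h.tolist(),
        "pixel_size_um": stack.pixel_size_um,
    }))


def read_stack(in_dir: str | Path) -> ImageStack:
    d = Path(in_dir)
    meta = json.loads((d / "stack.json").read_text())
    return ImageStack(
        brightfield=tifffile.imread(d / "brightfield.tif"),
        sensor=tifffile.imread(d / "sensor.tif"),
        times_h=np.asarray(meta["times_h"], float),
        pixel_size_um=float(meta["pixel_size_um"]),
    )


def write_calibration_frames(cal: CalibrationFrames, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "calibration_anoxic.tif", cal.anoxic.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(out / "calibration_air.tif", cal.air.astype(np.float32), photometric="minisblack")


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    """Label maps as multi-page TIFF, scalar truth as a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "labels.tif", truth.labels.astype(np.int32), photometric="minisblack")
    tifffile.imwrite(out / "o2_truth.tif", truth.o2.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(out / "particle_mask.tif",
                     truth.particle_mask.astype(np.uint8), photometric="minisblack")
    tifffile.imwrite(out / "diatom_mask.tif", truth.diatom_mask.astype(np.uint8), photometric="minisblack")
    (out / "ground_truth.json").write_text(json.dumps({
        "areas_um2": {str(k): v.tolist() for k, v in truth.areas_um2.items()},
        "lag_windows_h": {str(k): list(v) for k, v in truth.lag_windows.items()},
        "colony_centers_px": {str(k): list(v)
                              for k, v in truth.colony_centers.items()},
    }))


def observations_to_frame(observations: list[ColonyObservation]) -> pd.DataFrame:
    """Tidy table: one row per colony per frame."""
    return pd.DataFrame([o.as_dict() for o in observations],
                        columns=OBSERVATION_COLUMNS)


def observations_from_frame(df: pd.DataFrame) -> list[ColonyObservation]:
    out = []
    for row in df.itertuples(index=False):
        out.append(ColonyObservation(
            frame_index=int(row.frame_index), time_h=float(row.time_h),
            label=int(row.label), area_um2=float(row.area_um2),
            centroid=(float(row.centroid_row_px), float(row.centroid_col_px)),
            distance_to_edge_um=float(row.distance_to_edge_um),
            median_o2_umol_L=float(row.median_o2_umol_L),
            o2_category=str(row.o2_category),
        ))
    return out


def tracks_to_frame(tracks: list[ColonyTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for o in tr.observations:
            d = o.as_dict()
            d["track_id"] = tr.track_id
            rows.append(d)
    return pd.DataFrame(rows, columns=["track_id", *OBSERVATION_COLUMNS])


def tracks_from_frame(df: pd.DataFrame) -> list[ColonyTrack]:
    tracks = []
    for tid, g in df.groupby("track_id"):
        obs = observations_from_frame(g.sort_values("frame_index"))
        tracks.append(ColonyTrack(
            track_id=int(tid), birth_frame=obs[0].frame_index,
            observations=obs,
            final_distance_to_edge_um=obs[-1].distance_to_edge_um,
        ))
    return tracks


def load_scene_config(path: str | Path) -> SceneConfig:
    """SceneConfig from a YAML run config."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "growth_law" in data:
        data["growth_law"] = DiauxicGrowthParams(**data["growth_law"])
    if "colony_seed_positions" in data and data["colony_seed_positions"] != "random":
        data["colony_seed_positions"] = [tuple(p)
                                         for p in data["colony_seed_positions"]]
    return SceneConfig(**data)


def dump_scene_config(config: SceneConfig, path: str | Path) -> None:
    d = asdict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
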