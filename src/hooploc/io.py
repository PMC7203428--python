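"""File formats: cameras JSON, tabular CSVs, interest-area JSON, config YAML.

All tabular artifacts are headered CSVs (world coordinates in meters, image
coordinates in pixels); cameras and interest areas are JSON; run
configuration is YAML. Floats round-trip at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .assignment import Detection, DetectionSet, OptimizationConfig, PlayerLocalization
from .detection import InterestArea
from .errors import SchemaError
from .geometry import CameraModel, Correspondence, ImagePoint, N_DLT_PARAMS, WorldPoint

PathLike = Union[str, Path]

DETECTIONS_COLUMNS = ["frame_id", "camera_id", "x", "y", "score"]
LOCALIZATIONS_COLUMNS = ["frame_id", "label", "method", "X", "Y", "Z", "n_points", "score"]
TRUTH_COLUMNS = ["frame", "label", "X", "Y", "Z"]
CORRESPONDENCE_COLUMNS = ["camera_id", "X", "Y", "Z", "x", "y"]


# ----------------------------------------------------------------- cameras


def save_cameras(models: Sequence[CameraModel], path: PathLike) -> None:
    payload = [
        {"camera_id": int(m.camera_id), "lambdas": [float(v) for v in m.lambdas]}
        for m in models
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_cameras(path: PathLike) -> list[CameraModel]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, list):
        raise SchemaError(f"{path}: expected a JSON array of cameras")
    models, seen = [], set()
    for entry in payload:
        try:
            camera_id = int(entry["camera_id"])
            lambdas = entry["lambdas"]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: camera entry missing camera_id/lambdas") from exc
        if len(lambdas) != N_DLT_PARAMS:
            raise SchemaError(
                f"{path}: camera {camera_id} has {len(lambdas)} lambdas, expected {N_DLT_PARAMS}"
            )
        if camera_id in seen:
            raise SchemaError(f"{path}: duplicate camera_id {camera_id}")
        seen.add(camera_id)
        models.append(CameraModel(camera_id=camera_id, lambdas=tuple(float(v) for v in lambdas)))
    return models


# -------------------------------------------------------------- detections


def save_detections(detections_by_frame: dict[int, Sequence[Detection]], path: PathLike) -> None:
    rows = [
        {
            "frame_id": frame_id,
            "camera_id": d.camera_id,
            "x": d.image.x,
            "y": d.image.y,
            "score": "" if d.score is None else d.score,
        }
        for frame_id in sorted(detections_by_frame)
        for d in detections_by_frame[frame_id]
    ]
    pd.DataFrame(rows, columns=DETECTIONS_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def load_detections(path: PathLike, cameras: Sequence[CameraModel]) -> dict[int, DetectionSet]:
    df = pd.read_csv(path)
    missing = set(DETECTIONS_COLUMNS) - {"score"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing detection columns {sorted(missing)}")
    out: dict[int, DetectionSet] = {}
    for frame_id, group in df.groupby("frame_id"):
        detections = [
            Detection(
                point_index=p,
                camera_id=int(row.camera_id),
                image=ImagePoint(float(row.x), float(row.y)),
                score=None if "score" not in df.columns or pd.isna(row.score) else float(row.score),
            )
            for p, row in enumerate(group.itertuples())
        ]
        out[int(frame_id)] = DetectionSet(int(frame_id), detections, list(cameras))
    return out


# ----------------------------------------------------------- localizations


def save_localizations(
    localizations_by_frame: dict[int, Sequence[PlayerLocalization]], path: PathLike
) -> None:
    rows = [
        {
            "frame_id": frame_id,
            "label": loc.label,
            "method": loc.method,
            "X": loc.position.X,
            "Y": loc.position.Y,
            "Z": loc.position.Z,
            "n_points": loc.n_points,
            "score": loc.score,
        }
        for frame_id in sorted(localizations_by_frame)
        for loc in localizations_by_frame[frame_id]
    ]
    pd.DataFrame(rows, columns=LOCALIZATIONS_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


def load_localizations(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LOCALIZATIONS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing localization columns {sorted(missing)}")
    return df


# ------------------------------------------------------------------- truth


def save_truth(truth_by_frame: dict[int, Sequence[tuple[int, WorldPoint]]], path: PathLike) -> None:
    rows = [
        {"frame": frame, "label": label, "X": p.X, "Y": p.Y, "Z": p.Z}
        for frame in sorted(truth_by_frame)
        for label, p in truth_by_frame[frame]
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def load_truth(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing truth columns {sorted(missing)}")
    return df


# --------------------------------------------------------- correspondences


def load_correspondences(path: PathLike) -> dict[int, list[Correspondence]]:
    df = pd.read_csv(path)
    missing = set(CORRESPONDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing correspondence columns {sorted(missing)}")
    out: dict[int, list[Correspondence]] = {}
    for row in df.itertuples():
        out.setdefault(int(row.camera_id), []).append(
            Correspondence(
                world=WorldPoint(float(row.X), float(row.Y), float(row.Z)),
                image=ImagePoint(float(row.x), float(row.y)),
                camera_id=int(row.camera_id),
            )
        )
    return out


# ---------------------------------------------------------- interest areas


def save_interest_areas(areas: Sequence[InterestArea], path: PathLike) -> None:
    payload = [
        {"camera_id": a.camera_id, "vertices": [[x, y] for x, y in a.vertices]} for a in areas
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_interest_areas(path: PathLike) -> dict[int, InterestArea]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    areas = {}
    for entry in payload:
        try:
            area = InterestArea(
                camera_id=int(entry["camera_id"]),
                vertices=tuple((float(x), float(y)) for x, y in entry["vertices"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad interest-area entry: {exc}") from exc
        areas[area.camera_id] = area
    return areas


# ------------------------------------------------------------------ config


def load_optimization_config(path: Optional[PathLike]) -> OptimizationConfig:
    """OptimizationConfig from a YAML file (missing keys take defaults)."""
    if path is None:
        return OptimizationConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a YAML mapping")
    allowed = {"tau_px", "h_min", "h_max", "mean_height", "max_players"}
    unknown = set(raw) - allowed - {"seed"}
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return OptimizationConfig(**{k: v for k, v in raw.items() if k in allowed})
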