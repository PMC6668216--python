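"""Readers and writers for the interchange formats.

Radial segmentation sets travel as JSON::

    {
      "subject_id": "S0001", "eye_id": "OD",
      "scans": [
        {"angle_deg": 0, "scale_x_um": 5.47, "scale_z_um": 3.87,
         "x_px": [...], "ilm_z_px": [...],
         "bm_z_px": [..., null, ...],        # null inside the BM opening
         "margin_left_idx": 486, "margin_right_idx": 537},
        ... exactly 6 scans at 0,30,60,90,120,150 degrees ...
      ]
    }

All indices are 0-based; depths are pixels with explicit microns-per-pixel
scales.  Macula grids are a CSV matrix of thickness in mm plus a JSON
sidecar with the pixel spacing and fovea position.  Volume results are a
tidy CSV with one row per (eye, representation, base mode).

Schema violations raise :class:`SchemaError` carrying a JSON-pointer-style
path to the offending element.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .types import (
    REQUIRED_ANGLES,
    MaculaGrid,
    RadialScanSet,
    SegmentedBScan,
    ValidationError,
    VolumeResult,
)

VOLUME_TABLE_COLUMNS = [
    "subject_id",
    "eye_id",
    "representation",
    "base_mode",
    "onhv_mm3",
    "bmdv_mm3",
    "cv_mm3",
]


class SchemaError(ValidationError):
    """Interchange file violates the documented schema."""

    def __init__(self, path: str, message: str) -> None:
        self.path = path
        super().__init__(f"{path}: {message}")


def _require(obj: dict, key: str, path: str) -> Any:
    if key not in obj:
        raise SchemaError(f"{path}/{key}", "missing required field")
    return obj[key]


def _scan_from_dict(d: dict, path: str) -> SegmentedBScan:
    for key in ("angle_deg", "scale_x_um", "scale_z_um", "x_px", "ilm_z_px",
                "bm_z_px", "margin_left_idx", "margin_right_idx"):
        _require(d, key, path)
    x = np.asarray(d["x_px"], dtype=float)
    ilm = np.asarray(d["ilm_z_px"], dtype=float)
    bm = np.array([np.nan if v is None else float(v) for v in d["bm_z_px"]])
    if not (x.size == ilm.size == bm.size):
        raise SchemaError(f"{path}/x_px", "trace arrays have unequal lengths")
    if np.any(np.diff(x) <= 0):
        raise SchemaError(f"{path}/x_px", "lateral samples must be strictly increasing")
    ml, mr = int(d["margin_left_idx"]), int(d["margin_right_idx"])
    if not (0 <= ml < mr < x.size):
        raise SchemaError(
            f"{path}/margin_left_idx",
            f"margins ({ml}, {mr}) must satisfy 0 <= left < right < {x.size}",
        )
    try:
        return SegmentedBScan(
            angle_deg=int(d["angle_deg"]),
            x_px=x,
            ilm_z_px=ilm,
            bm_z_px=bm,
            margin_left_idx=ml,
            margin_right_idx=mr,
            scale_x_um=float(d["scale_x_um"]),
            scale_z_um=float(d["scale_z_um"]),
        )
    except ValidationError as exc:
        raise SchemaError(path, str(exc)) from exc


def read_radial_set(path: str | Path, width_mm: float | None = None) -> RadialScanSet:
    """Load and validate a radial segmentation JSON file.

    Scans are truncated to a common width on load (the minimum scan width
    unless ``width_mm`` is given), so the result is ready for volumetry.
    """
    from .volumetrics import truncate_scan_set

    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise SchemaError("/", "top level must be an object")
    subject_id = str(_require(doc, "subject_id", ""))
    eye_id = str(_require(doc, "eye_id", ""))
    raw_scans = _require(doc, "scans", "")
    if not isinstance(raw_scans, list):
        raise SchemaError("/scans", "scans must be an array")
    scans = [_scan_from_dict(s, f"/scans/{i}") for i, s in enumerate(raw_scans)]
    angles = sorted(s.angle_deg for s in scans)
    if len(scans) != 6 or angles != sorted(REQUIRED_ANGLES):
        missing = sorted(set(REQUIRED_ANGLES) - set(angles))
        raise SchemaError(
            "/scans",
            f"expected 6 scans at angles {sorted(REQUIRED_ANGLES)}, got "
            f"{len(scans)}; missing angles: {missing}",
        )
    try:
        return truncate_scan_set(
            scans, subject_id=subject_id, eye_id=eye_id, width_mm=width_mm
        )
    except ValidationError as exc:
        raise SchemaError("/scans", str(exc)) from exc


def write_radial_set(scan_set: RadialScanSet, path: str | Path) -> None:
    """Serialize a radial scan set to the interchange JSON format."""
    doc = {
        "subject_id": scan_set.subject_id,
        "eye_id": scan_set.eye_id,
        "scans": [
            {
                "angle_deg": s.angle_deg,
                "scale_x_um": s.scale_x_um,
                "scale_z_um": s.scale_z_um,
                "x_px": s.x_px.tolist(),
                "ilm_z_px": s.ilm_z_px.tolist(),
                "bm_z_px": [None if not np.isfinite(v) else v for v in s.bm_z_px],
                "margin_left_idx": s.margin_left_idx,
                "margin_right_idx": s.margin_right_idx,
            }
            for s in scan_set.scans
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_macula_grid(csv_path: str | Path, sidecar_path: str | Path | None = None) -> MaculaGrid:
    """Load a macula thickness grid (CSV matrix, mm) and its JSON sidecar."""
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    thickness = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("pixel_dx_mm", "pixel_dy_mm", "fovea_xy_mm"):
        _require(meta, key, "")
    return MaculaGrid(
        thickness_mm=thickness,
        pixel_dx_mm=float(meta["pixel_dx_mm"]),
        pixel_dy_mm=float(meta["pixel_dy_mm"]),
        fovea_xy_mm=tuple(float(v) for v in meta["fovea_xy_mm"]),
    )


def write_macula_grid(grid: MaculaGrid, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    np.savetxt(csv_path, grid.thickness_mm, delimiter=",", fmt="%.6f")
    csv_path.with_suffix(".json").write_text(
        json.dumps(
            {
                "pixel_dx_mm": grid.pixel_dx_mm,
                "pixel_dy_mm": grid.pixel_dy_mm,
                "fovea_xy_mm": list(grid.fovea_xy_mm),
            }
        )
    )


def volume_table(
    results: Sequence[tuple[str, str, VolumeResult]]
) -> pd.DataFrame:
    """Tidy frame from (subject_id, eye_id, VolumeResult) triples."""
    if not results:
        raise ValidationError("no volume results to tabulate")
    rows = [
        {
            "subject_id": sid,
            "eye_id": eid,
            "representation": res.representation.mode,
            "base_mode": res.base_mode,
            "onhv_mm3": res.onhv_mm3,
            "bmdv_mm3": res.bmdv_mm3,
            "cv_mm3": res.cv_mm3,
        }
        for sid, eid, res in results
    ]
    return pd.DataFrame(rows, columns=VOLUME_TABLE_COLUMNS)


def write_volume_table(
    results: Sequence[tuple[str, str, VolumeResult]], path: str | Path
) -> pd.DataFrame:
    """Write volumes as tidy CSV, 6 decimals of mm^3 (sub-cubic-micron)."""
    df = volume_table(results)
    df.to_csv(path, index=False, float_format="%.6f")
    return df


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration: defaults < config file < command-line flags."""

    representations: tuple[str, ...] = ("traditional", "estimated", "excluded")
    base_mode: str = "chord"
    n_intervals: int = 510
    central_half_width_mm: float = 1.6
    width_mm: float | None = None  # None: min width of the sample
    seed: int = 0

    def __post_init__(self) -> None:
        for rep in self.representations:
            if rep not in ("traditional", "estimated", "excluded"):
                raise ValidationError(f"unknown representation {rep!r}")
        if self.base_mode not in ("chord", "sector"):
            raise ValidationError(f"unknown base_mode {self.base_mode!r}")
        if self.n_intervals < 1:
            raise ValidationError("n_intervals must be >= 1")
        if self.central_half_width_mm <= 0:
            raise ValidationError("central_half_width_mm must be positive")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides: Any) -> "RunConfig":
        values: dict[str, Any] = {}
        if path is not None:
            with open(path) as fh:
                values.update(json.load(fh))
        values.update({k: v for k, v in overrides.items() if v is not None})
        if "representations" in values:
            values["representations"] = tuple(values["representations"])
        return cls(**values)

    def dump(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["representations"] = list(self.representations)
        Path(path).write_text(json.dumps(doc, indent=2))
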