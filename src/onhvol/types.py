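"""Core domain types for radial OCT optic nerve head volumetry.

Depth convention: z increases posteriorly (away from the vitreous), so an
elevated (swollen) internal limiting membrane has a *smaller* z than Bruch's
membrane beneath it, and optic nerve head height = BM depth - ILM depth is
positive for normal anatomy.

All raw segmentations are stored in pixels with explicit microns-per-pixel
scales; lateral positions and depths are converted to millimetres on access.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

REQUIRED_ANGLES = (0, 30, 60, 90, 120, 150)
UM_PER_MM = 1000.0

BMMode = Literal["traditional", "estimated", "excluded"]
BaseMode = Literal["chord", "sector"]


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


@dataclass
class SegmentedBScan:
    """One segmented radial B-scan through the optic nerve head.

    ``bm_z_px`` is NaN at samples inside the BM opening, i.e. strictly
    between the rater-marked margin indices; it must be finite everywhere
    else.  ``x_px`` must be strictly increasing.
    """

    angle_deg: int
    x_px: np.ndarray
    ilm_z_px: np.ndarray
    bm_z_px: np.ndarray
    margin_left_idx: int
    margin_right_idx: int
    scale_x_um: float
    scale_z_um: float

    def __post_init__(self) -> None:
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.ilm_z_px = np.asarray(self.ilm_z_px, dtype=float)
        self.bm_z_px = np.asarray(self.bm_z_px, dtype=float)
        n = self.x_px.size
        if self.angle_deg not in REQUIRED_ANGLES:
            raise ValidationError(
                f"angle_deg must be one of {REQUIRED_ANGLES}, got {self.angle_deg}"
            )
        if self.ilm_z_px.size != n or self.bm_z_px.size != n:
            raise ValidationError("x_px, ilm_z_px, bm_z_px must have equal length")
        if n < 4:
            raise ValidationError("scan must have at least 4 lateral samples")
        if np.any(np.diff(self.x_px) <= 0):
            raise ValidationError("x_px must be strictly increasing")
        if not (self.scale_x_um > 0 and self.scale_z_um > 0):
            raise ValidationError("pixel scales must be strictly positive")
        ml, mr = self.margin_left_idx, self.margin_right_idx
        if not (0 <= ml < mr <= n - 1):
            raise ValidationError(
                f"margins must satisfy 0 <= left < right <= {n - 1}, "
                f"got ({ml}, {mr})"
            )
        if not np.all(np.isfinite(self.ilm_z_px)):
            raise ValidationError("ilm_z_px must be finite everywhere")
        outside = np.ones(n, dtype=bool)
        outside[ml + 1 : mr] = False
        if not np.all(np.isfinite(self.bm_z_px[outside])):
            raise ValidationError("bm_z_px must be finite outside the BM opening")

    # -- mm-space views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.x_px.size

    @property
    def center_x_px(self) -> float:
        """Assumed optic nerve head center: the lateral midpoint of the scan."""
        return 0.5 * (self.x_px[0] + self.x_px[-1])

    @property
    def x_mm(self) -> np.ndarray:
        """Lateral position in mm relative to the scan center (signed)."""
        return (self.x_px - self.center_x_px) * self.scale_x_um / UM_PER_MM

    @property
    def ilm_mm(self) -> np.ndarray:
        return self.ilm_z_px * self.scale_z_um / UM_PER_MM

    @property
    def bm_mm(self) -> np.ndarray:
        return self.bm_z_px * self.scale_z_um / UM_PER_MM

    @property
    def width_mm(self) -> float:
        return (self.x_px[-1] - self.x_px[0]) * self.scale_x_um / UM_PER_MM

    def trimmed(self, lo: int, hi: int) -> "SegmentedBScan":
        """Return a copy restricted to sample indices [lo, hi]."""
        if not (0 <= lo <= self.margin_left_idx and self.margin_right_idx <= hi < self.n_samples):
            raise ValidationError(
                f"truncation [{lo}, {hi}] would drop a BM opening margin "
                f"({self.margin_left_idx}, {self.margin_right_idx}) on scan "
                f"at {self.angle_deg} deg"
            )
        return replace(
            self,
            x_px=self.x_px[lo : hi + 1].copy(),
            ilm_z_px=self.ilm_z_px[lo : hi + 1].copy(),
            bm_z_px=self.bm_z_px[lo : hi + 1].copy(),
            margin_left_idx=self.margin_left_idx - lo,
            margin_right_idx=self.margin_right_idx - lo,
        )


@dataclass
class RadialScanSet:
    """One eye's six segmented radial B-scans after common-width truncation."""

    subject_id: str
    eye_id: str
    scans: list[SegmentedBScan]
    truncated_width_mm: float

    def __post_init__(self) -> None:
        angles = sorted(s.angle_deg for s in self.scans)
        if angles != sorted(REQUIRED_ANGLES):
            raise ValidationError(
                f"scan set must contain exactly the angles {REQUIRED_ANGLES}, got {angles}"
            )
        if not self.truncated_width_mm > 0:
            raise ValidationError("truncated_width_mm must be positive")
        self.scans = sorted(self.scans, key=lambda s: s.angle_deg)

    @property
    def radius_mm(self) -> float:
        """Truncation radius R: half the common scan width."""
        return 0.5 * self.truncated_width_mm

    def scan_at(self, angle_deg: int) -> SegmentedBScan:
        for s in self.scans:
            if s.angle_deg == angle_deg:
                return s
        raise KeyError(angle_deg)


@dataclass(frozen=True)
class BMRepresentation:
    """How Bruch's membrane is represented across the artifact-prone center.

    ``traditional`` joins the rater-marked opening margins with a straight
    chord; ``estimated`` replaces BM inside +/- ``central_half_width_mm``
    with a chord between the segmented BM points at that distance;
    ``excluded`` removes the central region from volume calculations
    entirely.
    """

    mode: BMMode = "traditional"
    central_half_width_mm: float = 1.6

    def __post_init__(self) -> None:
        if self.mode not in ("traditional", "estimated", "excluded"):
            raise ValidationError(f"unknown BM representation mode {self.mode!r}")
        if not self.central_half_width_mm > 0:
            raise ValidationError("central_half_width_mm must be positive")


@dataclass
class HalfScanProfile:
    """One of the 12 half-scans, resampled onto a common radial grid."""

    theta_deg: float
    r_mm: np.ndarray
    height_mm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.r_mm = np.asarray(self.r_mm, dtype=float)
        self.height_mm = np.asarray(self.height_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.r_mm.size == self.height_mm.size == self.valid.size):
            raise ValidationError("r_mm, height_mm, valid must have equal length")
        if self.r_mm[0] != 0.0 or np.any(np.diff(self.r_mm) <= 0):
            raise ValidationError("r_mm must start at 0 and be strictly increasing")
        if not (0.0 <= self.theta_deg < 360.0):
            raise ValidationError("theta_deg must be in [0, 360)")
        if not np.all(np.isfinite(self.height_mm[self.valid])):
            raise ValidationError("height_mm must be finite wherever valid")


@dataclass(frozen=True)
class SecantLine:
    """Per-scan reference line through the outermost segmented BM points.

    Depths at the left and right truncation edges; linearly interpolated
    between them.
    """

    z0_mm: float
    z1_mm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z0_mm) and np.isfinite(self.z1_mm)):
            raise ValidationError("secant endpoint depths must be finite")

    def depth_at(self, x_mm: np.ndarray, x0_mm: float, x1_mm: float) -> np.ndarray:
        t = (np.asarray(x_mm, dtype=float) - x0_mm) / (x1_mm - x0_mm)
        return self.z0_mm + t * (self.z1_mm - self.z0_mm)


@dataclass(frozen=True)
class VolumeResult:
    """Volumes (mm^3) for one eye under one BM representation and base mode."""

    onhv_mm3: float
    bmdv_mm3: float
    cv_mm3: float
    representation: BMRepresentation
    base_mode: BaseMode


@dataclass
class MaculaGrid:
    """2-D grid of ganglion cell complex thickness over the macula.

    Pixel (row j, col i) has its center at ((i + 0.5) * pixel_dx_mm,
    (j + 0.5) * pixel_dy_mm) in grid coordinates; fovea_xy_mm is given in
    the same frame.
    """

    thickness_mm: np.ndarray
    pixel_dx_mm: float
    pixel_dy_mm: float
    fovea_xy_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        if self.thickness_mm.ndim != 2:
            raise ValidationError("thickness_mm must be a 2-D grid")
        if np.any(self.thickness_mm < 0):
            raise ValidationError("thickness must be non-negative")
        if not (self.pixel_dx_mm > 0 and self.pixel_dy_mm > 0):
            raise ValidationError("pixel spacings must be positive")
        fx, fy = self.fovea_xy_mm
        ny, nx = self.thickness_mm.shape
        if not (0 <= fx <= nx * self.pixel_dx_mm and 0 <= fy <= ny * self.pixel_dy_mm):
            raise ValidationError("fovea center must lie inside the grid")


@dataclass(frozen=True)
class ModelFitTerm:
    name: str
    coef: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ModelFit:
    """Coefficients, Wald 95% CIs and p-values from a GEE or linear fit."""

    terms: list[ModelFitTerm]
    outcome: str
    predictors: list[str]
    cluster: str | None
    correlation_structure: str | None
    n_obs: int
    n_clusters: int
    pearson_r: float | None = None

    def term(self, name: str) -> ModelFitTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)
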