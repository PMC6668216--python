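"""Volume estimation from six radial OCT B-scans.

The pipeline converts per-scan ILM/BM segmentations into three volumes:

* ONHV — optic nerve head volume, the tissue between the ILM and a
  continuous BM boundary, with central ILM dips below the BM interpolation
  (the optic cup) excluded;
* BMDV — Bruch's membrane displacement volume, the signed volume between BM
  and a per-scan secant line through the outermost BM points (anterior
  deflection toward the vitreous counts negative);
* CV — cup volume, the space between the ILM and the line joining the ILM
  points immediately above the BM opening margins.

Each scan is split at the optic nerve head center into two half-scans,
giving 12 half-scans at 30 degree spacing.  Heights are resampled onto a
common radial grid and integrated as trapezoidal prisms over the 12 wedges
between adjacent half-scans.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .types import (
    REQUIRED_ANGLES,
    BaseMode,
    BMRepresentation,
    HalfScanProfile,
    MaculaGrid,
    RadialScanSet,
    SecantLine,
    SegmentedBScan,
    ValidationError,
    VolumeResult,
)

DEFAULT_N_INTERVALS = 510

# chord mode: planar trapezoid between two rays 30 degrees apart
_CHORD_FACTOR = math.sin(math.radians(15.0)) * math.cos(math.radians(15.0))
_SECTOR_FACTOR = math.pi / 12.0


# ---------------------------------------------------------------------------
# Truncation
# ---------------------------------------------------------------------------

def truncate_scan_set(
    scans: Sequence[SegmentedBScan],
    subject_id: str = "",
    eye_id: str = "",
    width_mm: float | None = None,
) -> RadialScanSet:
    """Truncate six radial scans to a common width about their centers.

    If ``width_mm`` is omitted it defaults to the minimum physical scan
    width in the set (the shortest scan dictates the common width).  Each
    scan keeps the samples within width/2 of its lateral midpoint; a BM
    opening margin falling outside the retained span is an error.
    """
    if len(scans) != 6:
        raise ValidationError(f"expected 6 scans, got {len(scans)}")
    angles = sorted(s.angle_deg for s in scans)
    if angles != sorted(REQUIRED_ANGLES):
        raise ValidationError(f"scan angles must be {REQUIRED_ANGLES}, got {angles}")

    widths = [s.width_mm for s in scans]
    if width_mm is None:
        width_mm = min(widths)
    tol = 1e-9 * width_mm
    for s, w in zip(scans, widths):
        if width_mm > w + tol:
            raise ValidationError(
                f"requested width {width_mm} mm exceeds scan width {w:.4f} mm "
                f"at {s.angle_deg} deg"
            )

    half = 0.5 * width_mm
    trimmed = []
    for s in scans:
        x = s.x_mm
        keep = np.abs(x) <= half + tol
        lo = int(np.argmax(keep))
        hi = int(len(keep) - 1 - np.argmax(keep[::-1]))
        trimmed.append(s.trimmed(lo, hi))
    return RadialScanSet(
        subject_id=subject_id, eye_id=eye_id, scans=trimmed, truncated_width_mm=width_mm
    )


# ---------------------------------------------------------------------------
# BM boundary representations
# ---------------------------------------------------------------------------

def bm_boundary(
    scan: SegmentedBScan, rep: BMRepresentation
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous BM depth curve (mm) and per-sample validity mask.

    traditional: the BM gap across the opening is bridged by a straight
    chord between the depths at the rater-marked margins; every sample is
    valid.

    estimated: BM inside +/- ``central_half_width_mm`` of the scan center
    is replaced by the chord between the segmented BM depths at exactly
    that distance on either side; outside, the segmentation is used
    unchanged.

    excluded: the segmentation is used where it exists outside the central
    half-width; samples strictly inside the central region are invalid
    (NaN curve) and are dropped from volume integration downstream.
    """
    x = scan.x_mm
    bm = scan.bm_mm.copy()
    ml, mr = scan.margin_left_idx, scan.margin_right_idx

    if rep.mode == "traditional":
        inside = slice(ml + 1, mr)
        t = (x[inside] - x[ml]) / (x[mr] - x[ml])
        bm[inside] = bm[ml] + t * (bm[mr] - bm[ml])
        return bm, np.ones_like(bm, dtype=bool)

    hw = rep.central_half_width_mm
    if hw >= abs(x[0]) or hw >= abs(x[-1]):
        raise ValidationError(
            "central_half_width_mm must be smaller than the truncation radius"
        )

    if rep.mode == "estimated":
        if not (x[ml] >= -hw - 1e-12 and x[mr] <= hw + 1e-12):
            raise ValidationError(
                "estimated BM representation requires segmented BM at "
                f"+/-{hw} mm, but the opening margins extend past that distance"
            )
        finite = np.isfinite(bm)
        z_left = float(np.interp(-hw, x[finite], bm[finite]))
        z_right = float(np.interp(hw, x[finite], bm[finite]))
        central = np.abs(x) < hw
        t = (x[central] + hw) / (2.0 * hw)
        bm[central] = z_left + t * (z_right - z_left)
        return bm, np.ones_like(bm, dtype=bool)

    # excluded
    valid = (np.abs(x) >= hw) & np.isfinite(bm)
    bm[~valid] = np.nan
    return bm, valid


def secant_of_scan(scan: SegmentedBScan) -> SecantLine:
    """Line through the segmented BM depths at the outermost retained samples."""
    bm = scan.bm_mm
    if not (np.isfinite(bm[0]) and np.isfinite(bm[-1])):
        raise ValidationError(
            f"BM undefined at an outermost sample of the {scan.angle_deg} deg scan"
        )
    return SecantLine(z0_mm=float(bm[0]), z1_mm=float(bm[-1]))


# ---------------------------------------------------------------------------
# Per-scan height surfaces
# ---------------------------------------------------------------------------

def onh_height(
    scan: SegmentedBScan, bm_curve: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optic nerve head height = BM depth - ILM depth, clamped at zero.

    Samples where the ILM lies posterior to the BM boundary (the optic
    cup) contribute zero height rather than negative volume.
    """
    if bm_curve.size != scan.n_samples or valid.size != scan.n_samples:
        raise ValidationError("bm_curve/valid length does not match the scan")
    h = bm_curve - scan.ilm_mm
    h = np.where(valid, np.maximum(h, 0.0), np.nan)
    return h, valid.copy()


def bm_displacement(
    scan: SegmentedBScan,
    bm_curve: np.ndarray,
    valid: np.ndarray,
    secant: SecantLine,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed BM displacement relative to the secant line (no clamping).

    Positive where BM lies posterior to (deeper than) the secant; negative
    where BM is deflected anteriorly toward the vitreous.
    """
    if bm_curve.size != scan.n_samples or valid.size != scan.n_samples:
        raise ValidationError("bm_curve/valid length does not match the scan")
    x = scan.x_mm
    sec = secant.depth_at(x, x[0], x[-1])
    d = np.where(valid, bm_curve - sec, np.nan)
    return d, valid.copy()


def cup_height(scan: SegmentedBScan) -> tuple[np.ndarray, np.ndarray]:
    """Cup depth below the line joining the ILM points above the BM margins.

    Between the margins, height = max(0, ILM depth - cup-top depth); where
    the ILM is anterior to the cup-top line the height is zero.  Outside
    the margins the height is zero and the mask is False.
    """
    x = scan.x_mm
    ilm = scan.ilm_mm
    ml, mr = scan.margin_left_idx, scan.margin_right_idx
    t = (x - x[ml]) / (x[mr] - x[ml])
    cup_top = ilm[ml] + t * (ilm[mr] - ilm[ml])
    h = np.maximum(ilm - cup_top, 0.0)
    mask = np.zeros_like(h, dtype=bool)
    mask[ml : mr + 1] = True
    h[~mask] = 0.0
    return h, mask


_SurfaceFn = Callable[[SegmentedBScan], tuple[np.ndarray, np.ndarray]]

SURFACES = ("onh_height", "bm_displacement", "cup_height")


def _surface_fn(surface: str, rep: BMRepresentation) -> _SurfaceFn:
    if surface == "onh_height":
        def fn(scan: SegmentedBScan) -> tuple[np.ndarray, np.ndarray]:
            bm, valid = bm_boundary(scan, rep)
            return onh_height(scan, bm, valid)
    elif surface == "bm_displacement":
        def fn(scan: SegmentedBScan) -> tuple[np.ndarray, np.ndarray]:
            bm, valid = bm_boundary(scan, rep)
            return bm_displacement(scan, bm, valid, secant_of_scan(scan))
    elif surface == "cup_height":
        # the cup is defined from the traditional opening geometry only
        def fn(scan: SegmentedBScan) -> tuple[np.ndarray, np.ndarray]:
            return cup_height(scan)
    else:
        raise ValidationError(f"unknown surface {surface!r}; expected one of {SURFACES}")
    return fn


# ---------------------------------------------------------------------------
# Radial resampling and wedge integration
# ---------------------------------------------------------------------------

def build_half_profiles(
    scan_set: RadialScanSet,
    surface: str,
    rep: BMRepresentation | None = None,
    n_intervals: int = DEFAULT_N_INTERVALS,
) -> list[HalfScanProfile]:
    """Resample a height surface onto 12 half-scan radial profiles.

    Each scan is split at its center into two half-scans at azimuths
    ``angle`` and ``angle + 180``; per-sample heights are linearly
    interpolated onto a uniform grid of ``n_intervals + 1`` nodes from the
    center (r = 0) to the truncation radius.  In the excluded BM
    representation, nodes with r strictly inside the central half-width
    are marked invalid for the ONH and displacement surfaces.
    """
    if n_intervals < 1:
        raise ValidationError("n_intervals must be >= 1")
    rep = rep if rep is not None else BMRepresentation()
    R = scan_set.radius_mm
    r_grid = np.linspace(0.0, R, n_intervals + 1)
    fn = _surface_fn(surface, rep)

    analytic_invalid = None
    if rep.mode == "excluded" and surface in ("onh_height", "bm_displacement"):
        analytic_invalid = r_grid < rep.central_half_width_mm

    profiles: list[HalfScanProfile] = []
    for scan in scan_set.scans:
        if scan.width_mm > scan_set.truncated_width_mm * (1 + 1e-9):
            raise ValidationError("scan set must be truncated before profiling")
        vals, valid = fn(scan)
        x = scan.x_mm
        for sign, theta in ((+1.0, float(scan.angle_deg)),
                            (-1.0, float(scan.angle_deg) + 180.0)):
            half = sign * x >= 0.0
            r = sign * x[half]
            v = vals[half]
            m = valid[half]
            order = np.argsort(r)
            r, v, m = r[order], v[order], m[order]
            if np.any(m):
                # heights come from valid samples only; beyond their range
                # np.interp holds the edge value (sub-sample-size error)
                hv = np.interp(r_grid, r[m], v[m])
                if analytic_invalid is not None:
                    node_valid = ~analytic_invalid
                else:
                    # a node is valid when bracketed by valid samples
                    ind = np.interp(r_grid, r, m.astype(float))
                    node_valid = ind >= 1.0 - 1e-9
                node_valid &= np.isfinite(hv)
            else:
                hv = np.full_like(r_grid, np.nan)
                node_valid = np.zeros_like(r_grid, dtype=bool)
            hv = np.where(node_valid, hv, np.nan)
            profiles.append(
                HalfScanProfile(theta_deg=theta % 360.0, r_mm=r_grid.copy(),
                                height_mm=hv, valid=node_valid)
            )
    profiles.sort(key=lambda p: p.theta_deg)
    return profiles


def integrate_wedges(
    profiles: Sequence[HalfScanProfile], base_mode: BaseMode = "chord"
) -> float:
    """Sum trapezoidal prisms over the 12 wedges between adjacent half-scans.

    Each prism spans one radial interval of one wedge; its volume is the
    wedge base area times the mean of the four corner heights (two radii x
    two bounding half-scans).  A prism with any invalid corner is dropped.

    base area per interval [r0, r1]:
      chord  — (r1^2 - r0^2) sin15 cos15, the planar trapezoid between the
               two bounding rays;
      sector — (pi/12)(r1^2 - r0^2), the annular sector.
    """
    if len(profiles) != 12:
        raise ValidationError(f"expected 12 half-scan profiles, got {len(profiles)}")
    ordered = sorted(profiles, key=lambda p: p.theta_deg)
    thetas = np.array([p.theta_deg for p in ordered])
    if not np.allclose(np.diff(thetas), 30.0):
        raise ValidationError("half-scan azimuths must be 30 degrees apart")
    r = ordered[0].r_mm
    for p in ordered[1:]:
        if p.r_mm.shape != r.shape or not np.allclose(p.r_mm, r):
            raise ValidationError("all profiles must share the same radial grid")
    if base_mode == "chord":
        factor = _CHORD_FACTOR
    elif base_mode == "sector":
        factor = _SECTOR_FACTOR
    else:
        raise ValidationError(f"unknown base_mode {base_mode!r}")

    H = np.stack([p.height_mm for p in ordered])          # (12, n+1)
    V = np.stack([p.valid for p in ordered])
    Hn = np.where(V, H, 0.0)
    base = factor * (r[1:] ** 2 - r[:-1] ** 2)            # (n,)

    Ha, Va = Hn, V
    Hb, Vb = np.roll(Hn, -1, axis=0), np.roll(V, -1, axis=0)
    corners_ok = Va[:, :-1] & Va[:, 1:] & Vb[:, :-1] & Vb[:, 1:]
    mean_h = 0.25 * (Ha[:, :-1] + Ha[:, 1:] + Hb[:, :-1] + Hb[:, 1:])
    return float(np.sum(base[None, :] * np.where(corners_ok, mean_h, 0.0)))


def compute_volumes(
    scan_set: RadialScanSet,
    rep: BMRepresentation | None = None,
    base_mode: BaseMode = "chord",
    n_intervals: int = DEFAULT_N_INTERVALS,
) -> VolumeResult:
    """ONHV, BMDV and CV for one eye under one BM representation.

    The secant for BMDV is always taken through the outermost segmented BM
    points of each truncated scan, for every representation.  CV is
    independent of the BM representation.
    """
    rep = rep if rep is not None else BMRepresentation()
    onhv = integrate_wedges(
        build_half_profiles(scan_set, "onh_height", rep, n_intervals), base_mode
    )
    bmdv = integrate_wedges(
        build_half_profiles(scan_set, "bm_displacement", rep, n_intervals), base_mode
    )
    cv = integrate_wedges(
        build_half_profiles(scan_set, "cup_height", rep, n_intervals), base_mode
    )
    return VolumeResult(
        onhv_mm3=onhv, bmdv_mm3=bmdv, cv_mm3=cv, representation=rep, base_mode=base_mode
    )


# ---------------------------------------------------------------------------
# Macula and QC utilities
# ---------------------------------------------------------------------------

def gcc_volume(grid: MaculaGrid, diameter_mm: float = 3.0) -> float:
    """Ganglion cell complex volume within a disk centered on the fovea.

    Sums thickness x pixel area over pixels whose centers fall inside the
    disk (default 3 mm diameter).  The disk must lie entirely inside the
    grid.
    """
    ny, nx = grid.thickness_mm.shape
    fx, fy = grid.fovea_xy_mm
    rad = 0.5 * diameter_mm
    if (fx - rad < 0 or fy - rad < 0
            or fx + rad > nx * grid.pixel_dx_mm or fy + rad > ny * grid.pixel_dy_mm):
        raise ValidationError("measurement disk extends beyond the macula grid")
    cx = (np.arange(nx) + 0.5) * grid.pixel_dx_mm
    cy = (np.arange(ny) + 0.5) * grid.pixel_dy_mm
    in_disk = (cx[None, :] - fx) ** 2 + (cy[:, None] - fy) ** 2 <= rad**2
    return float(
        np.sum(grid.thickness_mm[in_disk]) * grid.pixel_dx_mm * grid.pixel_dy_mm
    )


def rater_disagreement(
    seg_a: np.ndarray, seg_b: np.ndarray, threshold_px: float = 2.0
) -> np.ndarray:
    """Sample indices where two raters' boundary depths differ by more than
    ``threshold_px`` pixels (strict inequality)."""
    a = np.asarray(seg_a, dtype=float)
    b = np.asarray(seg_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("rater traces must have equal length")
    return np.nonzero(np.abs(a - b) > threshold_px)[0]
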