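"""Synthetic radial scan sets, macula grids and cohorts with known truth.

The radial phantom is built from analytic, radially symmetric surfaces so
that every volume estimator can be checked against a one-dimensional
quadrature oracle:

* Bruch's membrane: a flat reference plane at ``baseline_z_mm`` plus a
  quadratic bow ``bm_bow_mm * (1 - (r/R)^2)`` (positive = posterior bowing,
  i.e. away from the vitreous);
* ILM: the BM surface elevated by a Gaussian swelling bump
  ``bump_amp_mm * exp(-r^2 / (2 sigma^2))`` and optionally depressed by a
  central parabolic cup of depth ``cup_depth_mm`` within ``cup_radius_mm``;
* BM opening: the BM trace is withheld (NaN) for ``|x| <
  opening_radius_mm`` with rater margins placed at the sampling nodes
  flanking +/- opening_radius.

An optional ``asym(theta_deg, r_mm)`` hook adds an angular modulation to
the ILM elevation for asymmetry tests; the quadrature oracle is undefined
for asymmetric phantoms.

Cohort simulation draws per-subject intracranial pressure and per-eye
volumes from a linear generating law with subject-level random intercepts,
mirroring the paired-eye structure of a clinical ICP cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .types import (
    REQUIRED_ANGLES,
    BaseMode,
    BMRepresentation,
    MaculaGrid,
    RadialScanSet,
    SegmentedBScan,
    ValidationError,
)
from .volumetrics import truncate_scan_set

AsymFn = Callable[[float, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class PhantomParams:
    """Analytic surface parameters for one synthetic eye.

    Defaults describe a mildly swollen optic nerve head on a Spectralis-like
    sampling grid: 5.59 mm truncated width (R = 2.795 mm), 1.5 mm BM
    opening diameter, a 0.5 mm Gaussian swelling bump and a 0.1 mm
    posterior BM bow.
    """

    R_mm: float = 2.795
    opening_radius_mm: float = 0.75
    bump_amp_mm: float = 0.5
    bump_sigma_mm: float = 0.8
    bm_bow_mm: float = 0.1
    cup_depth_mm: float = 0.0
    cup_radius_mm: float = 0.4
    baseline_z_mm: float = 0.9
    n_samples_per_scan: int = 1024
    scale_z_um: float = 3.87

    def __post_init__(self) -> None:
        if not (self.R_mm > 0 and self.bump_sigma_mm > 0 and self.cup_radius_mm > 0):
            raise ValidationError("radii and sigma must be positive")
        if not 0 < self.opening_radius_mm < self.R_mm:
            raise ValidationError("opening_radius_mm must be in (0, R_mm)")
        if self.n_samples_per_scan < 16:
            raise ValidationError("n_samples_per_scan must be >= 16")
        if self.scale_z_um <= 0:
            raise ValidationError("scale_z_um must be positive")

    @property
    def scale_x_um(self) -> float:
        """Lateral sampling pitch implied by the scan width and sample count."""
        return 2.0 * self.R_mm * 1000.0 / (self.n_samples_per_scan - 1)

    # -- analytic surfaces (depth in mm, z increases posteriorly) --------

    def bm_depth(self, r: np.ndarray) -> np.ndarray:
        """Full BM depth, including across the opening."""
        r = np.asarray(r, dtype=float)
        return self.baseline_z_mm + self.bm_bow_mm * (1.0 - (r / self.R_mm) ** 2)

    def ilm_elevation(self, r: np.ndarray) -> np.ndarray:
        """ILM height above the local BM surface (bump minus cup dip)."""
        r = np.asarray(r, dtype=float)
        bump = self.bump_amp_mm * np.exp(-(r**2) / (2.0 * self.bump_sigma_mm**2))
        dip = np.where(
            r < self.cup_radius_mm,
            self.cup_depth_mm * (1.0 - (r / self.cup_radius_mm) ** 2),
            0.0,
        )
        return bump - dip

    def ilm_depth(self, r: np.ndarray) -> np.ndarray:
        return self.bm_depth(r) - self.ilm_elevation(r)


def make_radial_phantom(
    params: PhantomParams,
    subject_id: str = "PHANTOM",
    eye_id: str = "OD",
    asym: AsymFn | None = None,
    jitter_px_sd: float = 0.0,
    seed: int | None = None,
) -> RadialScanSet:
    """Sample the analytic surfaces into six radial B-scans.

    Each scan spans the diameter [-R, R] with ``n_samples_per_scan``
    uniformly spaced samples (both endpoints included), so the set is
    already at its common truncated width.  ``jitter_px_sd`` adds i.i.d.
    Gaussian pixel noise to both boundary traces (a crude segmentation
    error model).
    """
    n = params.n_samples_per_scan
    x_mm = np.linspace(-params.R_mm, params.R_mm, n)
    r = np.abs(x_mm)
    rng = np.random.default_rng(seed) if jitter_px_sd > 0 else None

    scans = []
    for angle in REQUIRED_ANGLES:
        ilm_mm = params.ilm_depth(r)
        if asym is not None:
            extra = np.where(
                x_mm >= 0,
                asym(float(angle), r),
                asym(float(angle) + 180.0, r),
            )
            ilm_mm = ilm_mm - extra
        bm_mm = params.bm_depth(r).copy()

        ml = int(np.nonzero(x_mm <= -params.opening_radius_mm)[0][-1])
        mr = int(np.nonzero(x_mm >= params.opening_radius_mm)[0][0])
        bm_mm[ml + 1 : mr] = np.nan

        ilm_px = ilm_mm * 1000.0 / params.scale_z_um
        bm_px = bm_mm * 1000.0 / params.scale_z_um
        if rng is not None:
            ilm_px = ilm_px + rng.normal(0.0, jitter_px_sd, n)
            jit = rng.normal(0.0, jitter_px_sd, n)
            bm_px = np.where(np.isfinite(bm_px), bm_px + jit, np.nan)

        scans.append(
            SegmentedBScan(
                angle_deg=angle,
                x_px=np.arange(n, dtype=float),
                ilm_z_px=ilm_px,
                bm_z_px=bm_px,
                margin_left_idx=ml,
                margin_right_idx=mr,
                scale_x_um=params.scale_x_um,
                scale_z_um=params.scale_z_um,
            )
        )
    return truncate_scan_set(scans, subject_id=subject_id, eye_id=eye_id)


# ---------------------------------------------------------------------------
# Quadrature oracle
# ---------------------------------------------------------------------------

_CHORD_OVER_SECTOR = 3.0 / math.pi  # inscribed-dodecagon / disk area ratio


def _rep_bm_depth(params: PhantomParams, rep: BMRepresentation, r: np.ndarray) -> np.ndarray:
    """BM depth under a representation, on a radial grid (symmetric case)."""
    bm = params.bm_depth(r)
    if rep.mode == "traditional":
        chord = params.bm_depth(np.array(params.opening_radius_mm))
        return np.where(r < params.opening_radius_mm, chord, bm)
    hw = rep.central_half_width_mm
    if hw >= params.R_mm:
        raise ValidationError("central_half_width_mm must be below the radius")
    if rep.mode == "estimated":
        if params.opening_radius_mm > hw:
            raise ValidationError("opening must lie within the estimation half-width")
        chord = params.bm_depth(np.array(hw))
        return np.where(r < hw, chord, bm)
    return bm  # excluded: the exclusion is applied as an integration mask


def phantom_oracle_volumes(
    params: PhantomParams,
    rep: BMRepresentation | None = None,
    base_mode: BaseMode = "chord",
    n_quad: int = 20001,
) -> dict[str, float]:
    """Ground-truth ONHV/BMDV/CV by dense 1-D radial quadrature.

    Valid only for radially symmetric phantoms: the solid of revolution
    2*pi * integral of r * h(r) dr is evaluated with the trapezoid rule on
    ``n_quad`` nodes, then scaled by 3/pi for chord-mode base areas (the
    inscribed-dodecagon to disk area ratio).
    """
    rep = rep if rep is not None else BMRepresentation()
    r = np.linspace(0.0, params.R_mm, n_quad)
    ilm = params.ilm_depth(r)
    bm_rep = _rep_bm_depth(params, rep, r)

    include = np.ones_like(r, dtype=bool)
    if rep.mode == "excluded":
        include = r >= rep.central_half_width_mm

    onh_h = np.where(include, np.maximum(bm_rep - ilm, 0.0), 0.0)
    secant_z = params.bm_depth(np.array(params.R_mm))  # same at both edges
    disp = np.where(include, bm_rep - secant_z, 0.0)

    cup_top = params.ilm_depth(np.array(params.opening_radius_mm))
    cup_h = np.where(
        r <= params.opening_radius_mm, np.maximum(ilm - cup_top, 0.0), 0.0
    )

    factor = 1.0 if base_mode == "sector" else _CHORD_OVER_SECTOR
    if base_mode not in ("chord", "sector"):
        raise ValidationError(f"unknown base_mode {base_mode!r}")

    def solid(h: np.ndarray) -> float:
        return factor * 2.0 * math.pi * float(np.trapezoid(r * h, r))

    return {"onhv_mm3": solid(onh_h), "bmdv_mm3": solid(disp), "cv_mm3": solid(cup_h)}


def calibrate_bump_amplitude(
    target_onhv_mm3: float,
    params: PhantomParams,
    rep: BMRepresentation | None = None,
    base_mode: BaseMode = "chord",
) -> float:
    """Bump amplitude A whose pure-bump oracle ONHV equals the target.

    The oracle ONHV of a phantom with no BM bow and no cup is exactly
    linear in A, so the calibration is a single division.  Bow and cup
    terms in ``params`` are ignored for the purpose of the calibration.
    """
    if target_onhv_mm3 < 0:
        raise ValidationError("target ONHV must be non-negative")
    pure = replace(params, bump_amp_mm=1.0, bm_bow_mm=0.0, cup_depth_mm=0.0)
    unit = phantom_oracle_volumes(pure, rep, base_mode)["onhv_mm3"]
    return target_onhv_mm3 / unit


def make_macula_phantom(
    thickness_mm: float = 0.1,
    grid_shape: tuple[int, int] = (512, 512),
    pixel_mm: float = 0.012,
    fovea_xy_mm: tuple[float, float] | None = None,
) -> MaculaGrid:
    """Uniform-thickness macula grid with the fovea at the grid center."""
    ny, nx = grid_shape
    if fovea_xy_mm is None:
        fovea_xy_mm = (0.5 * nx * pixel_mm, 0.5 * ny * pixel_mm)
    return MaculaGrid(
        thickness_mm=np.full(grid_shape, thickness_mm, dtype=float),
        pixel_dx_mm=pixel_mm,
        pixel_dy_mm=pixel_mm,
        fovea_xy_mm=fovea_xy_mm,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Generating law for a synthetic paired-eye ICP cohort.

    Per subject: ICP ~ Uniform(icp_range), one shared random intercept per
    outcome ~ Normal(0, sd_subject^2); both eyes are usable with
    probability ``p_both_eyes``.  Per eye: GCCV ~ Normal(gcc_mean, gcc_sd),
    and each volume = intercept + slope * ICP (+ gcc_coef * GCCV for ONHV)
    + subject effect + Normal(0, sd_eye^2) residual.

    Default intercepts and slopes are the univariable all-eyes estimates
    for the traditional BM representation (ONHV 4.606 + 0.136 * ICP mm^3,
    BMDV 2.100 - 0.038 * ICP mm^3); the cohort size and eye availability
    mirror the source cohort (17 subjects, 30 usable eyes).  The variance
    components are chosen to reproduce eye-level scatter comparable to the
    reported one-eye Pearson correlations (~0.7).
    """

    n_subjects: int = 17
    p_both_eyes: float = 13.0 / 17.0
    icp_range_cmH2O: tuple[float, float] = (10.0, 55.0)
    onhv_intercept_mm3: float = 4.606
    onhv_slope_mm3_per_cmH2O: float = 0.136
    bmdv_intercept_mm3: float = 2.100
    bmdv_slope_mm3_per_cmH2O: float = -0.038
    gcc_mean_mm3: float = 0.73
    gcc_sd_mm3: float = 0.05
    gcc_coef: float = 0.0
    cv_mean_mm3: float = 0.15
    cv_sd_mm3: float = 0.05
    sd_subject_mm3: float = 1.2
    sd_eye_mm3: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if not 0.0 <= self.p_both_eyes <= 1.0:
            raise ValidationError("p_both_eyes must be a probability")
        lo, hi = self.icp_range_cmH2O
        if not (0.0 < lo < hi < 100.0):
            raise ValidationError("ICP range must be within (0, 100) cm H2O")
        for s in (self.sd_subject_mm3, self.sd_eye_mm3, self.gcc_sd_mm3, self.cv_sd_mm3):
            if s < 0:
                raise ValidationError("scale parameters must be non-negative")


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a tidy per-eye cohort table from the generating law.

    Columns: subject_id, eye (OD/OS), icp_cmH2O, gccv_mm3, onhv_mm3,
    bmdv_mm3, cv_mm3.  Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.icp_range_cmH2O
    rows = []
    for s in range(params.n_subjects):
        sid = f"S{s + 1:04d}"
        icp = rng.uniform(lo, hi)
        u_onhv = rng.normal(0.0, params.sd_subject_mm3)
        u_bmdv = rng.normal(0.0, params.sd_subject_mm3)
        both = rng.random() < params.p_both_eyes
        if both:
            eyes = ["OD", "OS"]
        else:
            eyes = ["OD" if rng.random() < 0.5 else "OS"]
        for eye in eyes:
            gccv = max(rng.normal(params.gcc_mean_mm3, params.gcc_sd_mm3), 1e-3)
            onhv = (
                params.onhv_intercept_mm3
                + params.onhv_slope_mm3_per_cmH2O * icp
                + params.gcc_coef * gccv
                + u_onhv
                + rng.normal(0.0, params.sd_eye_mm3)
            )
            bmdv = (
                params.bmdv_intercept_mm3
                + params.bmdv_slope_mm3_per_cmH2O * icp
                + u_bmdv
                + rng.normal(0.0, params.sd_eye_mm3)
            )
            cv = max(params.cv_mean_mm3 + rng.normal(0.0, params.cv_sd_mm3), 0.0)
            rows.append(
                {
                    "subject_id": sid,
                    "eye": eye,
                    "icp_cmH2O": icp,
                    "gccv_mm3": gccv,
                    "onhv_mm3": onhv,
                    "bmdv_mm3": bmdv,
                    "cv_mm3": cv,
                }
            )
    return pd.DataFrame(rows)
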