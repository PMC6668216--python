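"""Unit and property tests for the per-scan geometry and wedge integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from onhvol import (
    BMRepresentation,
    PhantomParams,
    bm_boundary,
    bm_displacement,
    build_half_profiles,
    compute_volumes,
    cup_height,
    gcc_volume,
    integrate_wedges,
    make_macula_phantom,
    make_radial_phantom,
    onh_height,
    rater_disagreement,
    secant_of_scan,
    truncate_scan_set,
)
from onhvol.types import HalfScanProfile, MaculaGrid, ValidationError

from conftest import make_flat_scan, make_flat_scan_sextet

R = 2.795


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

class TestTruncation:
    def test_width_defaults_to_shortest_scan(self):
        widths = [5.59, 5.8, 5.8, 5.9, 5.9, 6.0]
        scans = [
            make_flat_scan(angle_deg=a, width_mm=w)
            for a, w in zip((0, 30, 60, 90, 120, 150), widths)
        ]
        ss = truncate_scan_set(scans)
        assert ss.truncated_width_mm == pytest.approx(5.59)
        for s in ss.scans:
            assert s.width_mm <= 5.59 + 1e-9

    def test_full_width_is_identity(self):
        scans = make_flat_scan_sextet(width_mm=5.8)
        ss = truncate_scan_set(scans, width_mm=5.8)
        for orig, trimmed in zip(scans, ss.scans):
            assert trimmed.n_samples == orig.n_samples
            np.testing.assert_array_equal(trimmed.x_px, orig.x_px)

    def test_width_exceeding_scan_is_an_error(self):
        scans = make_flat_scan_sextet(width_mm=5.8)
        with pytest.raises(ValidationError, match="exceeds"):
            truncate_scan_set(scans, width_mm=7.0)

    def test_margin_lost_by_truncation_is_an_error(self):
        scans = make_flat_scan_sextet(width_mm=5.8, opening_radius_mm=2.0)
        with pytest.raises(ValidationError, match="margin"):
            truncate_scan_set(scans, width_mm=3.0)

    def test_wrong_scan_count_rejected(self):
        scans = make_flat_scan_sextet()
        with pytest.raises(ValidationError):
            truncate_scan_set(scans[:5])


# ---------------------------------------------------------------------------
# BM boundary representations
# ---------------------------------------------------------------------------

class TestBMBoundary:
    def test_traditional_chord_between_equal_margins_is_horizontal(self):
        scan = make_flat_scan(opening_radius_mm=1.7, width_mm=5.59, bm_mm=0.9)
        bm, valid = bm_boundary(scan, BMRepresentation("traditional"))
        assert valid.all()
        center = np.argmin(np.abs(scan.x_mm))
        assert bm[center] == pytest.approx(0.9)
        assert np.all(np.isfinite(bm))

    def test_estimated_chord_of_linear_bm_is_the_line(self):
        scan = make_flat_scan()
        # tilt BM linearly in x, keeping the opening gap
        slope_px_per_mm = 10.0
        bm = scan.bm_z_px + slope_px_per_mm * scan.x_mm
        scan.bm_z_px = bm
        curve, valid = bm_boundary(scan, BMRepresentation("estimated"))
        expected = (
            np.full(scan.n_samples, 0.9) * 1000 / scan.scale_z_um
            + slope_px_per_mm * scan.x_mm
        ) * scan.scale_z_um / 1000
        np.testing.assert_allclose(curve, expected, atol=1e-9)
        assert valid.all()

    def test_excluded_invalidates_exactly_the_central_samples(self):
        scan = make_flat_scan()
        rep = BMRepresentation("excluded", central_half_width_mm=1.6)
        _, valid = bm_boundary(scan, rep)
        brute = np.abs(scan.x_mm) < 1.6
        assert np.count_nonzero(~valid) == np.count_nonzero(brute)

    def test_estimated_fails_when_opening_exceeds_half_width(self):
        scan = make_flat_scan(opening_radius_mm=1.8)
        with pytest.raises(ValidationError, match="estimated"):
            bm_boundary(scan, BMRepresentation("estimated", central_half_width_mm=1.6))


class TestSecant:
    def test_flat_bm_gives_flat_secant(self):
        scan = make_flat_scan(bm_mm=0.5)
        sec = secant_of_scan(scan)
        assert sec.z0_mm == pytest.approx(0.5)
        assert sec.z1_mm == pytest.approx(0.5)
        mid = sec.depth_at(np.array([0.0]), scan.x_mm[0], scan.x_mm[-1])
        assert mid[0] == pytest.approx(0.5)

    def test_secant_of_linear_bm_equals_bm(self):
        scan = make_flat_scan()
        scan.bm_z_px = scan.bm_z_px + 10.0 * scan.x_mm
        sec = secant_of_scan(scan)
        depth = sec.depth_at(scan.x_mm, scan.x_mm[0], scan.x_mm[-1])
        finite = np.isfinite(scan.bm_mm)
        np.testing.assert_allclose(depth[finite], scan.bm_mm[finite], atol=1e-12)

    def test_bm_missing_at_edge_is_an_error(self):
        scan = make_flat_scan()
        scan.bm_z_px[-1] = np.nan
        with pytest.raises(ValidationError, match="outermost"):
            secant_of_scan(scan)


# ---------------------------------------------------------------------------
# height surfaces
# ---------------------------------------------------------------------------

class TestHeightSurfaces:
    def test_coincident_boundaries_give_zero_height(self):
        scan = make_flat_scan(ilm_mm=0.9, bm_mm=0.9)
        bm, valid = bm_boundary(scan, BMRepresentation("traditional"))
        h, _ = onh_height(scan, bm, valid)
        np.testing.assert_allclose(h, 0.0, atol=1e-12)

    def test_uniform_separation_gives_uniform_height(self):
        scan = make_flat_scan(ilm_mm=0.6, bm_mm=0.9)
        bm, valid = bm_boundary(scan, BMRepresentation("traditional"))
        h, _ = onh_height(scan, bm, valid)
        np.testing.assert_allclose(h, 0.3, atol=1e-12)

    def test_ilm_dip_below_chord_contributes_zero(self):
        scan = make_flat_scan(ilm_mm=0.6, bm_mm=0.9)
        center = np.argmin(np.abs(scan.x_mm))
        lo, hi = center - 10, center + 10  # 20 central samples
        scan.ilm_z_px[lo:hi] = (0.9 + 0.1) * 1000 / scan.scale_z_um
        bm, valid = bm_boundary(scan, BMRepresentation("traditional"))
        h, _ = onh_height(scan, bm, valid)
        assert np.count_nonzero(h == 0.0) == 20
        assert np.all(h >= 0.0)

    def test_displacement_sign_convention(self):
        # tiny opening so the BM chord barely perturbs the central bow
        scan = make_flat_scan(bm_mm=0.9, opening_radius_mm=0.05)
        # bow BM anteriorly (toward vitreous, smaller z) by 0.1 mm at center
        x = scan.x_mm
        bow = 0.1 * (1 - (x / x[-1]) ** 2)
        scan.bm_z_px = scan.bm_z_px - bow * 1000 / scan.scale_z_um
        bm, valid = bm_boundary(scan, BMRepresentation("traditional"))
        d, _ = bm_displacement(scan, bm, valid, secant_of_scan(scan))
        center = np.argmin(np.abs(x))
        assert d[center] == pytest.approx(-0.1, abs=1e-3)
        assert d[center] < 0

    def test_displacement_zero_when_bm_is_secant(self):
        scan = make_flat_scan()
        bm, valid = bm_boundary(scan, BMRepresentation("traditional"))
        d, _ = bm_displacement(scan, bm, valid, secant_of_scan(scan))
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_cup_zero_when_ilm_is_anterior(self):
        scan = make_flat_scan(ilm_mm=0.6, bm_mm=0.9)
        h, mask = cup_height(scan)
        np.testing.assert_allclose(h, 0.0, atol=1e-12)
        assert mask[scan.margin_left_idx] and mask[scan.margin_right_idx]
        assert not mask[0]

    def test_parabolic_dip_depth_recovered(self):
        scan = make_flat_scan(ilm_mm=0.6)
        x = scan.x_mm
        dip = np.where(np.abs(x) < 0.4, 0.15 * (1 - (x / 0.4) ** 2), 0.0)
        scan.ilm_z_px = scan.ilm_z_px + dip * 1000 / scan.scale_z_um
        h, _ = cup_height(scan)
        assert h.max() == pytest.approx(0.15, abs=1e-9)


# ---------------------------------------------------------------------------
# profiles and integration
# ---------------------------------------------------------------------------

def flat_profiles(h: float = 1.0, n_intervals: int = 510, radius: float = R):
    r = np.linspace(0.0, radius, n_intervals + 1)
    return [
        HalfScanProfile(
            theta_deg=30.0 * k,
            r_mm=r,
            height_mm=np.full_like(r, h),
            valid=np.ones_like(r, dtype=bool),
        )
        for k in range(12)
    ]


class TestProfilesAndIntegration:
    def test_twelve_profiles_with_default_grid(self, swollen_scan_set):
        profs = build_half_profiles(swollen_scan_set, "onh_height")
        assert len(profs) == 12
        assert all(p.r_mm.size == 511 for p in profs)
        assert sorted(p.theta_deg for p in profs) == [30.0 * k for k in range(12)]

    def test_constant_surface_resamples_to_constant(self):
        ss = truncate_scan_set(make_flat_scan_sextet(ilm_mm=0.6, bm_mm=0.9))
        profs = build_half_profiles(ss, "onh_height", BMRepresentation("traditional"))
        for p in profs:
            np.testing.assert_allclose(p.height_mm, 0.3, atol=1e-12)

    def test_excluded_invalid_nodes_are_exactly_the_central_ones(self, swollen_scan_set):
        rep = BMRepresentation("excluded", central_half_width_mm=1.6)
        profs = build_half_profiles(swollen_scan_set, "onh_height", rep)
        for p in profs:
            np.testing.assert_array_equal(~p.valid, p.r_mm < 1.6)

    def test_flat_closed_form_chord(self):
        vol = integrate_wedges(flat_profiles(1.0), "chord")
        assert vol == pytest.approx(3 * R**2, rel=1e-12)

    def test_flat_closed_form_sector(self):
        vol = integrate_wedges(flat_profiles(1.0), "sector")
        assert vol == pytest.approx(math.pi * R**2, rel=1e-12)

    def test_gaussian_bump_matches_solid_of_revolution(self):
        A, sigma = 0.5, 0.8
        r = np.linspace(0.0, R, 511)
        h = A * np.exp(-(r**2) / (2 * sigma**2))
        profs = [
            HalfScanProfile(30.0 * k, r, h.copy(), np.ones_like(r, bool))
            for k in range(12)
        ]
        vol = integrate_wedges(profs, "sector")
        exact = 2 * math.pi * sigma**2 * A * (1 - math.exp(-(R**2) / (2 * sigma**2)))
        assert vol == pytest.approx(exact, rel=5e-3)

    def test_sector_convergence_and_chord_ratio(self):
        sigma, A = 0.9, 0.4
        exact = 2 * math.pi * sigma**2 * A * (1 - math.exp(-(R**2) / (2 * sigma**2)))
        errs = []
        for n in (50, 510):
            r = np.linspace(0.0, R, n + 1)
            h = A * np.exp(-(r**2) / (2 * sigma**2))
            profs = [
                HalfScanProfile(30.0 * k, r, h.copy(), np.ones_like(r, bool))
                for k in range(12)
            ]
            sector = integrate_wedges(profs, "sector")
            chord = integrate_wedges(profs, "chord")
            errs.append(abs(sector - exact))
            assert chord == pytest.approx(sector * 3.0 / math.pi, rel=1e-12)
        assert errs[1] < errs[0]

    def test_invalid_corner_removes_prism(self):
        profs = flat_profiles(1.0, n_intervals=10)
        profs[0].valid[5] = False
        full = integrate_wedges(flat_profiles(1.0, n_intervals=10), "sector")
        partial = integrate_wedges(profs, "sector")
        # node 5 is a corner of intervals 4 and 5 in the two wedges adjacent
        # to half-scan 0
        r = profs[0].r_mm
        lost = 2 * (math.pi / 12) * ((r[5] ** 2 - r[4] ** 2) + (r[6] ** 2 - r[5] ** 2))
        assert full - partial == pytest.approx(lost, rel=1e-12)

    def test_mismatched_grids_rejected(self):
        profs = flat_profiles(1.0, n_intervals=10)
        bad = flat_profiles(1.0, n_intervals=12)
        with pytest.raises(ValidationError):
            integrate_wedges(profs[:11] + [bad[11]], "sector")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(0.0, 10.0), seed=st.integers(0, 2**16))
    def test_scaling_heights_scales_volume_linearly(self, c, seed):
        rng = np.random.default_rng(seed)
        r = np.linspace(0.0, R, 51)
        profs, scaled = [], []
        for k in range(12):
            h = rng.uniform(0.0, 1.0, r.size)
            valid = rng.uniform(size=r.size) > 0.1
            profs.append(HalfScanProfile(30.0 * k, r, h, valid))
            scaled.append(HalfScanProfile(30.0 * k, r, c * h, valid.copy()))
        v = integrate_wedges(profs, "chord")
        assert integrate_wedges(scaled, "chord") == pytest.approx(c * v, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(offset=st.floats(-0.5, 0.5), seed=st.integers(0, 2**16))
    def test_constant_offset_shifts_volume_by_masked_flat_volume(self, offset, seed):
        rng = np.random.default_rng(seed)
        r = np.linspace(0.0, R, 51)
        heights = [rng.uniform(-1, 1, r.size) for _ in range(12)]
        valids = [rng.uniform(size=r.size) > 0.2 for _ in range(12)]
        base = [HalfScanProfile(30 * k, r, h, v) for k, (h, v) in enumerate(zip(heights, valids))]
        shifted = [
            HalfScanProfile(30 * k, r, h + offset, v.copy())
            for k, (h, v) in enumerate(zip(heights, valids))
        ]
        ones = [
            HalfScanProfile(30 * k, r, np.ones_like(r), v.copy())
            for k, v in enumerate(valids)
        ]
        lhs = integrate_wedges(shifted, "sector") - integrate_wedges(base, "sector")
        rhs = offset * integrate_wedges(ones, "sector")
        assert lhs == pytest.approx(rhs, abs=1e-10)


class TestComputeVolumes:
    def test_flat_phantom_has_zero_volumes(self, representation):
        params = PhantomParams(bump_amp_mm=0.0, bm_bow_mm=0.0, cup_depth_mm=0.0)
        ss = make_radial_phantom(params)
        res = compute_volumes(ss, representation, "sector")
        assert res.onhv_mm3 == pytest.approx(0.0, abs=1e-9)
        assert res.bmdv_mm3 == pytest.approx(0.0, abs=1e-9)
        assert res.cv_mm3 == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_bow_bmdv_closed_form(self):
        params = PhantomParams(
            bump_amp_mm=0.0, bm_bow_mm=0.1, opening_radius_mm=0.05
        )
        ss = make_radial_phantom(params)
        sector = compute_volumes(ss, BMRepresentation("traditional"), "sector")
        exact = 0.1 * math.pi * R**2 / 2
        assert sector.bmdv_mm3 == pytest.approx(exact, rel=5e-3)
        chord = compute_volumes(ss, BMRepresentation("traditional"), "chord")
        assert chord.bmdv_mm3 == pytest.approx(exact * 3 / math.pi, rel=5e-3)

    def test_cup_exclusion_consistency(self):
        # deep cup dipping below the BM chord: clamping the ILM at the
        # chord must not change ONHV
        params = PhantomParams(
            bump_amp_mm=0.2, bm_bow_mm=0.0, cup_depth_mm=0.5, cup_radius_mm=0.5
        )
        ss = make_radial_phantom(params)
        rep = BMRepresentation("traditional")
        onhv_raw = compute_volumes(ss, rep, "sector").onhv_mm3
        clamped = make_radial_phantom(params)
        for scan in clamped.scans:
            bm, _ = bm_boundary(scan, rep)
            bm_px = bm * 1000.0 / scan.scale_z_um
            scan.ilm_z_px = np.minimum(scan.ilm_z_px, bm_px)
        onhv_clamped = compute_volumes(clamped, rep, "sector").onhv_mm3
        assert onhv_raw == pytest.approx(onhv_clamped, rel=1e-12)

    def test_representation_nesting_for_linear_central_bm(self):
        # flat BM is linear within +/-1.6 mm, margins inside: traditional
        # and estimated must agree to floating point
        params = PhantomParams(bump_amp_mm=0.5, bm_bow_mm=0.0)
        ss = make_radial_phantom(params)
        trad = compute_volumes(ss, BMRepresentation("traditional"), "chord")
        est = compute_volumes(ss, BMRepresentation("estimated"), "chord")
        assert trad.onhv_mm3 == pytest.approx(est.onhv_mm3, rel=1e-12)
        assert trad.bmdv_mm3 == pytest.approx(est.bmdv_mm3, abs=1e-12)

    def test_excluded_onhv_bounded_by_estimated(self, swollen_scan_set):
        excl = compute_volumes(swollen_scan_set, BMRepresentation("excluded"), "chord")
        est = compute_volumes(swollen_scan_set, BMRepresentation("estimated"), "chord")
        assert abs(excl.onhv_mm3) <= est.onhv_mm3


# ---------------------------------------------------------------------------
# macula and QC
# ---------------------------------------------------------------------------

class TestGCCVolume:
    def test_uniform_thickness_matches_cylinder(self):
        grid = make_macula_phantom(thickness_mm=0.1, grid_shape=(512, 512), pixel_mm=0.012)
        vol = gcc_volume(grid, diameter_mm=3.0)
        assert vol == pytest.approx(0.1 * math.pi * 1.5**2, rel=1e-2)

    def test_two_mm_disk(self):
        grid = make_macula_phantom(thickness_mm=0.1)
        assert gcc_volume(grid, diameter_mm=2.0) == pytest.approx(
            0.1 * math.pi * 1.0**2, rel=1e-2
        )

    def test_zero_thickness_gives_zero(self):
        grid = make_macula_phantom(thickness_mm=0.0)
        assert gcc_volume(grid) == 0.0

    def test_disk_outside_grid_is_an_error(self):
        grid = MaculaGrid(
            thickness_mm=np.full((50, 50), 0.1),
            pixel_dx_mm=0.02,
            pixel_dy_mm=0.02,
            fovea_xy_mm=(0.5, 0.5),
        )
        with pytest.raises(ValidationError, match="disk"):
            gcc_volume(grid, diameter_mm=3.0)


class TestRaterDisagreement:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            (np.zeros(50), []),
            (np.eye(1, 50, 7).ravel() * 3.0, [7]),
            (np.full(50, 2.0), []),  # exactly at threshold: strict inequality
        ],
    )
    def test_threshold_rule(self, delta, expected):
        a = np.full(50, 100.0)
        assert rater_disagreement(a, a + delta).tolist() == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rater_disagreement(np.zeros(5), np.zeros(6))
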