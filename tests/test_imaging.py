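"""Bead z-tracking pipeline and confocal volume measurement."""

import numpy as np
import pytest

from porocell.imaging import (
    Calibration,
    calibrate,
    find_centroid,
    outer_ring_radius,
    radial_projection,
    track_trajectory,
    volume_from_stack,
)
from porocell.imaging.centroid import CentroidError
from porocell.imaging.ring import RadialProfile, RingDetectionError
from porocell.synthdata import (
    ConfocalSpec,
    RingImageSpec,
    gen_calibration_stack,
    gen_confocal_stack,
    gen_defocus_series,
    render_defocus_frame,
)

RING = RingImageSpec()


def naive_radial_projection(img, center, delta=1.0):
    """Independent per-pixel double-loop oracle for the annulus averaging."""
    xc, yc = center
    n = int(np.ceil(np.hypot(*img.shape) / delta)) + 2
    wsum = np.zeros(n)
    isum = np.zeros(n)
    for iy in range(img.shape[0]):
        for ix in range(img.shape[1]):
            d = np.hypot(ix - xc, iy - yc)
            i = int(d // delta)
            w_hi = d / delta - i
            wsum[i] += 1 - w_hi
            isum[i] += (1 - w_hi) * img[iy, ix]
            wsum[i + 1] += w_hi
            isum[i + 1] += w_hi * img[iy, ix]
    with np.errstate(invalid="ignore"):
        return np.where(wsum > 0, isum / np.where(wsum > 0, wsum, 1), np.nan)


class TestCentroid:
    def test_recovers_subpixel_center(self):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[0:64, 0:64]
        img = 500 * np.exp(-(((xx - 40.3) ** 2 + (yy - 17.7) ** 2) / (2 * 2.0**2)))
        img = rng.poisson(img + 10).astype(float)
        cen = find_centroid(img, (40, 18))
        assert abs(cen.x - 40.3) < 0.1
        assert abs(cen.y - 17.7) < 0.1

    def test_symmetric_image_gives_geometric_center(self):
        yy, xx = np.mgrid[0:41, 0:41]
        img = 100 * np.exp(-((xx - 20.0) ** 2 + (yy - 20.0) ** 2) / 8.0) + 5
        cen = find_centroid(img, (20, 20))
        assert cen.x == pytest.approx(20.0, abs=1e-6)
        assert cen.y == pytest.approx(20.0, abs=1e-6)

    def test_flat_image_raises(self):
        rng = np.random.default_rng(1)
        img = rng.normal(100, 3, size=(64, 64))
        with pytest.raises(CentroidError):
            find_centroid(img, (32, 32))

    def test_seed_outside_image_rejected(self):
        with pytest.raises(ValueError):
            find_centroid(np.zeros((10, 10)), (50, 5))


class TestRadialProjection:
    def test_uniform_image_gives_constant_profile(self):
        img = np.full((40, 40), 7.5)
        prof = radial_projection(img, (19.5, 19.5))
        finite = np.isfinite(prof.intensity)
        assert np.allclose(prof.intensity[finite], 7.5, atol=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64))
        prof = radial_projection(img, (31.2, 30.7))
        oracle = naive_radial_projection(img, (31.2, 30.7))
        n = prof.intensity.size
        both = np.isfinite(prof.intensity) & np.isfinite(oracle[:n])
        assert np.max(np.abs(prof.intensity[both] - oracle[:n][both])) < 1e-10

    def test_single_pixel_at_annulus_node(self):
        img = np.zeros((21, 21))
        img[10, 15] = 3.0  # distance exactly 5 from center
        prof = radial_projection(img, (10.0, 10.0))
        assert prof.intensity[5] > 0  # full weight into annulus 5
        # neighbouring annuli got weight from other (zero) pixels only
        assert prof.intensity[4] == 0 and prof.intensity[6] == 0

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(3)
        img = rng.random((48, 48)) * 100
        prof = radial_projection(img, (23.3, 24.1))
        finite = np.isfinite(prof.intensity)
        total = np.sum(prof.intensity[finite] * prof.weights[finite])
        assert total == pytest.approx(img.sum(), rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            radial_projection(np.ones((10, 10)), (20, 5))
        with pytest.raises(ValueError):
            radial_projection(np.ones((10, 10)), (5, 5), delta=0.0)


class TestOuterRing:
    def test_annular_gaussian_tail_position(self):
        # independent 1D oracle: the rendered intensity is an exact radial
        # function f(r) = blob + ring + baseline; apply the triangular
        # annulus binning to f analytically (area-weighted quadrature, no
        # pixels involved) and locate the outermost 5% crossing of the
        # binned profile by the same interpolation rule
        frame = render_defocus_frame(1.5, RING, rng=None)
        r0 = (1.5 - RING.cal_intercept) / RING.cal_slope
        ny, nx = RING.shape
        max_r = min(RING.center[0], RING.center[1],
                    nx - 1 - RING.center[0], ny - 1 - RING.center[1])
        amp = RING.ring_peak * np.sqrt(0.5 * max_r / r0)

        def f(r):
            return (RING.blob_amp * np.exp(-(r**2) / (2 * RING.blob_sigma**2))
                    + amp * np.exp(-((r - r0) ** 2) / (2 * RING.ring_width**2))
                    + RING.baseline)

        centers = np.arange(int(max_r) + 1, dtype=float)
        binned = np.empty_like(centers)
        for i, ri in enumerate(centers):
            rr = np.linspace(max(ri - 1.0, 0.0), ri + 1.0, 2001)
            w = np.clip(1.0 - np.abs(rr - ri), 0.0, None) * rr
            binned[i] = np.trapezoid(w * f(rr), rr) / max(np.trapezoid(w, rr), 1e-300)
        y = binned / binned.max()
        above = np.flatnonzero(y > 0.05)
        i = above[-1]
        expected = centers[i] + (y[i] - 0.05) / (y[i] - y[i + 1])

        prof = radial_projection(frame.intensity, RING.center)
        rad = outer_ring_radius(prof)
        assert rad == pytest.approx(expected, abs=0.1)

    def test_reproducible_across_noise_seeds(self):
        rads = []
        for seed in range(6):
            frame = render_defocus_frame(1.5, RING, rng=np.random.default_rng(seed))
            prof = radial_projection(frame.intensity, RING.center)
            rads.append(outer_ring_radius(prof))
        assert np.ptp(rads) < 0.2

    def test_scale_invariance(self):
        frame = render_defocus_frame(1.5, RING, rng=None)
        p1 = radial_projection(frame.intensity, RING.center)
        p2 = radial_projection(10.0 * frame.intensity, RING.center)
        assert outer_ring_radius(p1) == pytest.approx(outer_ring_radius(p2), abs=1e-12)

    def test_constant_profile_raises(self):
        prof = RadialProfile(r=np.arange(10.0), intensity=np.full(10, 0.05),
                             weights=2 * np.pi * np.arange(10.0) + 1, delta=1.0)
        with pytest.raises(RingDetectionError):
            outer_ring_radius(prof)


class TestCalibration:
    def test_exact_line_recovered(self):
        radii = np.array([10.0, 20.0, 30.0, 40.0])
        pairs = [(r, 0.05 * r + 1.0) for r in radii]
        cal = calibrate(pairs)
        assert cal.slope == pytest.approx(0.05, rel=1e-12)
        assert cal.intercept == pytest.approx(1.0, rel=1e-12)
        assert cal.fit_residual == pytest.approx(0.0, abs=1e-12)

    def test_pair_order_irrelevant(self):
        pairs = [(10.0, 1.5), (30.0, 2.5), (20.0, 2.0), (25.0, 2.3)]
        a = calibrate(pairs)
        b = calibrate(pairs[::-1])
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            calibrate([(10.0, 1.0), (10.0, 2.0), (10.0, 3.0)])
        with pytest.raises(ValueError):
            calibrate([(10.0, 1.0), (20.0, 2.0)])

    def test_extrapolation_guard(self):
        cal = Calibration(slope=0.05, intercept=0.0, fit_residual=0.0,
                          valid_range=(10.0, 40.0))
        with pytest.raises(ValueError):
            cal.z_of_radius(80.0)
        assert cal.z_of_radius(80.0, extrapolate=True) == pytest.approx(4.0)

    def test_synthetic_stack_recovery(self):
        """End-to-end: 100 nm steps -> slope within 2%, residual <= 10 nm."""
        frames, truth = gen_calibration_stack(RING, z_start=1.1, n_steps=12, seed=4)
        pairs = []
        for f, z in zip(frames, truth["z"]):
            cen = find_centroid(f.intensity, (48, 48))
            prof = radial_projection(f.intensity, (cen.x, cen.y))
            pairs.append((outer_ring_radius(prof), z))
        cal = calibrate(pairs)
        assert abs(cal.slope / RING.cal_slope - 1.0) < 0.02
        assert cal.fit_residual <= 0.010  # um


@pytest.fixture(scope="module")
def fitted_cal():
    frames, truth = gen_calibration_stack(RING, z_start=1.1, n_steps=12, seed=11)
    pairs = []
    for f, z in zip(frames, truth["z"]):
        cen = find_centroid(f.intensity, (48, 48))
        prof = radial_projection(f.intensity, (cen.x, cen.y))
        pairs.append((outer_ring_radius(prof), z))
    return calibrate(pairs)


class TestTracking:
    def test_swelling_trajectory_rms_within_10nm(self, fitted_cal):
        from porocell.analytic import Slab1D, ramp_response
        from porocell.materials import PoroelasticMaterial, RampLoad

        mat = PoroelasticMaterial(E=1.0, nu=0.3, D=10.0)
        t = 0.1 * np.arange(100)
        c = ramp_response(t, mat, RampLoad(0.05, 0.0), Slab1D(5.5))
        z = 1.2 + 0.4 * c.delta / c.delta_inf
        frames, _ = gen_defocus_series((t, z), RING, seed=12)
        traj = track_trajectory(frames, (48, 48), fitted_cal)
        assert traj.reliable
        err = traj.z[traj.ok] - (z - z[0])[traj.ok]
        assert np.sqrt(np.mean(err**2)) <= 0.010  # um

    def test_static_bead_within_noise_floor(self, fitted_cal):
        t = 0.1 * np.arange(30)
        frames, _ = gen_defocus_series((t, np.full(30, 1.5)), RING, seed=13)
        traj = track_trajectory(frames, (48, 48), fitted_cal)
        assert np.max(np.abs(traj.z[traj.ok])) < 0.010

    def test_shuffled_frames_reordered_by_timestamp(self, fitted_cal):
        t = 0.1 * np.arange(20)
        z = 1.2 + 0.02 * np.arange(20)
        frames, _ = gen_defocus_series((t, z), RING, seed=14)
        traj_fwd = track_trajectory(frames, (48, 48), fitted_cal)
        rng = np.random.default_rng(0)
        shuffled = list(frames)
        rng.shuffle(shuffled)
        traj_shuf = track_trajectory(shuffled, (48, 48), fitted_cal)
        assert np.array_equal(traj_fwd.t, traj_shuf.t)
        assert np.allclose(traj_fwd.z, traj_shuf.z, equal_nan=True)

    def test_failed_frames_flagged_not_interpolated(self, fitted_cal):
        t = 0.1 * np.arange(10)
        z = np.full(10, 1.5)
        frames, _ = gen_defocus_series((t, z), RING, seed=15)
        frames[4].intensity[:] = 50.0  # dead frame
        traj = track_trajectory(frames, (48, 48), fitted_cal)
        assert not traj.ok[4]
        assert np.isnan(traj.z[4])
        assert traj.reliable  # 1/10 failures below the 20% threshold

    def test_trajectory_csv_roundtrip(self, fitted_cal, tmp_path):
        t = 0.1 * np.arange(10)
        frames, _ = gen_defocus_series((t, np.full(10, 1.5)), RING, seed=16)
        traj = track_trajectory(frames, (48, 48), fitted_cal)
        p = traj.write_csv(tmp_path / "traj.csv")
        from porocell.imaging.trajectory import BeadTrajectory

        back = BeadTrajectory.read_csv(p)
        assert np.array_equal(back.t, traj.t)
        assert np.allclose(back.z, traj.z, equal_nan=True)


class TestVolume:
    def test_noiseless_ellipsoid_within_2pc_of_closed_form(self):
        spec = ConfocalSpec(shape="ellipsoid", semi_axes=(10, 8, 4), noise=0.0,
                            n_slices=60)
        stack, truth = gen_confocal_stack(spec, seed=0)
        v = volume_from_stack(stack, (0.2, 0.2, 0.2))
        assert truth["volume_um3"] == pytest.approx(4 / 3 * np.pi * 320, rel=1e-12)
        assert v == pytest.approx(truth["volume_um3"], rel=0.02)

    def test_empty_stack_returns_zero_with_warning(self):
        rng = np.random.default_rng(5)
        stack = rng.normal(10, 2, size=(10, 30, 30))
        with pytest.warns(UserWarning):
            assert volume_from_stack(stack, 0.2) == 0.0

    @pytest.mark.parametrize("ratio", [0.88, 0.78])
    def test_volume_ratio_recovery(self, ratio):
        s_ref, _ = gen_confocal_stack(ConfocalSpec(), seed=6)
        s_mod, _ = gen_confocal_stack(ConfocalSpec(volume_ratio=ratio), seed=7)
        v_ref = volume_from_stack(s_ref, (0.2, 0.2, 0.2))
        v_mod = volume_from_stack(s_mod, (0.2, 0.2, 0.2))
        assert v_mod / v_ref == pytest.approx(ratio, abs=0.02)

    def test_monotone_under_foreground_superset(self):
        spec_small = ConfocalSpec(semi_axes=(8, 6, 3), noise=0.0)
        spec_big = ConfocalSpec(semi_axes=(10, 8, 4), noise=0.0)
        v_small = volume_from_stack(gen_confocal_stack(spec_small, 0)[0], 0.2)
        v_big = volume_from_stack(gen_confocal_stack(spec_big, 0)[0], 0.2)
        assert v_big > v_small

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            volume_from_stack(np.ones((4, 4)), 0.2)
        with pytest.raises(ValueError):
            volume_from_stack(np.ones((4, 4, 4)), (0.2, -0.1, 0.2))
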