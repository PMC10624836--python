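"""Geometry arithmetic, generators and the far-field forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.metrics import structural_similarity

import ptychostream as ps
from ptychostream.simkit import (exit_wave, positions_to_pixels,
                                 probe_intensity_fwhm, step_for_overlap)

PX = 16.0


class TestOverlapRatio:
    @pytest.mark.parametrize("step,beam,expected", [
        (50, 800, 0.9),            # dense training scan
        (180, 800, 0.6),           # sparse scan
        (0, 800, 1.0),             # zero step
        (800 / np.sqrt(3), 800, 0.0),  # adjacent discs just touch
    ])
    def test_known_values(self, step, beam, expected):
        assert ps.overlap_ratio(step, beam) == pytest.approx(expected, abs=0.05)

    def test_round_to_one_decimal(self):
        assert round(ps.overlap_ratio(50, 800), 1) == 0.9
        assert round(ps.overlap_ratio(180, 800), 1) == 0.6

    def test_invalid_beamsize(self):
        with pytest.raises(ValueError):
            ps.overlap_ratio(50, 0)

    @given(s1=st.floats(0, 500), s2=st.floats(0, 500))
    def test_strictly_decreasing_in_step(self, s1, s2):
        if s2 - s1 > 1e-6:
            assert ps.overlap_ratio(s1, 800) > ps.overlap_ratio(s2, 800)

    def test_unclamped_below_zero(self):
        assert ps.overlap_ratio(800, 800) < 0

    def test_step_for_overlap_inverts(self):
        s = step_for_overlap(0.73, 650)
        assert ps.overlap_ratio(s, 650) == pytest.approx(0.73)


class TestPixelSize:
    def test_beamline_value(self):
        g = ps.DetectorGeometry(10.0, 1.55, 512, 55.0)
        assert ps.pixel_size_from_geometry(g) == pytest.approx(6.82, abs=0.01)

    def test_linearity_in_distance(self):
        g1 = ps.DetectorGeometry(10.0, 1.55, 512, 55.0)
        g2 = ps.DetectorGeometry(10.0, 3.10, 512, 55.0)
        assert ps.pixel_size_from_geometry(g2) == pytest.approx(
            2 * ps.pixel_size_from_geometry(g1))

    def test_second_detector(self):
        g = ps.DetectorGeometry(10.0, 0.9, 128, 75.0)
        # direct formula evaluation: 0.123984 nm * 0.9 m / (128 * 75 um)
        assert ps.pixel_size_from_geometry(g) == pytest.approx(11.62, abs=0.01)

    def test_inverse_in_n_and_pitch(self):
        g1 = ps.DetectorGeometry(10.0, 1.0, 256, 50.0)
        g2 = ps.DetectorGeometry(10.0, 1.0, 512, 50.0)
        g3 = ps.DetectorGeometry(10.0, 1.0, 256, 100.0)
        p1 = ps.pixel_size_from_geometry(g1)
        assert ps.pixel_size_from_geometry(g2) == pytest.approx(p1 / 2)
        assert ps.pixel_size_from_geometry(g3) == pytest.approx(p1 / 2)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            ps.DetectorGeometry(-10.0, 1.55, 512, 55.0)


class TestDataVolume:
    def test_survey_scan_volume(self):
        # 1 mm^2 raster at 100 nm step, 1 Mpixel 16-bit frames
        assert ps.data_volume(1.0, 100.0, 1e6, 16) == pytest.approx(200e12)

    def test_single_frame(self):
        # area holding exactly one 100-nm-step position: one 1 Mpixel
        # 16-bit frame is 2 MB
        area_mm2 = 100.0 ** 2 / 1e12
        assert ps.data_volume(area_mm2, 100.0, 1e6, 16) == pytest.approx(2e6)

    def test_spiral_scan_volume(self):
        # 963 frames of 128x128 at 16 bit
        area_mm2 = 963 * 50.0 ** 2 / 1e12
        assert ps.data_volume(area_mm2, 50.0, 128 * 128, 16) == pytest.approx(
            31.56e6, rel=0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ps.data_volume(0.0, 100.0, 1e6, 16)


class TestSpiralScan:
    def test_point_count(self):
        plan = ps.make_spiral_scan(963, 50.0)
        assert plan.n_points == 963

    def test_single_point_at_center(self):
        plan = ps.make_spiral_scan(1, 50.0, center_nm=(10.0, 20.0))
        np.testing.assert_allclose(plan.positions_nm, [[10.0, 20.0]])

    def test_consecutive_spacing_matches_step(self):
        plan = ps.make_spiral_scan(963, 50.0)
        d = np.linalg.norm(np.diff(plan.positions_nm, axis=0), axis=1)
        assert abs(np.median(d) - 50.0) / 50.0 < 0.05

    def test_nearest_neighbor_spacing(self):
        from scipy.spatial import cKDTree
        plan = ps.make_spiral_scan(400, 50.0)
        dist, _ = cKDTree(plan.positions_nm).query(plan.positions_nm, k=2)
        assert abs(np.median(dist[:, 1]) - 50.0) / 50.0 < 0.05

    def test_deterministic(self):
        a = ps.make_spiral_scan(100, 30.0)
        b = ps.make_spiral_scan(100, 30.0)
        np.testing.assert_array_equal(a.positions_nm, b.positions_nm)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            ps.make_spiral_scan(0, 50.0)


class TestProbe:
    def test_annulus_fwhm_at_spot_size(self):
        p = ps.make_probe(object_pixel_nm=10.0, style="annulus", fwhm_nm=800,
                          n_pixels=128)
        w = probe_intensity_fwhm(p.intensity, 10.0)
        assert 760 <= w <= 840

    def test_power_normalized(self, probe32):
        assert probe32.power == pytest.approx(1.0, abs=1e-12)

    def test_donut_central_dip(self):
        p = ps.make_probe(object_pixel_nm=10.0, style="annulus", fwhm_nm=800,
                          n_pixels=128)
        from ptychostream.simkit import _radial_profile
        _, prof = _radial_profile(p.intensity, 10.0)
        assert prof[0] < 0.5 * prof.max()

    def test_gaussian_fwhm(self):
        p = ps.make_probe(object_pixel_nm=10.0, style="gaussian", fwhm_nm=500,
                          n_pixels=128)
        w = probe_intensity_fwhm(p.intensity, 10.0)
        assert w == pytest.approx(500, rel=0.1)

    def test_unreachable_fwhm(self):
        with pytest.raises(ValueError):
            ps.make_probe(object_pixel_nm=10.0, style="annulus", fwhm_nm=5000,
                          n_pixels=64)


class TestPhantom:
    def test_phase_within_declared_range(self, phantom):
        assert phantom.phase.min() >= -0.4 - 1e-9
        assert phantom.phase.max() <= 0.0 + 1e-9

    def test_seed_determinism(self):
        a = ps.make_phantom((64, 64), 10.0, (-0.4, 0.0), "random_etch", seed=5)
        b = ps.make_phantom((64, 64), 10.0, (-0.4, 0.0), "random_etch", seed=5)
        np.testing.assert_array_equal(a.phase, b.phase)

    def test_distinct_seeds_differ(self):
        a = ps.make_phantom((128, 128), 10.0, (-0.4, 0.0), "random_etch", seed=1)
        b = ps.make_phantom((128, 128), 10.0, (-0.4, 0.0), "random_etch", seed=2)
        assert structural_similarity(a.phase, b.phase, data_range=0.4) < 0.9

    def test_letters_style(self):
        p = ps.make_phantom((128, 128), 10.0, (-0.3, 0.0), "letters", seed=3)
        assert p.phase.min() < -0.05  # glyphs actually drawn

    def test_rejects_wrapping_range(self):
        with pytest.raises(ValueError):
            ps.make_phantom((32, 32), 10.0, (-4.0, 0.0), "random_etch", seed=0)


class TestForwardModel:
    def test_vacuum_frames_identical(self, probe32):
        vac = ps.Phantom(np.zeros((128, 128)), np.ones((128, 128)), PX, (0.0, 0.0))
        plan = ps.make_spiral_scan(5, 30.0, 440.0, center_nm=(64 * PX, 64 * PX))
        stack = ps.simulate_scan(vac, probe32, plan, exposure_ms=1.0,
                                 flux_scale=1e6, poisson=False)
        for i in range(1, stack.n_frames):
            np.testing.assert_allclose(stack.frames[i], stack.frames[0],
                                       rtol=1e-10)

    def test_parseval_count_conservation(self, phantom, probe32, dense_scan):
        plan, stack = dense_scan
        centers = positions_to_pixels(plan.positions_nm, phantom.phase.shape,
                                      PX, origin_nm=(0.0, 0.0))
        for i in [0, 17, 59]:
            psi = exit_wave(phantom.transmission, probe32.field, centers[i])
            expected = 1e8 * 1.0 * np.sum(np.abs(psi) ** 2)
            total = stack.frames[i].sum()
            assert abs(total - expected) / expected < 1e-6

    def test_poisson_mean_variance(self, phantom, probe32):
        plan = ps.make_spiral_scan(1, 30.0, 440.0, center_nm=(96 * PX, 96 * PX))
        frames = []
        for rep in range(100):
            s = ps.simulate_scan(phantom, probe32, plan, exposure_ms=1.0,
                                 flux_scale=1e5, poisson=True, seed=rep)
            frames.append(s.frames[0].astype(float))
        cube = np.stack(frames)
        mean = cube.mean(axis=0)
        var = cube.var(axis=0, ddof=1)
        sel = mean > 50  # enough counts for the ratio to stabilize
        ratio = var[sel].mean() / mean[sel].mean()
        assert abs(ratio - 1.0) < 0.2

    def test_poisson_counts_are_integral(self, phantom, probe32):
        plan = ps.make_spiral_scan(2, 30.0, 440.0, center_nm=(96 * PX, 96 * PX))
        s = ps.simulate_scan(phantom, probe32, plan, poisson=True, seed=1)
        assert np.issubdtype(s.frames.dtype, np.integer)

    def test_out_of_bounds_position_named(self, phantom, probe32):
        plan = ps.ScanPlan(np.array([[96 * PX, 96 * PX], [5.0, 5.0]]), 30.0, 440.0)
        with pytest.raises(ValueError, match="position 1"):
            ps.simulate_scan(phantom, probe32, plan, poisson=False)

    def test_seed_reproducibility(self, phantom, probe32):
        plan = ps.make_spiral_scan(3, 30.0, 440.0, center_nm=(96 * PX, 96 * PX))
        a = ps.simulate_scan(phantom, probe32, plan, poisson=True, seed=7)
        b = ps.simulate_scan(phantom, probe32, plan, poisson=True, seed=7)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestDoseMap:
    def test_single_position_is_probe_footprint(self, probe32):
        plan = ps.ScanPlan(np.array([[0.0, 0.0]]), 30.0, 440.0)
        d = ps.dose_map(plan, probe32, flux_scale=1e6, exposure_ms=1.0)
        assert d.grid.max() == pytest.approx(
            probe32.intensity.max() * 1e6 / PX ** 2, rel=1e-6)

    def test_total_dose_conservation(self, probe32):
        plan = ps.make_spiral_scan(40, 50.0, 440.0)
        d = ps.dose_map(plan, probe32, flux_scale=1e6, exposure_ms=2.0)
        assert d.total_photons == pytest.approx(40 * 2e6, rel=1e-9)

    def test_halving_step_quadruples_mean_dose(self, probe32):
        # same area covered with 4x the positions -> ~4x the average dose
        plan_a = ps.make_spiral_scan(100, 50.0, 440.0)
        plan_b = ps.make_spiral_scan(400, 25.0, 440.0)
        da = ps.dose_map(plan_a, probe32, flux_scale=1e6)
        db = ps.dose_map(plan_b, probe32, flux_scale=1e6)
        assert db.mean_dose / da.mean_dose == pytest.approx(4.0, rel=0.1)

    def test_empty_plan_rejected(self, probe32):
        with pytest.raises(ValueError):
            ps.ScanPlan(np.empty((0, 2)), 30.0, 440.0)
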