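import numpy as np
import pytest

from radfilm.calibration import GridGeometry, standard_grid_doses
from radfilm.gamma_analysis import GammaCriteria, compute_gamma
from radfilm.planes import centered_plane
from radfilm.scan_processing import Orientation, align_orientation, average_scans, compute_netod
from radfilm.synthetic_data import (
    FieldSpec,
    STANDARD_FIELD_SIZES_CM,
    default_film_model,
    make_calibration_grid_plane,
    make_open_field_plane,
    make_psqa_pair,
    simulate_film_scan,
)

SMALL_GEOM = GridGeometry(block_size_mm=(20, 20), block_pitch_mm=(32, 32), film_size_mm=(104, 104))


class TestOpenField:
    def test_central_dose_and_symmetry(self):
        plane = make_open_field_plane(FieldSpec(4.98, d_max_gy=5.0, spacing_mm=0.5))
        r, c = plane.shape[0] // 2, plane.shape[1] // 2
        assert plane.dose_gy[r, c] == pytest.approx(5.0, abs=5e-6)
        np.testing.assert_allclose(plane.dose_gy, plane.dose_gy[::-1, :], atol=1e-12)
        np.testing.assert_allclose(plane.dose_gy, plane.dose_gy[:, ::-1], atol=1e-12)

    def test_sharp_edge_limit_is_step(self):
        plane = make_open_field_plane(
            FieldSpec(2.0, d_max_gy=4.0, penumbra_sigma_mm=1e-4, spacing_mm=1.0)
        )
        interior = np.isclose(plane.dose_gy, 4.0, atol=1e-9)
        exterior = np.isclose(plane.dose_gy, 0.0, atol=1e-9)
        assert (interior | exterior).sum() >= plane.dose_gy.size - 4 * plane.dose_gy.shape[0]

    def test_monotone_in_field_size(self):
        small = make_open_field_plane(FieldSpec(2.49, spacing_mm=1.0, extent_mm=(60, 60)))
        large = make_open_field_plane(FieldSpec(4.98, spacing_mm=1.0, extent_mm=(60, 60)))
        assert np.all(large.dose_gy >= small.dose_gy - 1e-12)

    def test_extent_invariant_enforced(self):
        with pytest.raises(ValueError, match="extent"):
            FieldSpec(4.98, extent_mm=(50.0, 50.0))

    def test_determinism(self):
        a = make_open_field_plane(FieldSpec(4.98))
        b = make_open_field_plane(FieldSpec(4.98))
        np.testing.assert_array_equal(a.dose_gy, b.dose_gy)


class TestCalibrationGridPlane:
    def test_block_means_recover_dose_list(self):
        plane = make_calibration_grid_plane(geometry=SMALL_GEOM, sigma_mm=1.0, spacing_mm=0.5)
        xi = np.arange(plane.shape[1]) * 0.5
        yi = np.arange(plane.shape[0]) * 0.5
        for dose, (cx, cy) in zip(
            standard_grid_doses(), SMALL_GEOM.block_centers_mm((xi[-1], yi[-1]))
        ):
            cols = np.abs(xi - cx) <= 5.0
            rows = np.abs(yi - cy) <= 5.0
            interior = plane.dose_gy[np.ix_(rows, cols)]
            assert interior.mean() == pytest.approx(dose, abs=1e-3)

    def test_zero_doses_zero_plane(self):
        plane = make_calibration_grid_plane([0.0] * 9, SMALL_GEOM, sigma_mm=1.0, spacing_mm=1.0)
        np.testing.assert_array_equal(plane.dose_gy, 0.0)

    def test_no_cross_talk_between_blocks(self):
        doses = [0.0] * 9
        doses[4] = 21.0  # only the central block is hot
        plane = make_calibration_grid_plane(doses, SMALL_GEOM, sigma_mm=1.0, spacing_mm=0.5)
        xi = np.arange(plane.shape[1]) * 0.5
        yi = np.arange(plane.shape[0]) * 0.5
        cx, cy = SMALL_GEOM.block_centers_mm((xi[-1], yi[-1]))[0]  # a cold corner block
        cols = np.abs(xi - cx) <= 5.0
        rows = np.abs(yi - cy) <= 5.0
        assert plane.dose_gy[np.ix_(rows, cols)].max() < 1e-6 * 21.0

    def test_overlapping_blocks_rejected(self):
        tight = GridGeometry(block_size_mm=(30, 30), block_pitch_mm=(32, 32), film_size_mm=(104, 104))
        with pytest.raises(ValueError, match="overlap"):
            make_calibration_grid_plane(geometry=tight, sigma_mm=1.0)


class TestSimulateFilmScan:
    def test_zero_dose_noiseless_scans_equal_unexposed(self, film_model):
        plane = centered_plane(np.zeros((12, 16)), 0.5)
        scans, unexposed = simulate_film_scan(plane, film_model)
        assert len(scans) == 4
        for scan in scans:
            aligned = align_orientation(scan)
            np.testing.assert_array_equal(aligned.pixels, unexposed.pixels)

    def test_orientation_tags_cover_all_four(self, film_model):
        plane = centered_plane(np.zeros((4, 4)), 0.5)
        scans, _ = simulate_film_scan(plane, film_model)
        assert [s.orientation for s in scans] == [
            Orientation.ORIGINAL, Orientation.VFLIP, Orientation.HFLIP, Orientation.ROT180
        ]

    def test_seed_reproducibility(self):
        plane = make_open_field_plane(FieldSpec(2.49, d_max_gy=5.0, spacing_mm=1.0))
        m1 = default_film_model(seed=7, noise_sigma_fraction=0.01)
        m2 = default_film_model(seed=7, noise_sigma_fraction=0.01)
        m3 = default_film_model(seed=8, noise_sigma_fraction=0.01)
        s1, _ = simulate_film_scan(plane, m1)
        s2, _ = simulate_film_scan(plane, m2)
        s3, _ = simulate_film_scan(plane, m3)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
        assert any((a.pixels != c.pixels).any() for a, c in zip(s1, s3))

    def test_dose_above_invertible_range_rejected(self, film_model):
        plane = centered_plane(np.full((4, 4), 100.0), 0.5)
        with pytest.raises(ValueError, match="maximum representable"):
            simulate_film_scan(plane, film_model)

    def test_higher_dose_darker_film(self, film_model):
        plane = centered_plane(np.linspace(0, 20, 16).reshape(1, 16).repeat(2, axis=0), 1.0)
        scans, _ = simulate_film_scan(plane, film_model)
        pv = scans[0].pixels[0, :, 0].astype(float)
        assert np.all(np.diff(pv) < 0)

    def test_lateral_artifact_raises_edge_od(self):
        plane = centered_plane(np.full((5, 41), 10.0), 1.0)
        clean, _ = simulate_film_scan(plane, default_film_model())
        biased, _ = simulate_film_scan(plane, default_film_model(lateral_amplitude=0.05))
        mid, edge = 20, 0
        assert biased[0].pixels[2, mid, 0] == clean[0].pixels[2, mid, 0]
        assert biased[0].pixels[2, edge, 0] < clean[0].pixels[2, edge, 0]  # more OD = darker

    def test_round_trip_recovers_dose(self, film_model):
        """Noiseless, artifact-free loop through the scan-processing chain
        recovers the source plane within 0.1% of the maximum dose."""
        from radfilm.calibration import CalibrationPoint, fit_calibration
        from radfilm.dose_engine import apply_calibration

        plane = make_open_field_plane(FieldSpec(2.49, d_max_gy=5.0, spacing_mm=0.5))
        scans, unexposed = simulate_film_scan(plane, film_model)
        avg = average_scans([align_orientation(s) for s in scans])
        netod = compute_netod(avg, average_scans([unexposed]))
        a0, a1, a2, a3 = film_model.coefficients["red"]
        xs = np.linspace(0.01, film_model.netod_max["red"], 9)
        pts = [CalibrationPoint(float(x), float(a0 + a1 * x + a2 * x**2 + a3 * x**3), "red") for x in xs]
        curve = fit_calibration(pts, "red")
        film = apply_calibration(netod, curve, channel="red")
        assert np.max(np.abs(film.dose_gy - plane.dose_gy)) < 0.001 * 5.0


class TestPSQAPair:
    def test_error_free_case_passes_tight_gamma(self):
        case = make_psqa_pair("two_level", {"field_size_cm": 4.98, "d_max_gy": 6.0, "spacing_mm": 1.0})
        np.testing.assert_array_equal(case.plan.dose_gy, case.delivered.dose_gy)
        # compare the delivered distribution directly (film chain tested elsewhere)
        res = compute_gamma(case.plan, case.delivered, GammaCriteria(2, 2))
        assert res.pass_rate_pct == 100.0

    def test_scaling_error_fails_absolute_passes_relative(self):
        case = make_psqa_pair(
            "wedge", {"field_size_cm": 4.98, "d_max_gy": 6.0, "spacing_mm": 1.0, "scale_error": 1.05}
        )
        absolute = compute_gamma(case.plan, case.delivered, GammaCriteria(3, 3))
        relative = compute_gamma(
            case.plan, case.delivered, GammaCriteria(3, 3, normalization="relative", use_robust_max=False)
        )
        assert absolute.pass_rate_pct < 100.0
        assert relative.pass_rate_pct == 100.0

    def test_translation_error_ranks_criteria(self):
        case = make_psqa_pair(
            "offset_hotspot",
            {"field_size_cm": 4.98, "d_max_gy": 6.0, "spacing_mm": 1.0, "shift_mm": (2.0, 0.0)},
        )
        loose = compute_gamma(case.plan, case.delivered, GammaCriteria(3, 3), subgrid_step_mm=0.1)
        tight = compute_gamma(case.plan, case.delivered, GammaCriteria(3, 1), subgrid_step_mm=0.1)
        assert loose.pass_rate_pct > tight.pass_rate_pct

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            make_psqa_pair("spiral")

    def test_unknown_params_rejected(self):
        with pytest.raises(ValueError, match="unknown parameters"):
            make_psqa_pair("wedge", {"bogus": 1})

    def test_field_size_list_has_expected_range(self):
        assert min(STANDARD_FIELD_SIZES_CM) == pytest.approx(0.83)
        assert max(STANDARD_FIELD_SIZES_CM) == pytest.approx(19.92)
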