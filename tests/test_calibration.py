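"""Polynomial calibration, outlier removal, error reports, full pipeline."""

import numpy as np
import pytest

from pftcal import (
    ErrorReport,
    ImplicitCalibrator,
    PolynomialGazeRegressor,
    ReferenceSet,
    TrainingSet,
    evaluate_error,
    explicit_calibration,
    fit_calibration,
    predict_gaze,
    remove_outliers,
    run_implicit_pipeline,
)

from conftest import planted_session


def _quad_forward(E, cx, cy):
    ex, ey = E[:, 0], E[:, 1]
    mono = np.column_stack([ex**2, ey**2, ex * ey, ex, ey, np.ones_like(ex)])
    return np.column_stack([mono @ cx, mono @ cy])


class TestPolynomialGazeRegressor:
    def test_known_quadratic_coefficients_recovered(self, rng):
        cx = np.array([0.01, -0.02, 0.005, 1.2, -0.3, 7.0])
        cy = np.array([-0.015, 0.01, 0.0, 0.4, 0.9, -2.0])
        E = rng.uniform(0, 50, (15, 2))
        g = _quad_forward(E, cx, cy)
        model = fit_calibration(E, g, degree=2)
        d = model.to_dict()
        np.testing.assert_allclose(d["coeffs_x"], cx, atol=1e-6)
        np.testing.assert_allclose(d["coeffs_y"], cy, atol=1e-6)
        np.testing.assert_allclose(model.predict(E), g, atol=1e-6)

    def test_underdetermined_fit_rejected(self, rng):
        E = rng.uniform(0, 50, (5, 2))
        with pytest.raises(ValueError, match="cannot determine"):
            fit_calibration(E, np.zeros((5, 2)), degree=2)

    def test_rank_deficient_design_rejected(self):
        E = np.tile([3.0, 4.0], (10, 1))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_calibration(E, np.zeros((10, 2)), degree=1)

    def test_degree1_identity_predicts_input(self):
        E = np.random.default_rng(0).uniform(0, 100, (8, 2))
        model = fit_calibration(E, E, degree=1)
        np.testing.assert_allclose(predict_gaze(model, E), E, atol=1e-9)
        np.testing.assert_allclose(
            predict_gaze(model, np.array([12.0, 34.0])), [12.0, 34.0], atol=1e-9
        )

    def test_single_quadratic_monomial(self):
        # g_x = e_x^2 only: e = (3, 5) -> g_x = 9
        model = PolynomialGazeRegressor.from_dict(
            {
                "degree": 2,
                "n": 2,
                "powers": [[2, 0], [0, 2], [1, 1], [1, 0], [0, 1], [0, 0]],
                "coeffs_x": [1, 0, 0, 0, 0, 0],
                "coeffs_y": [0, 0, 0, 0, 0, 0],
            }
        )
        np.testing.assert_allclose(
            predict_gaze(model, np.array([3.0, 5.0])), [9.0, 0.0]
        )

    def test_constant_model_ignores_features(self):
        model = PolynomialGazeRegressor.from_dict(
            {
                "degree": 2,
                "n": 2,
                "powers": [[2, 0], [0, 2], [1, 1], [1, 0], [0, 1], [0, 0]],
                "coeffs_x": [0, 0, 0, 0, 0, 42.0],
                "coeffs_y": [0, 0, 0, 0, 0, 17.0],
            }
        )
        rng = np.random.default_rng(4)
        out = model.predict(rng.uniform(0, 500, (6, 2)))
        np.testing.assert_allclose(out, np.tile([42.0, 17.0], (6, 1)))

    def test_coefficient_rmse_shrinks_with_more_pairs(self, rng):
        cx = np.array([0.002, -0.001, 0.0, 1.1, -0.2, 5.0])
        cy = np.array([-0.001, 0.002, 0.001, 0.3, 0.8, -1.0])
        rmses = []
        for n_pairs in (20, 200):
            errs = []
            for rep in range(10):
                E = rng.uniform(0, 60, (n_pairs, 2))
                g = _quad_forward(E, cx, cy) + rng.normal(0, 1.0, (n_pairs, 2))
                d = fit_calibration(E, g, 2).to_dict()
                errs.append(
                    np.sqrt(
                        np.mean(
                            (np.array(d["coeffs_x"]) - cx) ** 2
                            + (np.array(d["coeffs_y"]) - cy) ** 2
                        )
                    )
                )
            rmses.append(np.mean(errs))
        assert rmses[1] < rmses[0]

    def test_interpolation_residuals_vanish(self, rng):
        # pairs on an exact degree-2 law: residuals <= 1e-8
        cx = np.array([0.01, 0.0, -0.005, 0.9, 0.1, 3.0])
        cy = np.array([0.0, 0.008, 0.002, -0.2, 1.1, 1.0])
        E = rng.uniform(0, 40, (12, 2))
        model = fit_calibration(E, _quad_forward(E, cx, cy), 2)
        assert np.abs(model.residuals_).max() <= 1e-8


class TestRemoveOutliers:
    def test_zero_removal_is_identity(self, rng):
        X = rng.uniform(0, 100, (10, 2))
        y = rng.uniform(0, 100, (10, 2))
        Xf, yf, keep = remove_outliers(X, y, 0.0)
        assert keep.all()
        np.testing.assert_array_equal(Xf, X)

    def test_exact_count_removed(self, rng):
        X = rng.uniform(0, 100, (10, 2))
        y = rng.uniform(0, 100, (10, 2))
        _, yf, keep = remove_outliers(X, y, 0.20)
        assert keep.sum() == 8

    def test_displaced_pairs_are_the_ones_removed(self, rng):
        # 16 exactly linear pairs + 4 far-displaced: the 4 go
        A = np.array([[2.0, 0.3], [-0.1, 1.5]])
        X = rng.uniform(0, 100, (20, 2))
        y = X @ A.T + 7.0
        bad = [3, 8, 13, 19]
        y[bad] += 40.0
        _, _, keep = remove_outliers(X, y, 0.20)
        assert sorted(np.where(~keep)[0]) == bad

    def test_removal_leaving_too_few_rejected(self, rng):
        X = rng.uniform(0, 100, (5, 2))
        with pytest.raises(ValueError, match="fewer than"):
            remove_outliers(X, X, 0.4)

    def test_output_is_subset(self, rng):
        X = rng.uniform(0, 100, (15, 2))
        y = rng.uniform(0, 100, (15, 2))
        Xf, yf, keep = remove_outliers(X, y, 0.3)
        np.testing.assert_array_equal(Xf, X[keep])
        assert keep.sum() == 15 - int(0.3 * 15)


class TestErrorReport:
    def test_pixel_scene_arithmetic(self):
        """rp=(320,240), g=(256,192) on a 640x480 scene -> exactly 10%/10%."""
        model = PolynomialGazeRegressor.from_dict(
            {
                "degree": 1,
                "n": 2,
                "powers": [[0, 0], [1, 0], [0, 1]],
                "coeffs_x": [256.0, 0, 0],
                "coeffs_y": [192.0, 0, 0],
            }
        )
        refs = ReferenceSet(np.zeros((1, 2)), np.array([[320.0, 240.0]]))
        rep = evaluate_error(model, refs, scene_w=640, scene_h=480)
        assert rep.error_x == pytest.approx(10.0)
        assert rep.error_y == pytest.approx(10.0)
        assert rep.avg_error == pytest.approx(10.0)

    def test_perfect_predictions_zero_error(self, rng):
        E = rng.uniform(0, 100, (9, 2))
        model = fit_calibration(E, E, degree=1)
        rep = evaluate_error(model, ReferenceSet(E, E))
        assert rep.avg_error == pytest.approx(0.0, abs=1e-9)

    def test_average_over_refpoints(self):
        model = PolynomialGazeRegressor.from_dict(
            {
                "degree": 1,
                "n": 2,
                "powers": [[0, 0], [1, 0], [0, 1]],
                "coeffs_x": [0.0, 1.0, 0.0],
                "coeffs_y": [0.0, 0.0, 1.0],
            }
        )
        # per-axis errors 10% and 20% -> mean 15%
        refs = ReferenceSet(
            np.array([[50.0, 50.0], [50.0, 50.0]]),
            np.array([[60.0, 60.0], [70.0, 70.0]]),
        )
        rep = evaluate_error(model, refs)
        assert rep.error_x == pytest.approx(15.0)
        assert rep.avg_error == pytest.approx(15.0)

    def test_translation_covariance_bound(self, rng):
        E = rng.uniform(0, 100, (9, 2))
        refs = ReferenceSet(E, E)
        base = evaluate_error(fit_calibration(E, E, 1), refs)
        shifted = fit_calibration(E, E + np.array([5.0, 0.0]), 1)
        rep = evaluate_error(shifted, refs)
        assert abs(rep.error_x - base.error_x) <= 5.0 + 1e-9


class TestExplicitCalibration:
    def test_noise_free_quadratic_recovery(self, rng):
        cx = np.array([0.01, -0.01, 0.0, 1.0, 0.2, 4.0])
        cy = np.array([0.0, 0.02, -0.01, 0.1, 0.8, 2.0])
        E = rng.uniform(0, 50, (18, 2))
        cal = ReferenceSet(E, _quad_forward(E, cx, cy), role="calibration")
        model = explicit_calibration(cal)
        d = model.to_dict()
        np.testing.assert_allclose(d["coeffs_x"], cx, atol=1e-7)

    def test_nine_point_grid_fixture(self):
        from pftcal import reference_grid

        grid = reference_grid()
        assert grid.shape == (9, 2)
        np.testing.assert_allclose(
            sorted(set(grid[:, 0])), [100 / 6, 50.0, 500 / 6]
        )

    def test_explicit_beats_center_on_noisy_sessions(self):
        wins = 0
        for seed in range(5):
            s = planted_session(seed, M_scenes=3, fix_per_scene=8,
                                attention=0.9, jitter=1.0, sensor=1.0)
            calib = evaluate_error(explicit_calibration(s.cal), s.ref)
            center = TrainingSet(
                s.training_set.features,
                [np.array([[50.0, 50.0]])] * s.training_set.M,
            )
            _, _, crep = run_implicit_pipeline(
                center, "dir", "exhaustive", 0.2, 2, refs=s.ref
            )
            wins += calib.avg_error < crep.avg_error
        assert wins == 5


class TestImplicitPipeline:
    def test_noise_free_session_recovers_ground_truth(self):
        s = planted_session(31, M_scenes=4, fix_per_scene=5)
        model, scored, rep = run_implicit_pipeline(
            s.training_set, "dir", "genetic", 0.2, 2, refs=s.ref, seed=0
        )
        assert np.array_equal(scored.mapping.indices, s.planted)
        # the fitted model must reproduce the hidden transform on the grid
        assert rep.avg_error <= 1e-4

    def test_center_baseline_collapses_to_scene_center(self):
        s = planted_session(5, M_scenes=3, fix_per_scene=5)
        ts = s.training_set
        center = TrainingSet(ts.features, [np.array([[50.0, 50.0]])] * ts.M)
        model, _, rep = run_implicit_pipeline(
            center, "dir", "exhaustive", 0.2, 2, refs=s.ref
        )
        preds = model.predict(s.ref.features)
        np.testing.assert_allclose(preds, np.tile([50.0, 50.0], (len(preds), 1)),
                                   atol=1e-6)
        assert rep.avg_error > 10.0  # large vs a dispersed reference grid

    @pytest.mark.parametrize("removal", [0.0, 0.1, 0.2, 0.3, 0.4])
    def test_removal_percent_sweep_runs(self, removal):
        s = planted_session(13, M_scenes=4, fix_per_scene=5,
                            attention=0.9, jitter=0.5, sensor=0.5)
        _, _, rep = run_implicit_pipeline(
            s.training_set, "dir", "genetic", removal, 2, refs=s.ref, seed=1
        )
        assert isinstance(rep, ErrorReport)
        assert np.isfinite(rep.avg_error)

    def test_estimator_api_roundtrip(self):
        s = planted_session(17, M_scenes=4, fix_per_scene=5)
        ts = s.training_set
        est = ImplicitCalibrator(mcf="dir", search="incremental",
                                 removal_percent=0.0)
        est.fit(ts.features, ts.target_sets)
        assert est.mapping_.shape == (ts.M,)
        assert est.inlier_mask_.all()
        assert est.predict(ts.features).shape == (ts.M, 2)
        params = est.get_params()
        assert params["mcf"] == "dir" and params["search"] == "incremental"
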