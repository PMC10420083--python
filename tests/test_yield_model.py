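"""Plot aggregation, OLS fits, LOOCV scoring, model ranking."""

import numpy as np
import pytest

from rapeyield.images import AbundanceImage, ReflectanceImage
from rapeyield.synth import TrialDesign, generate_trial, render_scene
from rapeyield.unmixing import unmix_image
from rapeyield.yield_model import (
    DegeneratePredictorError,
    PlotRecord,
    SampleSizeError,
    fit_linear,
    loocv_evaluate,
    plot_aggregate,
    rank_models,
    read_plots_csv,
    write_plots_csv,
)


class TestFitLinear:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_covariance_gives_zero_slope_and_r2(self):
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, 0.0, 1.0])  # orthogonal to x
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols_oracle(self, rng):
        x = rng.uniform(0, 1, 10)
        y = rng.uniform(0, 1, 10)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert fit.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fit_linear(np.ones(5), np.arange(5.0))


class TestLoocv:
    def test_exactly_linear_data_scores_perfectly(self):
        x = np.linspace(0, 1, 8)
        rep = loocv_evaluate(x, 3 * x + 2)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.cv == pytest.approx(0.0, abs=1e-9)

    def test_three_point_folds_match_hand_enumeration(self):
        # (0,0), (1,1), (2,4): each fold fits the remaining two points exactly
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 4.0])
        # manual enumeration oracle
        expected_resid = []
        for i in range(3):
            keep = [j for j in range(3) if j != i]
            slope = (y[keep[1]] - y[keep[0]]) / (x[keep[1]] - x[keep[0]])
            intercept = y[keep[0]] - slope * x[keep[0]]
            expected_resid.append(y[i] - (slope * x[i] + intercept))
        rep = loocv_evaluate(x, y)
        np.testing.assert_allclose(rep.fold_residuals, expected_resid, atol=1e-10)
        assert rep.rmse == pytest.approx(np.sqrt(np.mean(np.array(expected_resid) ** 2)), abs=1e-10)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)  # two points always fit exactly
        assert rep.cv == pytest.approx(100 * rep.rmse / y.mean(), abs=1e-10)

    def test_mean_fold_cv_variant_differs(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.1, 1.2, 3.8, 9.0])
        default = loocv_evaluate(x, y)
        variant = loocv_evaluate(x, y, cv_variant="mean_fold")
        assert default.cv != pytest.approx(variant.cv, abs=1e-9)

    def test_rmse_tracks_generator_noise_sd(self):
        # true-driver model: LOOCV RMSE estimates the yield noise sd
        rmses = []
        for seed in range(10):
            b = generate_trial(TrialDesign(seed=seed))
            rep = loocv_evaluate(
                b.table["driver_true"].to_numpy(), b.table["yield_kg_ha"].to_numpy()
            )
            rmses.append(rep.rmse)
        assert np.mean(rmses) == pytest.approx(150.0, rel=0.25)

    def test_too_few_points_rejected(self):
        with pytest.raises(SampleSizeError):
            loocv_evaluate(np.arange(2.0), np.arange(2.0))


@pytest.fixture(scope="module")
def scene_and_abund():
    bundle = generate_trial(TrialDesign(seed=8))
    scene, truth = render_scene(bundle, snr_db=None, seed=8)
    abund = unmix_image(scene, bundle.endmember_matrix)
    return bundle, scene, abund


class TestPlotAggregate:

    def test_constant_layer_mean_is_that_constant(self, sensor):
        img = ReflectanceImage(np.full((6, 6, 6), 0.25), sensor)
        ab = AbundanceImage(np.full((3, 6, 6), 1 / 3), residual=np.zeros((6, 6)))
        plots = [PlotRecord("p1", (1, 5, 1, 5), 90.0, 2000.0)]
        table = plot_aggregate(img, ab, plots)
        assert table.loc[0, "rho_b0"] == pytest.approx(0.25, abs=1e-12)
        assert table.loc[0, "abd_FL"] == pytest.approx(1 / 3, abs=1e-9)

    def test_four_pixel_mean(self, sensor):
        vals = np.full((6, 2, 2), 0.0)
        vals[0] = np.array([[1.0, 2], [3, 4]]) / 10
        img = ReflectanceImage(vals, sensor)
        ab = AbundanceImage(np.full((3, 2, 2), 1 / 3), residual=np.zeros((2, 2)))
        table = plot_aggregate(img, ab, [PlotRecord("p", (0, 2, 0, 2), 0.0, 1.0)])
        assert table.loc[0, "rho_b0"] == pytest.approx(0.25, abs=1e-12)

    def test_plot_means_match_design_truth_on_noise_free_scene(self, scene_and_abund):
        bundle, scene, abund = scene_and_abund
        table = plot_aggregate(scene, abund, bundle.plots)
        # Dirichlet jitter with concentration 300 leaves ROI means within a few sd
        merged = table.merge(bundle.table, on="plot_id", suffixes=("", "_truth"))
        assert np.max(np.abs(merged["abd_LF"] - merged["abd_LF_truth"])) <= 0.02

    def test_mean_reflectance_vi_differs_from_mean_pixel_vi_on_heterogeneous_plots(
        self, scene_and_abund
    ):
        bundle, scene, abund = scene_and_abund
        a = plot_aggregate(scene, abund, bundle.plots, vi_convention="mean_reflectance")
        b = plot_aggregate(scene, abund, bundle.plots, vi_convention="mean_pixel")
        assert not np.allclose(a["NDVI"], b["NDVI"], atol=1e-12)

    def test_empty_roi_excluded_with_warning(self, scene_and_abund):
        bundle, scene, abund = scene_and_abund
        scene_masked = ReflectanceImage(
            scene.values, scene.sensor, mask=np.zeros(scene.shape, dtype=bool)
        )
        with pytest.warns(UserWarning, match="excluded"):
            table = plot_aggregate(scene_masked, abund, bundle.plots[:1])
        assert table.empty

    def test_roi_outside_image_rejected(self, scene_and_abund):
        bundle, scene, abund = scene_and_abund
        bad = [PlotRecord("bad", (0, 10_000, 0, 4), 0.0, 1.0)]
        with pytest.raises(ValueError, match="outside"):
            plot_aggregate(scene, abund, bad)


@pytest.fixture(scope="module")
def table():
    bundle = generate_trial(TrialDesign(seed=21))
    scene, _ = render_scene(bundle, snr_db=40.0, seed=22)
    abund = unmix_image(scene, bundle.endmember_matrix)
    return plot_aggregate(scene, abund, bundle.plots)


class TestRankModels:

    def test_true_driver_family_outranks_plain_evi(self, table):
        reports = {r.label: r for r in rank_models(table)}
        assert reports["EVI x Abd_LF"].r2 > reports["EVI"].r2

    def test_all_27_models_reported_and_sorted(self, table):
        reports = rank_models(table)
        assert len(reports) == 27
        r2s = [r.r2 for r in reports]
        assert r2s == sorted(r2s, reverse=True)

    def test_constant_yield_does_not_crash(self, table):
        t = table.copy()
        t["yield_kg_ha"] = 2000.0
        reports = rank_models(t)
        assert len(reports) == 27
        assert all(r.r2 <= 1e-6 or np.isnan(r.rmse) for r in reports)

    def test_plot_order_permutation_leaves_reports_unchanged(self, table):
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = rank_models(table)
        b = rank_models(shuffled)
        for ra, rb in zip(a, b):
            assert ra.label == rb.label
            assert ra.r2 == pytest.approx(rb.r2, abs=1e-12)
            assert ra.rmse == pytest.approx(rb.rmse, abs=1e-9)


def test_plots_csv_round_trip(tmp_path, bundle):
    path = tmp_path / "plots.csv"
    write_plots_csv(bundle.plots, path)
    back = read_plots_csv(path)
    assert [p.plot_id for p in back] == [p.plot_id for p in bundle.plots]
    assert [p.roi for p in back] == [p.roi for p in bundle.plots]
    np.testing.assert_allclose(
        [p.yield_kg_ha for p in back],
        [p.yield_kg_ha for p in bundle.plots],
        rtol=1e-12,  # CSV text round trip
    )
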