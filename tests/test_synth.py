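"""Synthetic trial generator: spectra constraints, simplex truth, DN encoding."""

import numpy as np
import pytest

from rapeyield.spectra import resample_to_bands, uav6
from rapeyield.synth import (
    ParameterError,
    TrialDesign,
    encode_dn,
    generate_endmember_library,
    generate_trial,
    render_scene,
)
from rapeyield.unmixing import unmix_image
from rapeyield.yield_model import fit_linear


class TestEndmemberLibrary:
    @pytest.mark.parametrize("seed", [1, 2, 17])
    def test_spectral_ordering_constraints_hold_at_band_centers(self, seed):
        lib = generate_endmember_library(seed)
        fl, lf, sl = lib
        at = lambda s, w: np.interp(w, s.wavelength_nm, s.reflectance)
        assert at(fl, 550) > at(lf, 550)
        assert at(fl, 670) > at(lf, 670)
        assert at(fl, 800) < at(lf, 800)
        assert np.all(np.diff(sl.reflectance) >= 0)
        # leaf green peak / red dip
        assert at(lf, 550) > at(lf, 490) and at(lf, 550) > at(lf, 610)
        assert at(lf, 670) < at(lf, 610) and at(lf, 670) < at(lf, 720)

    def test_different_seeds_give_different_curves(self):
        a = generate_endmember_library(1)
        b = generate_endmember_library(2)
        assert not np.allclose(a[0].reflectance, b[0].reflectance)

    def test_reflectance_in_unit_interval(self):
        for seed in range(5):
            for s in generate_endmember_library(seed):
                assert np.all(s.reflectance >= 0) and np.all(s.reflectance <= 1)


class TestGenerateTrial:
    def test_leaf_abundance_peaks_at_n225_and_saturates(self):
        b = generate_trial(TrialDesign(seed=3, leaf_plot_sd=0.0, flower_plot_sd=0.0))
        means = b.table.groupby("nitrogen_rate")["abd_LF"].mean()
        assert means[225.0] >= means[:225.0].max()
        assert means[225.0] == pytest.approx(0.7, abs=0.01)
        assert means[0.0] == pytest.approx(0.2, abs=0.01)

    def test_abundances_sum_to_one(self, bundle):
        total = bundle.table[["abd_FL", "abd_LF", "abd_SL"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_yields_positive_and_span_configured_range(self, bundle):
        t = bundle.table
        assert (t["yield_kg_ha"] > 0).all()
        assert t["yield_true"].min() == pytest.approx(1000.0, abs=1e-6)
        assert t["yield_true"].max() == pytest.approx(3500.0, abs=1e-6)

    def test_noisy_yield_unbiased_over_many_seeds(self):
        # Monte-Carlo: the grand-mean noisy-minus-true deviation is within
        # 2 standard errors of zero
        devs = []
        for seed in range(40):
            b = generate_trial(TrialDesign(seed=seed))
            devs.append((b.table["yield_kg_ha"] - b.table["yield_true"]).mean())
        n_total = 40 * 24
        assert abs(np.mean(devs)) <= 2 * 150.0 / np.sqrt(n_total)

    def test_true_yield_regression_recovers_beta_exactly_without_noise(self):
        b = generate_trial(TrialDesign(seed=5, yield_noise_sd=0.0))
        fit = fit_linear(b.table["driver_true"], b.table["yield_kg_ha"])
        assert fit.slope == pytest.approx(b.beta1, rel=1e-9)
        assert fit.intercept == pytest.approx(b.beta0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_trend_design_raises_parameter_error(self):
        # abundance trends that push flower + leaf past the simplex
        hot = TrialDesign(seed=1, leaf_trend=lambda n: 0.9, flower_trend=lambda n: 0.3)
        with pytest.raises(ParameterError, match="simplex"):
            generate_trial(hot)
        with pytest.raises(ParameterError):
            TrialDesign(replicates=0)


class TestRenderScene:
    def test_noise_free_jitter_free_scene_is_exact_forward_model(self, bundle):
        scene, truth = render_scene(bundle, snr_db=None, jitter=False, seed=1)
        E = bundle.endmember_matrix.values
        recon = np.einsum("bk,khw->bhw", E, truth.values)
        np.testing.assert_allclose(scene.values, recon, atol=1e-12)

    def test_pure_pixel_reflectance_equals_endmember_column(self, bundle, sensor):
        # a synthetic one-plot bundle with pure flower abundance
        import copy

        b = copy.deepcopy(bundle)
        b.table.loc[:, ["abd_FL", "abd_LF", "abd_SL"]] = [1.0, 0.0, 0.0]
        scene, truth = render_scene(b, snr_db=None, jitter=False, seed=1)
        np.testing.assert_allclose(
            scene.values[:, 0, 0], b.endmember_matrix.values[:, 0], atol=1e-12
        )

    def test_truth_abundances_on_simplex(self, bundle):
        _, truth = render_scene(bundle, snr_db=40.0, seed=2)
        total = truth.values.sum(axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        assert truth.values.min() >= 0

    def test_40db_noise_sd_matches_nominal_within_10pct(self):
        design = TrialDesign(seed=4, plot_shape=(24, 24))  # >= 10^4 pixels
        b = generate_trial(design)
        clean, truth = render_scene(b, snr_db=None, jitter=True, seed=9)
        noisy, _ = render_scene(b, snr_db=40.0, jitter=True, seed=9)
        resid = noisy.values - clean.values
        nominal = np.sqrt(np.mean(clean.values**2, axis=(1, 2))) / 100.0
        got = resid.std(axis=(1, 2))
        assert np.all(np.abs(got - nominal) / nominal <= 0.10)

    def test_nonpositive_snr_rejected(self, bundle):
        with pytest.raises(ParameterError):
            render_scene(bundle, snr_db=0.0)

    def test_pipeline_identity_noise_free_unmixing(self, bundle, endmember_matrix):
        scene, truth = render_scene(bundle, snr_db=None, seed=11)
        out = unmix_image(scene, endmember_matrix)
        assert np.nanmax(np.abs(out.values - truth.values)) <= 1e-6


class TestEncodeDn:
    def test_gain_scaling_example(self, bundle):
        scene, _ = render_scene(bundle, snr_db=None, seed=1)
        scene.values[:, 0, 0] = 0.48
        dn = encode_dn(scene, gains=0.006, biases=0.0)
        assert dn.values[0, 0, 0] == 80

    def test_reflectance_below_bias_clamps_to_zero(self, bundle):
        scene, _ = render_scene(bundle, snr_db=None, seed=1)
        scene.values[:] = 0.0
        dn = encode_dn(scene, gains=0.006, biases=0.05)
        rows = dn.meta["scene_rows"]
        assert np.all(dn.values[:, :rows] == 0)  # (0 - 0.05)/0.006 clamps to 0
        assert dn.values.max() == round((0.48 - 0.05) / 0.006)  # brightest panel

    def test_panels_encode_their_reflectances(self, bundle):
        scene, _ = render_scene(bundle, snr_db=None, seed=1)
        dn = encode_dn(scene)
        for panel, expect in zip(dn.panels, (10, 40, 80)):
            block = dn.values[(slice(None),) + panel.slices]
            assert np.all(block == expect)

    def test_roundtrip_within_half_quantization_step(self, bundle):
        scene, _ = render_scene(bundle, snr_db=40.0, seed=6)
        dn = encode_dn(scene)
        rows = dn.meta["scene_rows"]
        decoded = 0.006 * dn.values[:, :rows].astype(float)
        assert np.max(np.abs(decoded - scene.values)) <= 0.006 / 2 + 1e-12

    def test_zero_gain_rejected(self, bundle):
        scene, _ = render_scene(bundle, snr_db=None, seed=1)
        with pytest.raises(ParameterError):
            encode_dn(scene, gains=0.0)
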