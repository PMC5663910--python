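"""Generators: determinism, forward-model consistency, distributional checks."""

import numpy as np
import pandas as pd
import pytest

from synquant import synthetic as syn


class TestGenerateFov:
    def test_no_axons_gives_background_only(self):
        fov = syn.generate_fov(syn.SimParams(n_axons=0), (64, 64), seed=0,
                               bg_level=5.0, noise_sd=1.0)
        assert len(fov.bouton_centers) == 0
        assert abs(fov.gz_image.mean() - 5.0) < 0.2

    def test_noiseless_peak_equals_amplitude_plus_background(self):
        # forward model: peak height = amplitude, on top of the background
        p = syn.SimParams(n_axons=1, boutons_per_axon=1,
                          gz_amplitude_dist=("constant", {"value": 50.0}),
                          uptake_dist=("constant", {"value": 0.4}))
        fov = syn.generate_fov(p, (64, 64), seed=1, bg_level=10.0,
                               noise_sd=0.0, integer_centers=True)
        r, c = fov.bouton_centers[0].astype(int)
        assert fov.gz_image[r, c] == pytest.approx(60.0, abs=1e-9)
        assert fov.sb_image[r, c] == pytest.approx(10.0 + 50.0 * 0.4, abs=1e-9)

    def test_determinism(self):
        p = syn.SimParams(n_axons=5, boutons_per_axon=10)
        a = syn.generate_fov(p, (128, 128), seed=1, noise_sd=3.0)
        b = syn.generate_fov(p, (128, 128), seed=1, noise_sd=3.0)
        np.testing.assert_array_equal(a.gz_image, b.gz_image)
        np.testing.assert_array_equal(a.sb_image, b.sb_image)
        np.testing.assert_array_equal(a.bouton_centers, b.bouton_centers)

    def test_invariants(self, noisy_fov):
        fov = noisy_fov
        assert fov.gz_image.shape == fov.sb_image.shape
        assert np.all(fov.bouton_centers >= 0)
        assert np.all(fov.bouton_centers[:, 0] < fov.shape[0])
        assert np.all(fov.bouton_centers[:, 1] < fov.shape[1])
        assert np.all(fov.bouton_gz > 0)
        assert np.all(fov.bouton_uptake >= 0)

    def test_small_shape_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_fov(syn.SimParams(), (32, 32), seed=0)

    def test_bad_psf_rejected(self):
        with pytest.raises(ValueError):
            syn.SimParams(psf_sigma=0.0)

    def test_gain_scales_both_channels(self):
        p = syn.SimParams(n_axons=2, boutons_per_axon=4)
        a = syn.generate_fov(p, (64, 64), seed=2, noise_sd=0.0, detector_gain=1.0)
        b = syn.generate_fov(p, (64, 64), seed=2, noise_sd=0.0, detector_gain=2.0)
        np.testing.assert_allclose(b.gz_image, 2 * a.gz_image, rtol=1e-12)
        np.testing.assert_allclose(b.sb_image, 2 * a.sb_image, rtol=1e-12)


class TestGradient:
    def test_zero_slope_constant(self):
        field = syn.generate_sb_gradient((64, 64), 0.0, (0, 0), base=7.0)
        assert np.all(field == 7.0)

    def test_monotone_from_origin(self):
        field = syn.generate_sb_gradient((64, 64), 0.5, (0, 0), base=100.0)
        assert field[0, 0] > field[63, 63]

    def test_radial_symmetry(self):
        field = syn.generate_sb_gradient((65, 65), 0.3, (32, 32), base=50.0)
        assert field[32, 40] == pytest.approx(field[40, 32])
        assert field[32, 40] == pytest.approx(field[24, 32])

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_sb_gradient((64, 64), -1.0, (0, 0))


class TestLocalizationCloud:
    def test_zero_precision_exact_radius(self):
        pts = syn.generate_localization_cloud(40.0, 0.0, 100, seed=0)
        r = np.hypot(pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(r, 20.0, rtol=1e-12)

    def test_mean_radial_distance_matches_rice_integral(self):
        # independent oracle: mean of the Rice distribution (radial distance
        # of a circle point jittered by isotropic Gaussian noise), computed
        # by numerical integration of its density
        R, sigma, n = 20.0, 5.0, 500
        from scipy.special import i0e

        r = np.linspace(0, 80, 40000)
        pdf = (r / sigma ** 2) * np.exp(-((r - R) ** 2) / (2 * sigma ** 2)) \
            * i0e(r * R / sigma ** 2)
        pdf /= np.trapezoid(pdf, r)
        expected = np.trapezoid(r * pdf, r)

        pts = syn.generate_localization_cloud(2 * R, sigma, n, seed=3)
        sample_mean = np.hypot(pts[:, 0], pts[:, 1]).mean()
        # Monte-Carlo error: sd(r)/sqrt(n), sd(r) ~ sigma
        assert sample_mean == pytest.approx(expected, abs=4 * sigma / np.sqrt(n))

    def test_determinism(self):
        a = syn.generate_localization_cloud(40, 5, 50, seed=9)
        b = syn.generate_localization_cloud(40, 5, 50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_localization_cloud(40, 5, 2)


class TestBindingData:
    def test_half_saturation_identity(self):
        df = syn.generate_binding_data(5.0, 1.0, [5.0], noise_sd=0.0)
        assert df["response"].iloc[0] == pytest.approx(0.5)

    def test_asymptote(self):
        df = syn.generate_binding_data(5.0, 1.0, [500.0], noise_sd=0.0)
        assert df["response"].iloc[0] == pytest.approx(1.0, rel=0.01)

    def test_monotone_on_log_grid(self):
        conc = np.logspace(-1, 2, 9)          # 0.1 - 100 nM
        df = syn.generate_binding_data(5.09, 1.0, conc, noise_sd=0.0)
        assert np.all(np.diff(df["response"]) > 0)


class TestTimeseries:
    def test_zero_rate_flat(self):
        df = syn.generate_uptake_timeseries(3, 10.0, 5, 50, [(10, 20)], 0.0)
        assert np.all(df["value"] == 0)

    def test_single_epoch_rise(self):
        k, rate = 12, 0.05
        df = syn.generate_uptake_timeseries(1, 10.0, 0, 40, [(10, 10 + k)], rate)
        v = df["value"].to_numpy()
        assert v[-1] - v[0] == pytest.approx(k * rate)

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_uptake_timeseries(1, 10.0, 0, 40, [(5, 15), (10, 20)], 0.1)

    def test_determinism(self):
        a = syn.generate_uptake_timeseries(2, 10.0, 3, 30, [(5, 10)], 0.1,
                                           noise_sd=0.5, seed=4)
        b = syn.generate_uptake_timeseries(2, 10.0, 3, 30, [(5, 10)], 0.1,
                                           noise_sd=0.5, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestTrajectory:
    def test_positions_within_cage(self):
        df = syn.generate_trajectory(120, 25.0, cage=(38.0, 22.0), seed=0)
        assert df["x_cm"].between(0, 38).all()
        assert df["y_cm"].between(0, 22).all()

    def test_pause_confinement(self):
        df = syn.generate_trajectory(60, 25.0, pause_schedule=[(20.0, 15.0)], seed=1)
        win = df[(df["t_s"] >= 20.0) & (df["t_s"] < 35.0)]
        anchor = win[["x_cm", "y_cm"]].iloc[0].to_numpy()
        disp = np.hypot(win["x_cm"] - anchor[0], win["y_cm"] - anchor[1])
        assert disp.max() <= 1.0 + 1e-9

    def test_overlapping_pauses_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_trajectory(60, 25.0, pause_schedule=[(5, 10), (12, 10)])

    def test_determinism(self):
        a = syn.generate_trajectory(30, 25.0, pause_schedule=[(5, 12)], seed=2)
        b = syn.generate_trajectory(30, 25.0, pause_schedule=[(5, 12)], seed=2)
        pd.testing.assert_frame_equal(a, b)


def test_distribution_sampling_matches_parameters():
    # requested uptake distribution recovered within 3 standard errors
    rng = np.random.default_rng(0)
    draws = syn.draw_distribution(("normal", {"mean": 0.3, "sd": 0.06}), 2000, rng)
    se_mean = 0.06 / np.sqrt(2000)
    assert abs(draws.mean() - 0.3) < 3 * se_mean
    se_sd = 0.06 / np.sqrt(2 * (2000 - 1))
    assert abs(draws.std(ddof=1) - 0.06) < 3 * se_sd


def test_write_fov_roundtrip(tmp_path, noisy_fov):
    import json
    import tifffile

    paths = syn.write_fov(noisy_fov, tmp_path, "fovA")
    gz = tifffile.imread(paths["gz"])
    assert gz.dtype == np.uint16
    assert gz.shape == noisy_fov.shape
    truth = json.loads(paths["truth"].read_text())
    assert len(truth["bouton_centers"]) == len(noisy_fov.bouton_centers)
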