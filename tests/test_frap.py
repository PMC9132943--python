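"""FRAP estimation tests: closed forms, oracles, and parameter recovery."""

import numpy as np
import pytest

import bmcquant as bq
from bmcquant.config import RunConfig
from bmcquant.errors import AnalysisError, InputError, ParameterError
from bmcquant.frap import _predicted_curve

from conftest import make_profile


class TestExtractProfile:
    def test_uniform_rod_gives_flat_profile(self, noiseless_series):
        series, _, params = noiseless_series
        prof = bq.extract_axial_profile(series)
        pre = prof.prebleach_profile
        interior = pre[3:-3]
        assert interior.std() / interior.mean() < 0.02

    def test_profile_geometry_passthrough(self):
        """A horizontal 40 px rod at 0.05 um/px spans 40 bins = 2.0 um."""
        frames = np.zeros((4, 20, 50))
        frames[:, 5:15, 5:45] = 100.0
        series = bq.ImageSeries(frames, pixel_size=0.05, frame_interval=60.0)
        prof = bq.extract_axial_profile(series)
        assert prof.positions.size == 40
        assert prof.positions[-1] + 0.025 == pytest.approx(2.0)

    def test_all_zero_frame_fails_segmentation(self):
        series = bq.ImageSeries(np.zeros((4, 20, 50)), pixel_size=0.05,
                                frame_interval=60.0)
        with pytest.raises(bq.SegmentationError):
            bq.extract_axial_profile(series)

    def test_too_few_frames_rejected(self):
        series = bq.ImageSeries(np.ones((2, 10, 30)), pixel_size=0.05,
                                frame_interval=60.0)
        with pytest.raises(InputError):
            bq.extract_axial_profile(series, prebleach_frames=1)


class TestNormalize:
    def test_half_total_frame_scaled_twice(self):
        pre = np.full(10, 4.0)
        prof = make_profile(pre, [pre * 0.5, pre * 0.5])
        norm = bq.normalize_profiles(prof)
        assert np.allclose(norm.profiles[1], pre)

    def test_prebleach_frame_unchanged(self):
        pre = np.linspace(1, 5, 12)
        prof = make_profile(pre, [pre * 0.3, pre * 0.2])
        norm = bq.normalize_profiles(prof)
        assert np.allclose(norm.profiles[0], pre, rtol=1e-14)

    def test_every_frame_matches_prebleach_total(self, cargo_series):
        series, _, _ = cargo_series
        norm = bq.normalize_profiles(bq.extract_axial_profile(series))
        target = norm.prebleach_profile.sum()
        assert np.allclose(norm.profiles.sum(axis=1), target, rtol=1e-12)

    def test_zero_total_frame_rejected(self):
        pre = np.full(8, 2.0)
        prof = make_profile(pre, [pre * 0.0, pre])
        with pytest.raises(bq.NormalizationError):
            bq.normalize_profiles(prof)


class TestBleachCenter:
    def test_generator_ground_truth_position(self, noiseless_profile):
        center = bq.find_bleach_center(noiseless_profile)
        # bleach line spans indices 27..32 on the 60 px grid; 29 and 30 are
        # equidistant from the cell center and the tie rule picks the lower
        assert center == 29

    def test_tie_broken_toward_cell_center_then_lower_index(self):
        pre = np.full(41, 10.0)
        post = pre.copy()
        post[10] = post[30] = 2.0  # equidistant from the center index 20
        prof = make_profile(pre, [post, post])
        assert bq.find_bleach_center(prof) == 10

    def test_unbleached_series_is_an_error(self):
        pre = np.full(20, 3.0)
        prof = make_profile(pre, [pre, pre])
        with pytest.raises(AnalysisError, match="no bleach"):
            bq.find_bleach_center(prof)


class TestRecoveryCurve:
    def test_prebleach_level_normalizes_to_one(self):
        pre = np.full(20, 5.0)
        post = pre.copy()
        post[10] = 1.0
        prof = make_profile(pre, [post, pre])  # second frame back at prebleach
        curve = bq.recovery_curve(prof, 10, window=1)
        assert curve.values[1] == pytest.approx(1.0)

    def test_first_postbleach_value_below_one(self, noiseless_profile):
        center = bq.find_bleach_center(noiseless_profile)
        curve = bq.recovery_curve(noiseless_profile, center)
        assert curve.values[0] < 1.0
        assert curve.times[0] == 0.0

    def test_fully_mobile_series_plateaus_at_one(self):
        params = bq.SimulationParams(mobile_fraction=1.0, D_mobile=4e-3,
                                     noise_gaussian_sigma=0.0, seed=2)
        series, _ = bq.generate_frap_series(params)
        prof = bq.normalize_profiles(bq.extract_axial_profile(series))
        curve = bq.recovery_curve(prof, bq.find_bleach_center(prof))
        assert curve.values[-1] == pytest.approx(1.0, abs=0.01)

    def test_window_exceeding_grid_rejected(self, noiseless_profile):
        with pytest.raises(InputError):
            bq.recovery_curve(noiseless_profile, 1, window=5)


class TestClosedForms:
    def test_mobile_fraction_direct_substitution(self):
        assert bq.mobile_fraction(1.0, 0.2, 0.8).raw == pytest.approx(0.75)

    def test_full_and_zero_recovery_limits(self):
        assert bq.mobile_fraction(1.0, 0.2, 1.0).raw == pytest.approx(1.0)
        assert bq.mobile_fraction(1.0, 0.2, 0.2).raw == pytest.approx(0.0)

    def test_no_bleach_is_an_error(self):
        with pytest.raises(AnalysisError):
            bq.mobile_fraction(0.5, 0.5, 0.7)

    def test_half_time_closed_form(self):
        assert bq.half_time(np.log(2)) == pytest.approx(1.0, rel=1e-12)
        assert bq.half_time(1.0) == pytest.approx(np.log(2), rel=1e-12)

    def test_half_time_requires_positive_rate(self):
        with pytest.raises(ParameterError):
            bq.half_time(0.0)

    def test_mobile_fraction_equals_amplitude_ratio(self):
        """With final = postbleach + A, M reduces to A / (pre - post)."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            pre = rng.uniform(0.8, 1.2)
            post = rng.uniform(0.0, pre - 0.05)
            A = rng.uniform(0.0, pre - post)
            m = bq.mobile_fraction(pre, post, post + A).raw
            assert abs(m - A / (pre - post)) <= 1e-10


class TestFitExponential:
    def test_exact_model_recovery(self):
        t = np.arange(0, 3601, 60.0)
        curve = bq.FrapCurve(times=t, values=0.2 + 0.8 * (1 - np.exp(-0.1 * t)))
        A, tau = bq.fit_exponential(curve)
        assert A == pytest.approx(0.8, abs=1e-6)
        assert tau == pytest.approx(0.1, abs=1e-6)

    def test_constant_curve_degenerates_to_zero_amplitude(self):
        t = np.arange(0, 601, 60.0)
        with pytest.warns(UserWarning, match="constant"):
            A, tau = bq.fit_exponential(bq.FrapCurve(times=t,
                                                     values=np.full(t.size, 0.4)))
        assert A == 0.0
        assert np.isnan(tau)

    def test_amplitude_unbiased_under_noise(self):
        """Monte-Carlo: mean fitted A within 0.02 of truth at sigma = 0.02."""
        t = np.arange(0, 3601, 60.0)
        clean = 0.2 + 0.8 * (1 - np.exp(-0.01 * t))
        rng = np.random.default_rng(17)
        fits = []
        for _ in range(20):
            vals = clean + rng.normal(0, 0.02, t.size)
            with np.errstate(all="ignore"):
                A, _ = bq.fit_exponential(bq.FrapCurve(times=t, values=vals))
            fits.append(A)
        assert abs(np.mean(fits) - 0.8) <= 0.02


class TestEstimateD:
    def test_objective_zero_minimum_from_forward_model(self):
        """A curve literally produced by the forward model pins D exactly."""
        pre = np.full(60, 10.0)
        post = pre.copy()
        post[27:33] = 2.0
        times = np.arange(0, 3600, 60.0)
        D_star = 5e-4
        sims = bq.simulate_recovery(pre, post, 0.7, D_star, times, 0.05)
        prof = make_profile(pre, sims)
        D_hat, rss = bq.estimate_D(prof, 30, 0.7)
        assert D_hat == pytest.approx(D_star, rel=5e-3)
        assert rss <= 1e-6  # limited only by the search tolerance

    def test_immobile_input_is_an_error(self, noiseless_profile):
        with pytest.raises(AnalysisError):
            bq.estimate_D(noiseless_profile, 30, 0.0)

    def test_predicted_curve_matches_observed_at_truth(self, noiseless_profile):
        center = bq.find_bleach_center(noiseless_profile)
        observed = bq.recovery_curve(noiseless_profile, center).values
        pred = _predicted_curve(noiseless_profile, center, 1, 0.8, 4e-4)
        assert np.max(np.abs(pred - observed)) < 5e-3


class TestAnalyzeCell:
    def test_noiseless_round_trip(self, noiseless_series):
        series, _, params = noiseless_series
        est = bq.analyze_cell(series)
        assert est.M == pytest.approx(params.mobile_fraction, abs=0.02)
        assert est.D == pytest.approx(params.D_mobile, rel=0.05)
        assert est.half_time == pytest.approx(np.log(2) / est.tau, rel=1e-9)

    def test_shell_like_fixture_is_nearly_immobile(self):
        series, _ = bq.generate_frap_series(bq.SimulationParams.shell_like(seed=4))
        est = bq.analyze_cell(series)
        assert est.M < 0.15

    def test_two_frame_series_rejected(self):
        series = bq.ImageSeries(np.ones((2, 10, 30)), pixel_size=0.05,
                                frame_interval=60.0)
        with pytest.raises(InputError):
            bq.analyze_cell(series)

    def test_half_time_decreases_with_diffusivity(self):
        """Faster diffusion must shorten the recovery half-time."""
        halves = []
        for D in (1e-4, 4e-4, 1e-3):
            series, _ = bq.generate_frap_series(bq.SimulationParams(
                D_mobile=D, mobile_fraction=0.8, noise_gaussian_sigma=0.0, seed=6))
            halves.append(bq.analyze_cell(series).half_time)
        assert halves[0] > halves[1] > halves[2]


class TestSummarize:
    @staticmethod
    def _est(D, M=0.8):
        return bq.FrapEstimate(M=M, M_raw=M, A=0.6, tau=0.01, half_time=69.3,
                               D=D, rss=0.0, n_frames=61)

    def test_fold_ratio_of_group_means(self):
        table, fold = bq.summarize({
            "cargo": [self._est(4.02e-4)], "shell": [self._est(0.28e-4)],
        })
        assert fold == pytest.approx(14.357, abs=0.01)

    def test_single_estimate_reports_zero_sd(self):
        table, _ = bq.summarize({"g": [self._est(1e-4)]})
        row = table.query("variable == 'D'").iloc[0]
        assert row["sd"] == 0.0 and row["n"] == 1

    def test_duplicate_estimates_have_zero_sd(self):
        table, _ = bq.summarize({"g": [self._est(1e-4), self._est(1e-4)]})
        assert table.query("variable == 'D'")["sd"].item() == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            bq.summarize({})
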