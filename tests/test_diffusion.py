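"""Diffusion-engine tests against closed-form and self-consistency oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import bmcquant as bq
from bmcquant.errors import InputError, ParameterError

DX = 0.05


def gaussian_profile(n=400, sigma=0.2, center=None, dx=DX):
    x = (np.arange(n) + 0.5) * dx
    c = center if center is not None else n * dx / 2
    return np.exp(-((x - c) ** 2) / (2 * sigma**2)), x


class TestLaplacian:
    def test_constant_profile_is_steady_state(self):
        lap = bq.discrete_laplacian(np.full(20, 3.7), DX)
        assert np.allclose(lap, 0.0)

    def test_unit_spike_direct_substitution(self):
        # interior point: (0 - 2 + 0)/dx^2; edge ghost reflected across the
        # boundary face gives single-neighbour flux (1 - 0)/dx^2
        lap = bq.discrete_laplacian(np.array([0.0, 1.0, 0.0]), 1.0)
        assert lap.tolist() == [1.0, -2.0, 1.0]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(hnp.arrays(float, st.integers(3, 100),
                      elements=st.floats(0, 1e3, allow_nan=False)))
    def test_sums_to_zero_no_flux(self, c):
        """Discrete divergence theorem: no-flux boundaries export no mass."""
        assert abs(bq.discrete_laplacian(c, DX).sum() * DX * DX) <= 1e-9

    def test_too_short_profile_rejected(self):
        with pytest.raises(InputError):
            bq.discrete_laplacian(np.array([1.0, 2.0]), DX)


class TestStep:
    def test_zero_diffusion_identity(self):
        c0 = np.array([1.0, 5.0, 2.0, 0.5])
        out = bq.step(bq.DiffusionState(c0, DX), 0.0, 1.0)
        assert np.array_equal(out.concentration, c0)

    def test_uniform_profile_unchanged(self):
        c0 = np.full(10, 4.0)
        out = bq.step(bq.DiffusionState(c0, DX), 1e-3, 0.1)
        assert np.allclose(out.concentration, c0, atol=1e-14)

    def test_stability_bound_enforced(self):
        with pytest.raises(ParameterError, match="stability"):
            bq.step(bq.DiffusionState(np.ones(5), DX), 1e-3, 10.0)

    def test_gaussian_spreading_variance_law(self):
        """After time t the variance of a Gaussian grows to s0^2 + 2Dt."""
        sigma0, D, t = 0.2, 1e-3, 10.0
        c0, x = gaussian_profile(sigma=sigma0)
        out = bq.evolve(bq.DiffusionState(c0, DX), D, [t])[0]
        mu = (out * x).sum() / out.sum()
        var = (out * (x - mu) ** 2).sum() / out.sum()
        assert var == pytest.approx(sigma0**2 + 2 * D * t, rel=0.02)


class TestEvolve:
    def test_current_time_returns_initial_profile(self):
        c0 = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        out = bq.evolve(bq.DiffusionState(c0, DX, time=7.0), 1e-3, [7.0])
        assert np.array_equal(out[0], c0)

    def test_step_function_equilibrates_to_conserved_mean(self):
        c0 = np.where(np.arange(64) < 32, 2.0, 0.0)
        L = 64 * DX
        D = 1e-3
        out = bq.evolve(bq.DiffusionState(c0, DX), D, [20 * L**2 / D])[0]
        assert np.max(np.abs(out - c0.mean())) <= 1e-3 * c0.mean()

    def test_mass_conserved_along_trajectory(self):
        c0, _ = gaussian_profile(n=64)
        times = np.linspace(0, 5000, 12)
        outs = bq.evolve(bq.DiffusionState(c0, DX), 4e-4, times)
        totals = np.array([o.sum() for o in outs])
        assert np.max(np.abs(totals / c0.sum() - 1)) <= 1e-9

    def test_dt_refinement_self_convergence(self):
        """Halving dt moves the t = 600 s profile by < 0.1%."""
        c0, _ = gaussian_profile(n=100)
        st_ = bq.DiffusionState(c0, DX)
        coarse = bq.evolve(st_, 1e-3, [600.0])[0]
        fine = bq.evolve(st_, 1e-3, [600.0], refine=2)[0]
        assert np.max(np.abs(coarse - fine)) / coarse.max() < 1e-3

    def test_semigroup_property(self):
        """Evolving t1 then t2 equals evolving t1 + t2 in one call."""
        c0, _ = gaussian_profile(n=64)
        D = 1e-3
        # commensurate intervals: both paths use the identical stable dt
        dt_max = 0.25 * DX**2 / D
        t1 = 400 * dt_max
        t2 = 800 * dt_max
        a = bq.evolve(bq.DiffusionState(c0, DX), D, [t1])[0]
        b = bq.evolve(bq.DiffusionState(a, DX, time=t1), D, [t1 + t2])[0]
        c = bq.evolve(bq.DiffusionState(c0, DX), D, [t1 + t2])[0]
        assert np.max(np.abs(b - c)) <= 1e-10

    def test_matches_cosine_series_oracle(self):
        """Engine vs analytic no-flux heat-equation solution on 64 points."""
        n = 64
        x = (np.arange(n) + 0.5) * DX
        L = n * DX
        c0 = 1.0 + 0.5 * np.cos(np.pi * x / L) + 0.3 * np.cos(3 * np.pi * x / L)
        D = 4e-4
        for frac in (0.05, 0.2, 0.5, 1.0):
            t = frac * L**2 / D
            eng = bq.evolve(bq.DiffusionState(c0, DX), D, [t])[0]
            ana = bq.cosine_series_solution(c0, DX, D, t)
            assert np.max(np.abs(eng - ana)) <= 5e-3 * np.max(np.abs(ana))

    def test_non_monotone_sample_times_rejected(self):
        with pytest.raises(InputError):
            bq.evolve(bq.DiffusionState(np.ones(5), DX), 1e-3, [10.0, 5.0])


class TestSimulateRecovery:
    def setup_method(self):
        self.n = 60
        self.pre = np.full(self.n, 10.0)
        self.post = self.pre.copy()
        self.post[27:33] = 2.0

    def test_fully_immobile_profile_is_frozen(self):
        outs = bq.simulate_recovery(self.pre, self.post, 0.0, 1e-3,
                                    [0, 600, 3600], DX)
        for o in outs:
            assert np.array_equal(o, self.post)

    def test_fully_mobile_equilibrates_to_postbleach_mean(self):
        L = self.n * DX
        D = 1e-3
        out = bq.simulate_recovery(self.pre, self.post, 1.0, D,
                                   [20 * L**2 / D], DX)[0]
        assert np.allclose(out, self.post.mean(), rtol=1e-6)

    def test_half_mobile_limit_is_frozen_plus_equilibrated_mixture(self):
        """At t -> inf the center tends to 0.5*mean(post) + 0.5*post[center]."""
        L = self.n * DX
        D = 1e-3
        out = bq.simulate_recovery(self.pre, self.post, 0.5, D,
                                   [20 * L**2 / D], DX)[0]
        expected = 0.5 * self.post.mean() + 0.5 * self.post[30]
        assert out[30] == pytest.approx(expected, rel=1e-6)

    def test_center_recovery_is_monotone_in_time(self):
        times = np.arange(0, 3600, 60.0)
        outs = bq.simulate_recovery(self.pre, self.post, 0.8, 4e-4, times, DX)
        center = np.array([o[30] for o in outs])
        assert np.all(np.diff(center) >= -1e-12)

    def test_observable_mass_conserved(self):
        times = np.arange(0, 3600, 60.0)
        outs = bq.simulate_recovery(self.pre, self.post, 0.8, 4e-4, times, DX)
        totals = np.array([o.sum() for o in outs])
        assert np.max(np.abs(totals / self.post.sum() - 1)) <= 1e-9

    def test_invalid_mobile_fraction_rejected(self):
        with pytest.raises(ParameterError):
            bq.simulate_recovery(self.pre, self.post, 1.2, 1e-3, [0.0], DX)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InputError):
            bq.simulate_recovery(self.pre[:-1], self.post, 0.5, 1e-3, [0.0], DX)
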