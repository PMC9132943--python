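"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

import bmcquant as bq


@pytest.fixture(scope="session")
def cargo_series():
    """Noisy cargo-like FRAP series with its ground truth (fixed seed)."""
    params = bq.SimulationParams.cargo_like(seed=11)
    return bq.generate_frap_series(params) + (params,)


@pytest.fixture(scope="session")
def noiseless_series():
    """Noise-free FRAP series for exact round trips."""
    params = bq.SimulationParams(
        D_mobile=4e-4, mobile_fraction=0.8, noise_gaussian_sigma=0.0, seed=5
    )
    return bq.generate_frap_series(params) + (params,)


@pytest.fixture(scope="session")
def noiseless_profile(noiseless_series):
    """Normalized axial profile extracted from the noiseless series."""
    series, _, _ = noiseless_series
    return bq.normalize_profiles(bq.extract_axial_profile(series))


def make_profile(pre, post_frames, dt=60.0, dx=0.05):
    """Assemble an AxialProfile from explicit prebleach/post-bleach vectors."""
    pre = np.asarray(pre, dtype=float)
    profiles = np.vstack([pre[None], np.asarray(post_frames, dtype=float)])
    n = profiles.shape[0]
    return bq.AxialProfile(
        positions=(np.arange(pre.size) + 0.5) * dx,
        profiles=profiles,
        frame_times=np.arange(n) * dt,
        bleach_index=1,
    )
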