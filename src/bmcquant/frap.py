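"""FRAP estimation: mobile fraction and diffusion coefficient per cell.

The pipeline mirrors the classical line-bleach analysis of elongated
structures: axial intensity profiles are extracted per frame, every frame
is rescaled to the prebleach total fluorescence (compensating acquisition
photobleaching), the bleach center is located as the minimum of the
(post-bleach − prebleach) difference profile, and the recovery curve at
that center is reduced to

  * the mobile fraction
    ``M = (final − postbleach) / (prebleach − postbleach)``,
    with "final" taken from the fitted plateau of a single-exponential
    recovery fit ``f(t) = A (1 − e^(−τ t))``, half-time
    ``τ½ = ln 0.5 / (−τ)``;
  * the diffusion coefficient ``D``, found by matching the observed curve
    against two-population finite-difference recovery simulations
    (:mod:`bmcquant.diffusion`) over a deterministic log-grid plus
    golden-section refinement.

M is estimated first and D conditional on M (two-stage); a joint (M, D)
refinement is available behind ``FrapConfig.joint_fit``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

from . import diffusion
from .config import FrapConfig, RunConfig
from .coloc import cell_mask
from .errors import AnalysisError, FitError, InputError, NormalizationError, ParameterError
from .io import ImageSeries

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AxialProfile:
    """Per-frame 1D intensity along the cell's long axis.

    ``positions`` are pixel-center coordinates in μm; ``profiles`` has shape
    (n_frames, n_positions).  Frames up to (excluding) ``bleach_index`` are
    prebleach; ``bleach_index`` is the first post-bleach frame.
    """

    positions: np.ndarray
    profiles: np.ndarray
    frame_times: np.ndarray
    bleach_index: int = 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.profiles.ndim != 2:
            raise InputError("profiles must be 2D (frames x positions)")
        if self.profiles.shape[1] != self.positions.size:
            raise InputError("profiles and positions disagree on grid length")
        if self.frame_times.size != self.profiles.shape[0]:
            raise InputError("frame_times and profiles disagree on frame count")
        if not 1 <= self.bleach_index <= self.profiles.shape[0] - 1:
            raise InputError(
                f"bleach_index {self.bleach_index} must leave >= 1 prebleach and "
                f">= 1 post-bleach frame of {self.profiles.shape[0]}"
            )

    @property
    def prebleach_index(self) -> int:
        """Index of the last prebleach frame."""
        return self.bleach_index - 1

    @property
    def n_frames(self) -> int:
        return self.profiles.shape[0]

    @property
    def dx(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def prebleach_profile(self) -> np.ndarray:
        """Mean of all prebleach frames."""
        return self.profiles[: self.bleach_index].mean(axis=0)

    @property
    def post_times(self) -> np.ndarray:
        """Frame times relative to the first post-bleach frame."""
        return self.frame_times[self.bleach_index:] - self.frame_times[self.bleach_index]


@dataclass
class FrapCurve:
    """Normalized recovery curve at the bleach center.

    ``times`` start at 0 (first post-bleach frame); ``values`` are relative
    to the prebleach center intensity (prebleach = 1).  Values far outside
    [−0.2, 1.5] indicate a normalization problem and trigger a warning.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InputError("times and values must be equal-length 1D arrays")
        if self.times[0] != 0:
            raise InputError("curve times must start at 0 (first post-bleach frame)")
        if np.any(self.values < -0.2) or np.any(self.values > 1.5):
            warnings.warn(
                "recovery curve outside the sanity band [-0.2, 1.5]; "
                "check normalization",
                stacklevel=2,
            )


class MobileFraction(NamedTuple):
    """Raw mobile fraction and its [0, 1]-clipped companion."""

    raw: float
    clipped: float


@dataclass
class FrapEstimate:
    """Per-cell FRAP result."""

    M: float                # mobile fraction, clipped to [0, 1]
    M_raw: float            # unclipped value, kept for QC
    A: float                # fitted recovery amplitude
    tau: float              # exponential rate constant, s^-1
    half_time: float        # ln 0.5 / (-tau), s
    D: float                # diffusion coefficient, μm² s⁻¹
    rss: float              # residual sum of squares of the D match
    n_frames: int
    qc_pass: bool = True
    provenance: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "M": self.M, "M_raw": self.M_raw, "A": self.A, "tau": self.tau,
            "half_time": self.half_time, "D": self.D, "rss": self.rss,
            "n_frames": self.n_frames, "qc_pass": self.qc_pass,
        }


# ---------------------------------------------------------------------------
# profile extraction and normalization
# ---------------------------------------------------------------------------

def extract_axial_profile(
    series: ImageSeries,
    mask: np.ndarray | None = None,
    prebleach_frames: int = 1,
) -> AxialProfile:
    """Extract per-frame intensity profiles along the cell's long axis.

    The cell mask is derived by Otsu thresholding of the mean prebleach
    frame when not supplied.  The long axis is the major axis of the mask's
    best-fit ellipse; masked pixel intensities are summed across the short
    axis into bins of one pixel pitch along that axis.
    """
    from skimage.measure import regionprops, label as sklabel

    if series.n_frames < prebleach_frames + 2:
        raise InputError(
            f"need >= {prebleach_frames + 2} frames "
            f"({prebleach_frames} prebleach + bleach + recovery), "
            f"got {series.n_frames}"
        )
    ref = series.frames[:prebleach_frames].mean(axis=0)
    if mask is None:
        mask = cell_mask(ref)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ref.shape:
        raise InputError("mask shape does not match frames")
    if not mask.any():
        raise InputError("mask is empty")

    props = regionprops(sklabel(mask))[0]
    theta = props.orientation  # angle between row axis and major axis
    # unit vector along the major axis in (row, col) coordinates
    u = np.array([-np.cos(theta), np.sin(theta)])
    rr, cc = np.nonzero(mask)
    s = rr * u[0] + cc * u[1]
    idx = np.round(s - s.min()).astype(int)
    n_bins = idx.max() + 1
    profiles = np.zeros((series.n_frames, n_bins))
    for t in range(series.n_frames):
        np.add.at(profiles[t], idx, series.frames[t][rr, cc])
    positions = (np.arange(n_bins) + 0.5) * series.pixel_size
    return AxialProfile(
        positions=positions,
        profiles=profiles,
        frame_times=np.asarray(series.timestamps, dtype=float),
        bleach_index=prebleach_frames,
    )


def normalize_profiles(profile: AxialProfile) -> AxialProfile:
    """Scale every frame to the prebleach total fluorescence.

    Equalizing per-frame totals against the prebleach cell compensates the
    intensity lost to acquisition photobleaching and microscope
    fluctuations, so post-bleach frames are comparable to the prebleach
    reference.
    """
    target = profile.prebleach_profile.sum()
    if target <= 0:
        raise NormalizationError("prebleach total fluorescence is not positive")
    sums = profile.profiles.sum(axis=1)
    if np.any(sums <= 0):
        bad = int(np.nonzero(sums <= 0)[0][0])
        raise NormalizationError(f"frame {bad} has non-positive total fluorescence")
    scaled = profile.profiles * (target / sums)[:, None]
    return AxialProfile(
        positions=profile.positions.copy(),
        profiles=scaled,
        frame_times=profile.frame_times.copy(),
        bleach_index=profile.bleach_index,
    )


def find_bleach_center(profile: AxialProfile) -> int:
    """Locate the bleach center as the minimum of the difference profile.

    The difference profile is (first post-bleach frame − prebleach frame);
    exact ties are broken toward the geometric cell center, then toward the
    lower index.
    """
    diff = profile.profiles[profile.bleach_index] - profile.prebleach_profile
    if diff.min() >= 0:
        raise AnalysisError("no bleach detected: difference profile is non-negative")
    minima = np.nonzero(diff == diff.min())[0]
    center = (diff.size - 1) / 2.0
    # sort by distance to the cell center, then by index
    order = sorted(minima, key=lambda i: (abs(i - center), i))
    return int(order[0])


def recovery_curve(
    profile: AxialProfile, center: int, window: int = 1
) -> FrapCurve:
    """Recovery curve at the bleach center, normalized to prebleach.

    The value at each post-bleach frame is the mean normalized intensity
    over ``[center − window, center + window]`` divided by the prebleach
    mean over the same window; times are relative to the first post-bleach
    frame.
    """
    n = profile.profiles.shape[1]
    if not 0 <= center < n:
        raise InputError(f"center {center} outside grid of length {n}")
    if window < 0 or center - window < 0 or center + window >= n:
        raise InputError(
            f"window {window} around center {center} exceeds grid of length {n}"
        )
    sl = slice(center - window, center + window + 1)
    ref = profile.prebleach_profile[sl].mean()
    if ref <= 0:
        raise AnalysisError("prebleach intensity at the bleach center is not positive")
    vals = profile.profiles[profile.bleach_index:, sl].mean(axis=1) / ref
    return FrapCurve(times=profile.post_times, values=vals)


# ---------------------------------------------------------------------------
# closed-form quantities
# ---------------------------------------------------------------------------

def mobile_fraction(
    prebleach_value: float, postbleach_value: float, final_value: float
) -> MobileFraction:
    """Mobile fraction M = (final − postbleach) / (prebleach − postbleach).

    All three values are on the normalized intensity scale at the bleach
    center.  Returns the raw ratio together with its [0, 1] clip; raw
    values outside the QC band indicate a failed estimate, not a valid
    extreme.
    """
    denom = prebleach_value - postbleach_value
    if denom <= 0:
        raise AnalysisError(
            "prebleach value must exceed postbleach value (no bleach detected)"
        )
    raw = (final_value - postbleach_value) / denom
    return MobileFraction(raw=raw, clipped=float(np.clip(raw, 0.0, 1.0)))


def half_time(tau: float) -> float:
    """Recovery half-time τ½ = ln 0.5 / (−τ) for rate constant τ > 0."""
    if tau <= 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    return float(np.log(0.5) / (-tau))


def fit_exponential(curve: FrapCurve) -> tuple[float, float]:
    """Least-squares fit of the recovery to f(t) = A (1 − e^(−τ t)).

    The fit is on recovery above the post-bleach baseline, i.e.
    ``values(t) − values(0)``.  Initialization: A₀ = last − first value,
    τ₀ = 1 / (time to half of A₀).  Returns (A, τ); a flat curve returns
    (0, nan) with a warning, and persistent non-convergence raises
    :class:`FitError`.
    """
    if curve.times.size < 4:
        raise InputError(f"need >= 4 post-bleach points, got {curve.times.size}")
    t = curve.times
    y = curve.values - curve.values[0]
    a0 = y[-1]
    if np.allclose(y, 0.0, atol=1e-12):
        warnings.warn("constant recovery curve: A = 0, tau unidentifiable",
                      stacklevel=2)
        return 0.0, float("nan")
    # time at which recovery first crosses half its end level
    crossing = np.nonzero(y >= 0.5 * a0)[0] if a0 > 0 else np.array([], dtype=int)
    t_half = t[crossing[0]] if crossing.size and t[crossing[0]] > 0 else t[-1] / 4
    tau0 = 1.0 / t_half

    def model(tt, A, tau):
        return A * (1.0 - np.exp(-tau * tt))

    last_err: Exception | None = None
    for a_init, tau_init in ((a0, tau0), (a0, tau0 * 10), (a0, tau0 / 10)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, t, y, p0=[a_init, tau_init],
                    bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=20000,
                )
            return float(popt[0]), float(popt[1])
        except RuntimeError as e:
            last_err = e
    raise FitError(
        f"exponential fit did not converge after restarts "
        f"(A0={a0:.4g}, tau0={tau0:.4g}): {last_err}"
    )


# ---------------------------------------------------------------------------
# diffusion-coefficient matching
# ---------------------------------------------------------------------------

def _predicted_curve(
    profile: AxialProfile, center: int, window: int, M: float, D: float
) -> np.ndarray:
    """Bleach-center curve predicted by the two-population diffusion model."""
    sl = slice(center - window, center + window + 1)
    pre = profile.prebleach_profile
    post = profile.profiles[profile.bleach_index]
    ref = pre[sl].mean()
    sims = diffusion.simulate_recovery(
        pre, post, M, D, profile.post_times, profile.dx
    )
    return np.array([s[sl].mean() / ref for s in sims])


def estimate_D(
    profile: AxialProfile,
    center: int,
    M: float,
    d_range: tuple[float, float] = (1e-6, 1e-1),
    points_per_decade: int = 25,
    rel_tol: float = 1e-3,
    window: int = 1,
) -> tuple[float, float]:
    """Match simulated to observed recovery to estimate D.

    For each candidate D the two-population diffusion model predicts the
    bleach-center curve at the observed frame times; the objective is the
    sum of squared differences to the observed curve.  The minimum is
    located by a log-grid scan (``points_per_decade``) followed by
    golden-section refinement to relative tolerance ``rel_tol`` — fully
    deterministic.  Returns (D, rss).
    """
    if not 0.0 <= M <= 1.0:
        raise ParameterError(f"M must be in [0, 1], got {M}")
    if M == 0.0:
        raise AnalysisError("M = 0: immobile profile carries no recovery information")
    lo, hi = d_range
    if not 0 < lo < hi:
        raise ParameterError(f"invalid D search range {d_range}")
    observed = recovery_curve(profile, center, window).values

    def objective_log(u: float) -> float:
        pred = _predicted_curve(profile, center, window, M, float(np.exp(u)))
        r = pred - observed
        return float(r @ r)

    n_grid = int(np.ceil(points_per_decade * np.log10(hi / lo))) + 1
    us = np.linspace(np.log(lo), np.log(hi), n_grid)
    vals = np.array([objective_log(u) for u in us])
    if vals.max() - vals.min() <= 1e-14 * max(vals.max(), 1.0):
        raise AnalysisError(
            "objective is flat across the D range: no recovery information"
        )
    i = int(np.argmin(vals))
    if i in (0, n_grid - 1):
        log.warning("D search minimum at range boundary %.3g", np.exp(us[i]))
        return float(np.exp(us[i])), float(vals[i])
    res = minimize_scalar(
        objective_log,
        bracket=(us[i - 1], us[i], us[i + 1]),
        method="golden",
        options={"xtol": rel_tol, "maxiter": 200},
    )
    u_best, rss = (res.x, res.fun) if res.fun <= vals[i] else (us[i], vals[i])
    return float(np.exp(u_best)), float(rss)


def _joint_refine(
    profile: AxialProfile, center: int, window: int,
    M0: float, D0: float,
) -> tuple[float, float, float]:
    """Local joint (M, D) least-squares refinement from the two-stage result."""
    observed = recovery_curve(profile, center, window).values
    times = profile.post_times

    def model(tt, M, logD):
        return _predicted_curve(profile, center, window,
                                float(np.clip(M, 0, 1)), float(np.exp(logD)))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            model, times, observed, p0=[M0, np.log(D0)],
            bounds=([0.0, np.log(1e-8)], [1.0, np.log(1.0)]),
            xtol=1e-10, ftol=1e-10, maxfev=200,
        )
    M, logD = popt
    r = model(times, M, logD) - observed
    return float(M), float(np.exp(logD)), float(r @ r)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def analyze_profile(profile: AxialProfile, config: RunConfig | None = None) -> FrapEstimate:
    """Run the estimation chain on an extracted axial profile."""
    cfg = (config or RunConfig()).frap
    run_cfg = config or RunConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise type(e)(f"[{name}] {e}") from e

    norm = stage("normalize", normalize_profiles, profile)
    center = stage("bleach-center", find_bleach_center, norm)
    curve = stage("recovery-curve", recovery_curve, norm, center, cfg.window)
    A, tau = stage("exp-fit", fit_exponential, curve)

    post0 = curve.values[0]
    if cfg.final_mode == "plateau":
        final = post0 + A
    elif cfg.final_mode == "last_frames":
        final = float(curve.values[-cfg.final_frames:].mean())
    else:
        raise ParameterError(f"unknown final_mode {cfg.final_mode!r}")
    mf = stage("mobile-fraction", mobile_fraction, 1.0, post0, final)
    t_half = half_time(tau) if np.isfinite(tau) and tau > 0 else float("nan")

    if mf.clipped > 0:
        D, rss = stage(
            "estimate-D", estimate_D, norm, center, mf.clipped,
            (cfg.d_min, cfg.d_max), cfg.d_points_per_decade, cfg.d_rel_tol,
            cfg.window,
        )
    else:
        D, rss = float("nan"), float("nan")

    M_final, M_raw = mf.clipped, mf.raw
    if cfg.joint_fit and np.isfinite(D):
        M_final, D, rss = stage("joint-fit", _joint_refine, norm, center,
                                cfg.window, mf.clipped, D)

    qc = cfg.m_qc_band[0] <= mf.raw <= cfg.m_qc_band[1]
    if not qc:
        log.warning("raw mobile fraction %.3f outside QC band %s", mf.raw, cfg.m_qc_band)
    return FrapEstimate(
        M=M_final, M_raw=M_raw, A=A, tau=tau, half_time=t_half,
        D=D, rss=rss, n_frames=profile.n_frames, qc_pass=qc,
        provenance={"seed": run_cfg.random_seed, "config": run_cfg.hash()},
    )


def analyze_cell(series: ImageSeries, config: RunConfig | None = None) -> FrapEstimate:
    """Full per-cell pipeline: extract → normalize → … → estimate_D."""
    cfg = (config or RunConfig()).frap
    profile = extract_axial_profile(series, prebleach_frames=cfg.prebleach_frames)
    return analyze_profile(profile, config)


def summarize(
    groups: dict[str, list[FrapEstimate]],
) -> tuple[pd.DataFrame, float | None]:
    """Per-group mean, SD and n of M, τ½ and D, plus a D fold-ratio.

    SD is the sample standard deviation (ddof=1), reported as 0 for n = 1.
    When exactly two groups are supplied the ratio of their mean D values
    (first listed / second listed) is returned as well.
    """
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise InputError("summarize needs >= 1 estimate per group")
    rows = []
    for name, ests in groups.items():
        for var, get in (("M", lambda e: e.M), ("half_time", lambda e: e.half_time),
                         ("D", lambda e: e.D)):
            x = np.array([get(e) for e in ests], dtype=float)
            rows.append({
                "group": name, "variable": var,
                "mean": float(np.nanmean(x)),
                "sd": float(np.nanstd(x, ddof=1)) if x.size > 1 else 0.0,
                "n": int(x.size),
            })
    table = pd.DataFrame(rows)
    fold = None
    if len(groups) == 2:
        g1, g2 = list(groups)
        d1 = table.query("group == @g1 and variable == 'D'")["mean"].item()
        d2 = table.query("group == @g2 and variable == 'D'")["mean"].item()
        fold = d1 / d2 if d2 != 0 else float("inf")
    return table, fold
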