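"""Ground-truth generators emulating confocal imaging of rod-shaped cells.

Three generators cover the three analysis stages:

* :func:`generate_frap_series` — line-bleach FRAP of an elongated
  intracellular structure: uniform prebleach profile, instantaneous
  multiplicative bleach scar, two-population (mobile/immobile) diffusive
  recovery imaged at a fixed frame interval, rendered into 2D rod images
  with Gaussian and optional Poisson detection noise.
* :func:`generate_coloc_pair` — a dual-channel still image with a
  programmed fraction ρ of colocalized foci.
* :func:`generate_birth_timelapse` — two-channel time-lapses in which
  shell and cargo foci appear at scheduled frames and axial positions.

Defaults mirror the study conditions the pipeline is meant for: ~1 × 3 μm
rods, one frame per minute for an hour, a ~0.3 μm bleach line across the
structure center, and 2% Gaussian detection noise.  All randomness flows
from the ``seed`` field through named substreams; the same seed gives
bit-identical output.  Ground truth (parameters, noiseless profiles,
appearance schedules) is returned alongside every dataset.

The FRAP ground truth is produced by the same finite-difference engine the
estimator inverts, which makes round trips a test of estimation rather
than of the engine; ``engine="analytic"`` switches the forward model to
the independent cosine-series solution to break that circularity.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import diffusion
from .config import substream_rng
from .errors import ParameterError
from .io import ImageSeries


@dataclass
class SimulationParams:
    """Ground-truth settings of the FRAP generator.

    Lengths in μm, times in s, intensities in arbitrary units chosen to sit
    comfortably inside a 16-bit range.  ``bleach_center`` is a fraction of
    the cell length; ``bleach_depth`` is the fraction of fluorescence
    removed inside the bleach line (0 disables the bleach).
    ``noise_gaussian_sigma`` is relative
    to the prebleach per-pixel intensity; ``noise_poisson_scale`` is
    photons per intensity unit (0 disables shot noise).
    """

    cell_length: float = 3.0
    cell_width: float = 1.0
    pixel_size: float = 0.05
    frame_interval: float = 60.0
    n_frames: int = 61               # total, including prebleach frames
    prebleach_frames: int = 1
    bleach_center: float = 0.5
    bleach_width: float = 0.3
    bleach_depth: float = 0.8
    D_mobile: float = 4.02e-4
    mobile_fraction: float = 0.83
    intensity: float = 1000.0        # prebleach per-pixel level
    noise_gaussian_sigma: float = 0.02
    noise_poisson_scale: float = 0.0
    seed: int = 0
    margin_px: int = 4               # background border around the cell

    def __post_init__(self) -> None:
        if min(self.cell_length, self.cell_width, self.pixel_size,
               self.frame_interval, self.bleach_width, self.intensity) <= 0:
            raise ParameterError("lengths, times and intensity must be positive")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ParameterError(
                f"bleach_depth must be in [0, 1], got {self.bleach_depth}"
            )
        if not 0.0 <= self.bleach_center <= 1.0:
            raise ParameterError("bleach_center is a fraction of cell length")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ParameterError(
                f"mobile_fraction must be in [0, 1], got {self.mobile_fraction}"
            )
        if self.D_mobile < 0 or self.noise_gaussian_sigma < 0 \
                or self.noise_poisson_scale < 0:
            raise ParameterError("D and noise levels must be non-negative")
        if self.n_frames < self.prebleach_frames + 2:
            raise ParameterError("n_frames must leave >= 2 post-bleach frames")

    @classmethod
    def cargo_like(cls, **overrides) -> "SimulationParams":
        """Highly mobile, liquid-like cargo-interior conditions."""
        return cls(**{"D_mobile": 4.02e-4, "mobile_fraction": 0.83, **overrides})

    @classmethod
    def shell_like(cls, **overrides) -> "SimulationParams":
        """Nearly static shell-protein conditions."""
        return cls(**{"D_mobile": 0.28e-4, "mobile_fraction": 0.06, **overrides})


@dataclass
class GroundTruth:
    """Generator truth serialized alongside every dataset."""

    params: dict
    profiles: np.ndarray | None = None   # noiseless axial profiles (T, X)
    schedule: list[tuple[str, int, float]] | None = None  # (channel, frame, position μm)
    extras: dict = field(default_factory=dict)

    def to_params_dict(self) -> dict:
        out = dict(self.params)
        out.update(self.extras)
        return out


# ---------------------------------------------------------------------------
# FRAP series
# ---------------------------------------------------------------------------

def frap_ground_truth_profiles(
    params: SimulationParams, engine: str = "fd"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless axial profiles (positions, profiles[T, X], timestamps).

    The structure fills the rod footprint, so the prebleach profile is
    uniform; the bleach multiplies it by (1 − depth) inside the line.  The
    post-bleach evolution uses the finite-difference engine (``"fd"``) or
    the independent cosine-series solution (``"analytic"``).
    """
    p = params
    n_ax = int(round(p.cell_length / p.pixel_size))
    n_rows = int(round(p.cell_width / p.pixel_size))
    positions = (np.arange(n_ax) + 0.5) * p.pixel_size
    pre = np.full(n_ax, p.intensity * n_rows)
    in_line = np.abs(positions - p.bleach_center * p.cell_length) <= p.bleach_width / 2
    if not in_line.any():
        raise ParameterError("bleach line narrower than one pixel")
    post = pre.copy()
    post[in_line] *= 1.0 - p.bleach_depth

    n_post = p.n_frames - p.prebleach_frames
    t_rel = np.arange(n_post) * p.frame_interval
    if engine == "fd":
        evolved = diffusion.simulate_recovery(
            pre, post, p.mobile_fraction, p.D_mobile, t_rel, p.pixel_size
        )
    elif engine == "analytic":
        immobile = (1.0 - p.mobile_fraction) * post
        mobile0 = p.mobile_fraction * post
        evolved = [
            diffusion.cosine_series_solution(mobile0, p.pixel_size, p.D_mobile, t)
            + immobile
            for t in t_rel
        ]
    else:
        raise ParameterError(f"unknown engine {engine!r}; use 'fd' or 'analytic'")
    profiles = np.vstack([np.tile(pre, (p.prebleach_frames, 1)), np.array(evolved)])
    timestamps = np.arange(p.n_frames) * p.frame_interval
    return positions, profiles, timestamps


def _render_rod_frames(
    profiles: np.ndarray, n_rows: int, margin: int
) -> np.ndarray:
    """Spread axial profiles uniformly across the rod cross-section."""
    n_frames, n_ax = profiles.shape
    frames = np.zeros((n_frames, n_rows + 2 * margin, n_ax + 2 * margin))
    per_px = profiles / n_rows
    frames[:, margin:margin + n_rows, margin:margin + n_ax] = per_px[:, None, :]
    return frames


def _apply_noise(
    frames: np.ndarray,
    gaussian_sigma_abs: float,
    poisson_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian detection noise, then optional Poisson shot noise."""
    out = frames.copy()
    if gaussian_sigma_abs > 0:
        out = out + rng.normal(0.0, gaussian_sigma_abs, size=out.shape)
    if poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0.0) * poisson_scale) / poisson_scale
    return np.maximum(out, 0.0)


def generate_frap_series(
    params: SimulationParams, engine: str = "fd"
) -> tuple[ImageSeries, GroundTruth]:
    """Simulate a line-bleach FRAP image series with known (D, M)."""
    p = params
    positions, profiles, timestamps = frap_ground_truth_profiles(p, engine)
    n_rows = int(round(p.cell_width / p.pixel_size))
    frames = _render_rod_frames(profiles, n_rows, p.margin_px)
    rng = substream_rng(p.seed, "frap_sim")
    noisy = _apply_noise(
        frames, p.noise_gaussian_sigma * p.intensity, p.noise_poisson_scale, rng
    )
    series = ImageSeries(
        frames=noisy,
        channel_label="frap",
        pixel_size=p.pixel_size,
        frame_interval=p.frame_interval,
        timestamps=timestamps,
    )
    truth = GroundTruth(params=asdict(p), profiles=profiles,
                        extras={"engine": engine})
    return series, truth


# ---------------------------------------------------------------------------
# colocalization pairs
# ---------------------------------------------------------------------------

def _gaussian_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    img = np.zeros(shape)
    if len(centers) == 0:
        return img
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    for r0, c0 in centers:
        img += amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2)
        )
    return img


def generate_coloc_pair(
    n_foci: int,
    overlap: float,
    params: SimulationParams | None = None,
    psf_sigma: float = 0.1,
    background: float = 200.0,
    amplitude: float = 1000.0,
) -> tuple[ImageSeries, ImageSeries, GroundTruth]:
    """Dual-channel image with a programmed focus-overlap fraction ρ.

    Channel-1 foci are placed uniformly inside the cell; ``round(ρ·n)``
    channel-2 foci share those centroids exactly and the rest are placed
    independently, kept at least 4 PSF widths away from every channel-1
    focus so ρ = 0 means disjoint by construction.
    """
    if n_foci < 1:
        raise ParameterError("n_foci must be >= 1")
    if not 0.0 <= overlap <= 1.0:
        raise ParameterError(f"overlap must be in [0, 1], got {overlap}")
    p = params or SimulationParams()
    rng = substream_rng(p.seed, "coloc_sim")
    n_ax = int(round(p.cell_length / p.pixel_size))
    n_rows = int(round(p.cell_width / p.pixel_size))
    m = p.margin_px
    shape = (n_rows + 2 * m, n_ax + 2 * m)
    sigma_px = psf_sigma / p.pixel_size
    pad = max(2.0 * sigma_px, 1.0)

    def draw(n: int, exclude: np.ndarray | None = None) -> np.ndarray:
        pts = []
        tries = 0
        while len(pts) < n:
            tries += 1
            if tries > 10000:
                raise ParameterError(
                    "cannot place non-overlapping foci; reduce n_foci or PSF"
                )
            r = rng.uniform(m + pad, m + n_rows - pad)
            c = rng.uniform(m + pad, m + n_ax - pad)
            if exclude is not None and len(exclude):
                d = np.hypot(exclude[:, 0] - r, exclude[:, 1] - c)
                if d.min() < 4.0 * sigma_px:
                    continue
            pts.append((r, c))
        return np.array(pts)

    centers1 = draw(n_foci)
    n_shared = int(round(overlap * n_foci))
    shared = centers1[:n_shared]
    indep = draw(n_foci - n_shared, exclude=centers1)
    centers2 = np.vstack([shared, indep]) if len(indep) else shared

    cell = np.zeros(shape, dtype=bool)
    cell[m:m + n_rows, m:m + n_ax] = True
    base = np.where(cell, background, 0.0)
    sigma_abs = p.noise_gaussian_sigma * background
    ch1 = _apply_noise(
        (base + _gaussian_spots(shape, centers1, sigma_px, amplitude))[None],
        sigma_abs, p.noise_poisson_scale, rng)[0]
    ch2 = _apply_noise(
        (base + _gaussian_spots(shape, centers2, sigma_px, amplitude))[None],
        sigma_abs, p.noise_poisson_scale, rng)[0]
    mk = lambda img, lbl: ImageSeries(
        frames=img[None], channel_label=lbl,
        pixel_size=p.pixel_size, frame_interval=p.frame_interval,
    )
    truth = GroundTruth(
        params=asdict(p),
        extras={
            "n_foci": n_foci, "overlap": overlap,
            "centers1": centers1.tolist(), "centers2": centers2.tolist(),
            "cell_area_px": int(cell.sum()),
        },
    )
    return mk(ch1, "channel1"), mk(ch2, "channel2"), truth


# ---------------------------------------------------------------------------
# birth-event time-lapses
# ---------------------------------------------------------------------------

def generate_birth_timelapse(
    schedule: dict[str, tuple[int, float]],
    params: SimulationParams | None = None,
    n_frames: int = 20,
    psf_sigma: float = 0.1,
    background: float = 200.0,
    amplitude: float = 300.0,
) -> tuple[dict[str, ImageSeries], GroundTruth]:
    """Two-channel time-lapse with scheduled focus appearances.

    ``schedule`` maps a channel name (e.g. ``"shell"``, ``"cargo"``) to a
    (frame, axial_fraction) pair.  Each channel shows cytosolic background
    inside the cell plus one focus that ramps from 0 to full intensity over
    two frames starting at its scheduled frame, at the scheduled axial
    position.
    """
    p = params or SimulationParams()
    for ch, (f, frac) in schedule.items():
        if not 0 <= f < n_frames:
            raise ParameterError(
                f"{ch} scheduled at frame {f}, outside 0..{n_frames - 1}"
            )
        if not 0.0 <= frac <= 1.0:
            raise ParameterError(f"{ch} axial fraction {frac} outside [0, 1]")
    rng = substream_rng(p.seed, "events_sim")
    n_ax = int(round(p.cell_length / p.pixel_size))
    n_rows = int(round(p.cell_width / p.pixel_size))
    m = p.margin_px
    shape = (n_rows + 2 * m, n_ax + 2 * m)
    sigma_px = psf_sigma / p.pixel_size
    cell = np.zeros(shape, dtype=bool)
    cell[m:m + n_rows, m:m + n_ax] = True
    base = np.where(cell, background, 0.0)
    sigma_abs = p.noise_gaussian_sigma * background

    out: dict[str, ImageSeries] = {}
    truth_schedule: list[tuple[str, int, float]] = []
    for ch, (f0, frac) in schedule.items():
        r0 = m + (n_rows - 1) / 2.0
        c0 = m + frac * (n_ax - 1)
        spot = _gaussian_spots(shape, np.array([[r0, c0]]), sigma_px, amplitude)
        frames = np.empty((n_frames,) + shape)
        for t in range(n_frames):
            ramp = 0.0 if t < f0 else (0.5 if t == f0 else 1.0)
            frames[t] = base + ramp * spot
        noisy = _apply_noise(frames, sigma_abs, p.noise_poisson_scale, rng)
        out[ch] = ImageSeries(
            frames=noisy, channel_label=ch,
            pixel_size=p.pixel_size, frame_interval=p.frame_interval,
        )
        truth_schedule.append((ch, f0, (frac * (n_ax - 1) + 0.5) * p.pixel_size))
    truth = GroundTruth(params=asdict(p), schedule=truth_schedule,
                        extras={"n_frames": n_frames})
    return out, truth


def sample_biased_folded_positions(
    n: int, p_polar: float = 0.704, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw folded axial positions with P(position <= 0.25) = ``p_polar``.

    Emulates the observed polar bias of initial assembly sites: with
    probability ``p_polar`` uniform in the polar quarter [0, 0.25],
    otherwise uniform in (0.25, 0.5].
    """
    if not 0.0 <= p_polar <= 1.0:
        raise ParameterError("p_polar must be in [0, 1]")
    rng = rng or np.random.default_rng()
    polar = rng.random(n) < p_polar
    u = rng.random(n)
    return np.where(polar, 0.25 * u, 0.25 + 0.25 * u)
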