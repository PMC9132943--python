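"""Dual-channel Pearson colocalization within a whole-cell mask.

Colocalization of shell and cargo fluorescence is scored as the pixel-wise
product-moment correlation R between the two channels over all pixels of
the cell mask, together with the scatter of paired intensities.  R near 1
indicates reliable colocalization, values near zero an uncorrelated
distribution.  No Costes thresholding or puncta ROIs: the correlation is
deliberately whole-cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import AnalysisError, InputError, SegmentationError


@dataclass
class ColocResult:
    """Pearson R, pixel count, and the paired-intensity scatter."""

    pearson_r: float
    n_pixels: int
    scatter: np.ndarray  # (n_pixels, 2): channel-1, channel-2 in row-major order

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise InputError(f"|R| must be <= 1, got {self.pearson_r}")
        if self.n_pixels != len(self.scatter) or self.n_pixels < 2:
            raise InputError("scatter length must equal n_pixels >= 2")


def cell_mask(reference_frame: np.ndarray) -> np.ndarray:
    """Binary cell mask from a reference image.

    Otsu threshold on the reference (typically the sum of both channels or
    the mean prebleach frame), keeping the largest connected component with
    holes filled.  Bright puncta occupying a small area would otherwise
    pull the Otsu split between cytosol and focus instead of between
    background and cell, so the threshold is computed on a copy clipped at
    the 90th percentile (a no-op for spot-free images).  When several cells
    are present only the largest is analyzed — a documented limitation, not
    a feature.
    """
    ref = np.asarray(reference_frame, dtype=float)
    if ref.ndim != 2:
        raise InputError(f"reference frame must be 2D, got shape {ref.shape}")
    if np.ptp(ref) == 0:
        raise SegmentationError("constant reference image: cannot segment")
    clipped = np.minimum(ref, np.percentile(ref, 90))
    if np.ptp(clipped) == 0:  # cell fills (nearly) the whole frame
        clipped = ref
    mask = clipped > threshold_otsu(clipped)
    if not mask.any():
        raise SegmentationError("Otsu threshold produced an empty mask")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def pearson_r(
    channel1: np.ndarray,
    channel2: np.ndarray,
    mask: np.ndarray,
    background_offset: float = 0.0,
) -> ColocResult:
    """Pearson correlation of two channels over the masked pixels.

    Scatter pairs are returned in row-major pixel order (channel-1 value
    first, matching the convention of plotting one fluorophore per axis).
    An optional constant ``background_offset`` is subtracted from both
    channels before correlating; R itself is invariant to any affine
    intensity rescaling.
    """
    c1 = np.asarray(channel1, dtype=float)
    c2 = np.asarray(channel2, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if c1.shape != c2.shape or c1.shape != m.shape:
        raise InputError(
            f"shape mismatch: {c1.shape} vs {c2.shape} vs mask {m.shape}"
        )
    x = c1[m] - background_offset
    y = c2[m] - background_offset
    if x.size < 2:
        raise InputError(f"need >= 2 masked pixels, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance in a channel: correlation undefined")
    xd = x - x.mean()
    yd = y - y.mean()
    r = float((xd @ yd) / np.sqrt((xd @ xd) * (yd @ yd)))
    return ColocResult(
        pearson_r=float(np.clip(r, -1.0, 1.0)),
        n_pixels=int(x.size),
        scatter=np.column_stack([x, y]),
    )
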