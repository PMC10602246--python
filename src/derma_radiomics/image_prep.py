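"""Channel splitting, circular ROI masking and grey-level quantization.

A capture is split into its red, green and blue channels; each channel
is restricted to a centred circular region of interest (default radius
300 px, which also discards the vignetted periphery of UV captures) and
quantized to ``Ng`` grey levels (default 64) on the fixed 0-255 range,
so the intensity-to-level map is identical for every image and baseline
ratios across timepoints stay comparable.

Conventions: pixel indices are row-major and 0-based; quantized levels
are 1-based (1..Ng) as in the co-occurrence literature.  The image
centre is ((H-1)/2, (W-1)/2) and the ROI boundary is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelGrid",
    "MaskedLevelGrid",
    "split_channels",
    "circular_mask",
    "crop_circular_roi",
    "quantize_levels",
    "prepare_channel",
]

CHANNEL_NAMES = ("red", "green", "blue")


@dataclass(frozen=True)
class ChannelGrid:
    """One 8-bit colour channel of a capture."""

    values: np.ndarray  # H x W uint8
    channel: str


@dataclass(frozen=True)
class MaskedLevelGrid:
    """Quantized levels (1..Ng) under a boolean ROI mask.

    Entries outside the mask are set to 0 as a sentinel and must never
    enter any co-occurrence count.
    """

    levels: np.ndarray  # H x W int, 0 outside the mask
    mask: np.ndarray  # H x W bool
    n_levels: int


def split_channels(pixels: np.ndarray) -> list[ChannelGrid]:
    """Split an H x W x 3 RGB array into (red, green, blue) grids."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {pixels.shape}")
    return [ChannelGrid(values=pixels[:, :, c].copy(), channel=name)
            for c, name in enumerate(CHANNEL_NAMES)]


def circular_mask(shape: tuple[int, int], radius: float) -> np.ndarray:
    """Boolean disc of the given radius centred at ((H-1)/2, (W-1)/2).

    A pixel belongs to the ROI iff its Euclidean distance from the
    centre is <= radius (inclusive boundary).
    """
    h, w = shape
    if 2 * radius > min(h, w):
        raise ValueError(f"ROI radius {radius} too large for a {h} x {w} image")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy = (np.arange(h) - cy) ** 2
    xx = (np.arange(w) - cx) ** 2
    return yy[:, None] + xx[None, :] <= radius**2


def crop_circular_roi(channel: ChannelGrid | np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a channel to the centred circular ROI.

    Returns ``(values, mask)`` cropped to the ROI bounding box; values
    outside the mask are retained in the array but flagged false in the
    mask and excluded from all later counting.
    """
    values = channel.values if isinstance(channel, ChannelGrid) else np.asarray(channel)
    mask = circular_mask(values.shape, radius)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return values[sl], mask[sl]


def quantize_levels(values: np.ndarray, mask: np.ndarray, n_levels: int = 64) -> MaskedLevelGrid:
    """Quantize 8-bit intensities to 1..Ng on the fixed [0, 255] range.

    level = floor(v * Ng / 256) + 1, so for Ng = 64 each level spans 4
    consecutive intensities.  The map does not depend on the image
    content (no per-image min-max), keeping longitudinal ratios on a
    common scale.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    values = np.asarray(values)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    levels = (values.astype(np.int64) * n_levels) // 256 + 1
    levels[~mask] = 0
    return MaskedLevelGrid(levels=levels, mask=mask, n_levels=n_levels)


def prepare_channel(channel: ChannelGrid | np.ndarray, radius: float, n_levels: int = 64) -> MaskedLevelGrid:
    """ROI-crop then quantize one channel (the standard preparation)."""
    values, mask = crop_circular_roi(channel, radius)
    return quantize_levels(values, mask, n_levels)
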