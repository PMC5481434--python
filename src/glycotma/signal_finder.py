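"""Parameter-free per-image signal detection.

Each channel image is processed independently: the background level is
estimated as the modal intensity over tissue pixels, the detection
threshold is ``mode + 3 * MAD`` (median absolute deviation of tissue
intensities), and the raw mask is cleaned by dropping connected components
smaller than 4 pixels (8-connectivity) and filling single-pixel holes.
No parameters are exposed at call time; everything adapts per image.

The detector is intensity-shift invariant (mode and MAD are equivariant /
invariant under a constant offset) and monotone in planted-region contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.morphology import closing, disk, remove_small_holes, remove_small_objects

__all__ = [
    "TissueMask",
    "SignalMap",
    "compute_tissue_mask",
    "find_signal",
    "percent_signal",
    "write_percent_table",
]

_MIN_COMPONENT_PX = 4
_HOLE_AREA_PX = 1
_TISSUE_REL_THRESHOLD = 0.05
_TISSUE_CLOSING_RADIUS = 2


@dataclass(frozen=True)
class TissueMask:
    """Binary mask of tissue-containing pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.dtype != bool or self.mask.ndim != 2:
            raise ValueError("tissue mask must be a 2-D boolean array")

    @property
    def tissue_pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class SignalMap:
    """Binary signal mask restricted to tissue, with its percent-of-tissue."""

    mask: np.ndarray
    percent_signal: float
    empty_tissue: bool = False
    channel: str | None = None

    @property
    def signal_pixel_count(self) -> int:
        return int(self.mask.sum())


def compute_tissue_mask(stack: Sequence[np.ndarray]) -> TissueMask:
    """Tissue = morphologically closed union of per-channel low-threshold foregrounds.

    Each channel contributes pixels brighter than 5% of its own maximum, so a
    channel that is entirely dark contributes nothing and leaves the mask
    unchanged.
    """

    stack = [np.asarray(img) for img in stack]
    if not stack:
        raise ValueError("need at least one channel image")
    shape = stack[0].shape
    if any(img.shape != shape for img in stack):
        raise ValueError("channel images have mismatched shapes")
    union = np.zeros(shape, dtype=bool)
    for img in stack:
        tau = 0.0 if img.size == 0 else _TISSUE_REL_THRESHOLD * float(img.max())
        union |= img > tau
    closed = closing(union, disk(_TISSUE_CLOSING_RADIUS))
    return TissueMask(mask=closed)


def _modal_intensity(values: np.ndarray) -> float:
    """Mode of an intensity sample via histogram (exact for integer images)."""

    if np.issubdtype(values.dtype, np.integer):
        lo = int(values.min())
        counts = np.bincount((values.astype(np.int64) - lo))
        return float(np.argmax(counts) + lo)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return lo
    counts, edges = np.histogram(values, bins=256, range=(lo, hi))
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2.0)


def find_signal(channel: np.ndarray, tissue: TissueMask, channel_name: str | None = None) -> SignalMap:
    """Detect signal pixels in one channel image within the tissue mask.

    Fully automatic: threshold = modal tissue intensity + 3 * MAD, followed
    by small-component removal and 1-px hole filling.  An empty tissue mask
    yields an empty, flagged map with percent 0.
    """

    channel = np.asarray(channel)
    if channel.shape != tissue.shape:
        raise ValueError("channel and tissue mask shapes differ")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel intensities must be finite")
    if tissue.tissue_pixel_count == 0:
        return SignalMap(
            mask=np.zeros(tissue.shape, dtype=bool),
            percent_signal=0.0,
            empty_tissue=True,
            channel=channel_name,
        )

    tvals = channel[tissue.mask]
    mode = _modal_intensity(tvals)
    med = float(np.median(tvals))
    mad = float(np.median(np.abs(tvals.astype(np.float64) - med)))
    threshold = mode + 3.0 * mad

    raw = (channel > threshold) & tissue.mask
    # drop components of < _MIN_COMPONENT_PX pixels (max_size is inclusive)
    cleaned = remove_small_objects(raw, max_size=_MIN_COMPONENT_PX - 1, connectivity=2)
    cleaned = remove_small_holes(cleaned, max_size=_HOLE_AREA_PX)
    cleaned &= tissue.mask
    pct = 100.0 * cleaned.sum() / tissue.tissue_pixel_count
    return SignalMap(mask=cleaned, percent_signal=float(pct), channel=channel_name)


def percent_signal(signal: SignalMap, tissue: TissueMask) -> float:
    """Percent of tissue pixels carrying signal (0 when tissue is empty)."""

    if signal.mask.shape != tissue.shape:
        raise ValueError("signal and tissue shapes differ")
    if np.any(signal.mask & ~tissue.mask):
        raise ValueError("signal mask is not contained in the tissue mask")
    n_tissue = tissue.tissue_pixel_count
    if n_tissue == 0:
        return 0.0
    return 100.0 * signal.signal_pixel_count / n_tissue


def write_percent_table(rows: Sequence[dict], path: str | Path) -> pd.DataFrame:
    """Write the per-tile percent table (core_id, tile_id, round, channel, percent_signal)."""

    table = pd.DataFrame(rows, columns=["core_id", "tile_id", "round", "channel", "percent_signal"])
    table.to_csv(path, index=False)
    return table
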