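"""Shared in-memory containers for images, label maps and decay data.

All image-like containers share a single pixel-grid convention: arrays are
indexed ``[row, col]``; physical angles are expressed in degrees in
``[-90, 90)`` measured counter-clockwise from the image x-axis (columns),
with y pointing up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CHANNEL_TAGS = ("NADH", "FAD", "2NBDG", "vimentin", "DRAQ5", "reference", "other")


@dataclass
class ChannelImage:
    """A single-channel intensity image with a channel tag.

    Parameters
    ----------
    pixels : 2D array of non-negative intensities.
    channel : one of :data:`CHANNEL_TAGS`.
    normalized : whether the image has been divided by a reference-dye mean.
    pixel_size_um : physical pixel size in micrometres.
    """

    pixels: np.ndarray
    channel: str = "other"
    normalized: bool = False
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be non-negative")
        if self.channel not in CHANNEL_TAGS:
            raise ValueError(
                f"unknown channel {self.channel!r}; expected one of {CHANNEL_TAGS}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMap:
    """Integer-labelled segmentation sharing the pixel grid with channel images.

    ``0`` is background; positive labels identify objects.  For paired
    nucleus/cell maps the same id refers to the same cell.
    """

    labels: np.ndarray
    kind: str = "cell"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.kind not in ("nuclei", "cell", "cytoplasm"):
            raise ValueError("kind must be 'nuclei', 'cell' or 'cytoplasm'")

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class DecayHistogram:
    """Photon counts per time bin for one pixel or pooled region.

    The acquisition period is divided into ``n_bins`` equal bins; a count in
    bin *j* is the number of photons with arrival time in
    ``[j*dt, (j+1)*dt)``, ``dt = period_ns / n_bins``.
    """

    counts: np.ndarray
    period_ns: float = 50.0
    origin: Optional[object] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("counts must be a 1D array with at least 2 bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.period_ns <= 0:
            raise ValueError("period_ns must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_centers_ns(self) -> np.ndarray:
        dt = self.period_ns / self.n_bins
        return (np.arange(self.n_bins) + 0.5) * dt

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())


@dataclass
class FLIMImage:
    """Per-pixel decay histograms on a shared grid: shape (H, W, n_bins)."""

    counts: np.ndarray
    period_ns: float = 50.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (H, W, n_bins)")
        if self.period_ns <= 0:
            raise ValueError("period_ns must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[2])

    @property
    def intensity(self) -> np.ndarray:
        """Total photons per pixel."""
        return self.counts.sum(axis=2)

    def pooled(self, mask: np.ndarray, origin: Optional[object] = None) -> DecayHistogram:
        """Sum histograms over a boolean pixel mask into one histogram."""
        mask = np.asarray(mask, bool)
        if mask.shape != self.shape:
            raise ValueError("mask shape does not match image grid")
        return DecayHistogram(
            counts=self.counts[mask].sum(axis=0),
            period_ns=self.period_ns,
            origin=origin,
        )
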