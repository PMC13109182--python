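"""Shared domain types for dual-channel nuclear image analysis.

The coordinate convention throughout the package is 0-based ``(row, col)``
indexing with pixel centers at integer coordinates; masks, correlation lags
and centroids all follow it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class ChannelRole(str, Enum):
    """Semantic role of an image channel."""

    DAMAGE = "damage"
    DNA = "dna"


@dataclass
class ChannelImage:
    """A single-channel 2D intensity image with physical pixel size.

    Parameters
    ----------
    pixels
        2D grid of nonnegative intensities (arbitrary units). Stored as
        ``float64``.
    pixel_size_nm
        Physical pixel size in nanometres (confocal default 45 nm).
    role
        Which signal the channel carries: ``damage`` (e.g. a DSB marker)
        or ``dna`` (counterstain).

    Notes
    -----
    Images smaller than ~32x32 are accepted by the type (tiny grids are
    useful for density arithmetic) but are rejected by the correlation
    estimator, which needs enough in-region pixel pairs per lag.
    """

    pixels: np.ndarray
    pixel_size_nm: float = 45.0
    role: ChannelRole = ChannelRole.DNA

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be >= 0")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel values must be finite")
        self.pixel_size_nm = float(self.pixel_size_nm)
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        self.role = ChannelRole(self.role)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Return a copy carrying new pixel data but the same metadata."""
        return ChannelImage(pixels, pixel_size_nm=self.pixel_size_nm, role=self.role)


@dataclass
class CountMask:
    """Integer-labeled nucleus segmentation.

    ``labels`` holds 0 for background and 1..n_objects for nuclei; each
    label occupies a nonempty 8-connected region and regions are disjoint
    by construction.
    """

    labels: np.ndarray
    n_objects: int = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        present = np.unique(self.labels)
        present = present[present > 0]
        n = int(present.size)
        if n and not np.array_equal(present, np.arange(1, n + 1)):
            raise ValueError("labels must be consecutive 1..n_objects")
        self.n_objects = n

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of one nucleus."""
        if not 1 <= label <= self.n_objects:
            raise KeyError(f"label {label} not in 1..{self.n_objects}")
        return self.labels == label

    def iter_regions(self):
        """Yield ``(label, boolean_mask)`` for each nucleus in label order."""
        for lab in range(1, self.n_objects + 1):
            yield lab, self.labels == lab


@dataclass
class BinaryMask:
    """A plain boolean mask sharing the shape of its source image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]
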