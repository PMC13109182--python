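"""Per-nucleus DNA density: normalized counterstain intensity averaged over
damage regions.

For each nucleus the DNA channel is divided by its in-nucleus maximum, which
removes cell-to-cell intensity variation (cell-cycle stage, staining
efficiency, field inhomogeneity); the density is then the mean of the
normalized intensity over the intersection of the nucleus with the damage
mask. High values indicate damage sitting in compact (bright-counterstain)
chromatin, low values in open chromatin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import BinaryMask, ChannelImage

NO_FOCI = "no foci"


@dataclass
class NormalizedDNAImage:
    """DNA intensity normalized to the in-nucleus maximum.

    ``values`` is NaN outside the nucleus region; inside, values lie in
    [0, 1] and attain 1 at the normalizing pixel(s).
    """

    values: np.ndarray
    nucleus_label: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def region(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class DensityResult:
    """Mean normalized DNA intensity over the damage ROI of one nucleus.

    ``dna_density`` is NaN (undefined) iff the ROI is empty, in which case
    ``reason`` is set and the cell is excluded from group statistics.
    """

    cell_id: int
    dna_density: float
    roi_area_px: int
    reason: str = ""

    @property
    def defined(self) -> bool:
        return self.roi_area_px > 0


def normalize_dna(
    dna_bg_subtracted: ChannelImage | np.ndarray,
    nucleus_region: np.ndarray,
    nucleus_label: int = 0,
    max_percentile: float | None = None,
) -> NormalizedDNAImage:
    """Divide the in-nucleus DNA intensity by its in-nucleus maximum.

    Parameters
    ----------
    dna_bg_subtracted
        Background-subtracted DNA-channel image.
    nucleus_region
        Boolean mask of one nucleus.
    max_percentile
        If given, normalize by this percentile of the in-region intensities
        instead of the strict maximum (robust to hot pixels); values are
        then clipped to 1. Default is the strict maximum.
    """
    pixels = dna_bg_subtracted.pixels if isinstance(dna_bg_subtracted, ChannelImage) else np.asarray(dna_bg_subtracted, dtype=np.float64)
    region = np.asarray(nucleus_region, dtype=bool)
    if pixels.shape != region.shape:
        raise ValueError("image and nucleus region shapes differ")
    if not region.any():
        raise ValueError("empty nucleus region")
    in_region = pixels[region]
    i_max = (
        float(np.percentile(in_region, max_percentile))
        if max_percentile is not None
        else float(in_region.max())
    )
    if i_max <= 0:
        raise ValueError("empty nucleus signal")
    values = np.full(pixels.shape, np.nan)
    values[region] = np.minimum(in_region / i_max, 1.0)
    return NormalizedDNAImage(values=values, nucleus_label=nucleus_label)


def dna_density(
    norm: NormalizedDNAImage,
    nucleus_region: np.ndarray,
    damage: BinaryMask,
) -> DensityResult:
    """Average the normalized DNA intensity over nucleus ∩ damage mask.

    An empty ROI (no damage pixels in this nucleus) yields an undefined
    density flagged ``"no foci"`` rather than an error.
    """
    region = np.asarray(nucleus_region, dtype=bool)
    if norm.shape != region.shape or damage.shape != region.shape:
        raise ValueError("shape mismatch between normalized image, region and mask")
    roi = region & damage.mask
    area = int(roi.sum())
    if area == 0:
        return DensityResult(
            cell_id=norm.nucleus_label, dna_density=math.nan, roi_area_px=0, reason=NO_FOCI
        )
    value = float(np.nanmean(norm.values[roi]))
    return DensityResult(cell_id=norm.nucleus_label, dna_density=value, roi_area_px=area)
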