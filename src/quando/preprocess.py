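"""Image pre-processing: nucleus count masks, background subtraction and
damage-region binary masks.

These operators mirror the classic interactive workflow (automatic
threshold -> particle analysis -> rolling-ball background subtraction ->
fixed-threshold damage masks) as deterministic, scriptable functions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

from .types import BinaryMask, ChannelImage, ChannelRole, CountMask

# 8-connectivity structuring element used for all component labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)


def isodata_threshold(image: ChannelImage | np.ndarray, n_bins: int = 256) -> float:
    """Classic isodata (iterative intermeans) threshold on an intensity histogram.

    The returned threshold ``t`` satisfies the isodata fixed point
    ``t = (mean(pixels <= t) + mean(pixels > t)) / 2`` within one bin width
    of the ``n_bins`` histogram spanning the intensity range.

    Parameters
    ----------
    image
        Input image; any 2D nonnegative grid.
    n_bins
        Number of histogram bins (256 matches 8-bit practice).

    Returns
    -------
    float
        Threshold in the intensity units of the input.

    Raises
    ------
    ValueError
        If the image is constant ("degenerate histogram") or empty.
    """
    pixels = _pixels(image)
    if pixels.size == 0:
        raise ValueError("empty image")
    lo, hi = float(pixels.min()), float(pixels.max())
    if lo == hi:
        raise ValueError("degenerate histogram: image is constant")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    counts, edges = np.histogram(pixels, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]

    # iterate t_{k+1} = (mu_low + mu_high)/2 on the binned data
    csum = np.cumsum(counts)
    cmass = np.cumsum(counts * centers)
    total_n, total_m = csum[-1], cmass[-1]

    t = float(pixels.mean())
    for _ in range(1000):
        k = int(np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1))
        n_low, m_low = csum[k], cmass[k]
        if n_low == 0 or n_low == total_n:
            # walk inward until both classes are populated
            nz = np.nonzero(counts)[0]
            k = int(np.clip(k, nz[0], nz[-1] - 1))
            n_low, m_low = csum[k], cmass[k]
        mu_low = m_low / n_low
        mu_high = (total_m - m_low) / (total_n - n_low)
        t_next = 0.5 * (mu_low + mu_high)
        if abs(t_next - t) < 0.5 * bin_width:
            t = t_next
            break
        t = t_next
    return float(t)


def rolling_ball_subtract(image: ChannelImage, radius_px: int = 10) -> ChannelImage:
    """Subtract the rolling-ball background from an image.

    The background is the upper envelope of a ball of radius ``radius_px``
    rolled under the intensity surface; the result is clipped at zero.
    Features much smaller than the radius are preserved, plateaus much
    larger than the radius are removed.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    pixels = image.pixels
    if radius_px >= min(pixels.shape):
        raise ValueError("radius too large for image dimensions")
    background = rolling_ball(pixels, radius=radius_px)
    # rolling_ball guarantees background <= image up to float round-off
    out = np.clip(pixels - background, 0.0, None)
    return image.with_pixels(out)


def damage_mask(damage_image: ChannelImage, threshold: float) -> BinaryMask:
    """Binary mask of damage regions: background-subtracted intensity strictly
    above a user-chosen threshold.

    The threshold is a per-experiment constant supplied by the caller (it is
    held fixed across images acquired in the same experiment); an all-false
    mask is a valid result.
    """
    if damage_image.role is not ChannelRole.DAMAGE:
        raise ValueError("damage_mask expects a channel with role='damage'")
    return BinaryMask(damage_image.pixels > threshold)


def segment_nuclei(
    dna_image: ChannelImage,
    min_area_px: int = 5000,
    exclude_border: bool = True,
    max_area_px: int | None = None,
    min_solidity: float | None = None,
    n_bins: int = 256,
) -> CountMask:
    """Segment nuclei from the DNA channel into a count mask.

    Binarizes at the isodata threshold, fills enclosed holes, labels
    8-connected components, then discards components smaller than
    ``min_area_px`` (and optionally: larger than ``max_area_px``, with
    solidity below ``min_solidity``, or touching the image border).
    Surviving objects are renumbered 1..n in raster order of their first
    pixel. Zero surviving objects is a valid (empty) CountMask.
    """
    if dna_image.role is not ChannelRole.DNA:
        raise ValueError("segment_nuclei expects a channel with role='dna'")
    pixels = dna_image.pixels
    t = isodata_threshold(pixels, n_bins=n_bins)
    binary = ndimage.binary_fill_holes(pixels > t)
    labeled, n = ndimage.label(binary, structure=_STRUCT8)

    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    areas = np.bincount(labeled.ravel(), minlength=n + 1)
    keep &= areas >= min_area_px
    if max_area_px is not None:
        keep &= areas <= max_area_px
    if exclude_border and n:
        border_labels = np.unique(
            np.concatenate(
                [labeled[0, :], labeled[-1, :], labeled[:, 0], labeled[:, -1]]
            )
        )
        keep[border_labels] = False
    if min_solidity is not None and n:
        for lab in range(1, n + 1):
            if keep[lab] and _solidity(labeled == lab) < min_solidity:
                keep[lab] = False

    filtered = np.where(keep[labeled], labeled, 0)
    return CountMask(_renumber_raster(filtered))


def count_foci(
    damage: BinaryMask, nucleus_region: np.ndarray, min_focus_px: int = 1
) -> int:
    """Count 8-connected damage components of area >= ``min_focus_px`` inside
    one nucleus region.

    Additive over disjoint nucleus regions: a focus is attributed to the
    region it intersects, and foci outside the region are ignored.
    """
    region = np.asarray(nucleus_region, dtype=bool)
    if damage.shape != region.shape:
        raise ValueError("damage mask and nucleus region shapes differ")
    inter = damage.mask & region
    labeled, n = ndimage.label(inter, structure=_STRUCT8)
    if n == 0:
        return 0
    areas = np.bincount(labeled.ravel(), minlength=n + 1)[1:]
    return int(np.count_nonzero(areas >= min_focus_px))


def _pixels(image: ChannelImage | np.ndarray) -> np.ndarray:
    if isinstance(image, ChannelImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def _solidity(region: np.ndarray) -> float:
    from skimage.morphology import convex_hull_image

    hull = convex_hull_image(region)
    hull_area = int(hull.sum())
    return float(region.sum()) / hull_area if hull_area else 0.0


def _renumber_raster(labeled: np.ndarray) -> np.ndarray:
    """Renumber nonzero labels 1..n by raster order of each label's first pixel."""
    flat = labeled.ravel()
    nonzero = np.flatnonzero(flat)
    if nonzero.size == 0:
        return np.zeros_like(labeled, dtype=np.int32)
    old = flat[nonzero]
    # first occurrence index of each label value, sorted by position
    _, first_idx = np.unique(old, return_index=True)
    order = np.argsort(nonzero[first_idx])
    old_sorted = np.unique(old)[order]
    mapping = np.zeros(int(labeled.max()) + 1, dtype=np.int32)
    mapping[old_sorted] = np.arange(1, old_sorted.size + 1, dtype=np.int32)
    return mapping[labeled]
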