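"""TIFF input/output for channel images and masks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .types import BinaryMask, ChannelImage, ChannelRole, CountMask


def read_channel_pair(
    path1: str | Path,
    path2: str | Path | None = None,
    channel_order: tuple[str, str] = ("damage", "dna"),
    pixel_size_nm: float = 45.0,
) -> tuple[ChannelImage, ChannelImage]:
    """Read a (damage, dna) channel pair.

    Either two single-channel TIFFs, or one multi-channel TIFF (``path2``
    omitted) whose channel axis is the smallest dimension. ``channel_order``
    names the role of the first and second channel.
    """
    roles = tuple(ChannelRole(r) for r in channel_order)
    if set(roles) != {ChannelRole.DAMAGE, ChannelRole.DNA}:
        raise ValueError("channel_order must name both 'damage' and 'dna'")
    if path2 is not None:
        planes = [_read_plane(path1), _read_plane(path2)]
    else:
        arr = np.asarray(tifffile.imread(str(path1)))
        if arr.ndim != 3 or 2 not in arr.shape:
            raise ValueError("expected a 2-channel TIFF when a single path is given")
        ch_axis = int(np.argmin(arr.shape))
        arr = np.moveaxis(arr, ch_axis, 0)
        planes = [arr[0], arr[1]]
    images = {
        role: ChannelImage(plane.astype(np.float64), pixel_size_nm=pixel_size_nm, role=role)
        for role, plane in zip(roles, planes)
    }
    return images[ChannelRole.DAMAGE], images[ChannelRole.DNA]


def write_channel(path: str | Path, image: ChannelImage) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def write_count_mask(path: str | Path, mask: CountMask) -> None:
    """Save a count mask as 16-bit TIFF (0 = background)."""
    if mask.n_objects > np.iinfo(np.uint16).max:
        raise ValueError("too many objects for 16-bit mask")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def write_binary_mask(path: str | Path, mask: BinaryMask) -> None:
    """Save a binary mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))


def _read_plane(path: str | Path) -> np.ndarray:
    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D TIFF, got shape {arr.shape}")
    return arr
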