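"""Synthetic dual-channel nuclei with known ground truth.

A scene is an elliptical nucleus containing a smooth euchromatin baseline
plus bright Gaussian heterochromatin blobs (DNA channel), and compact
Gaussian damage foci (damage channel) whose probability of sitting on a
blob center is the tunable ground truth ``p_het``. Both channels are
blurred with a Gaussian PSF, scaled to photons and Poisson-sampled, so the
whole analysis pipeline can be exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .types import BinaryMask, ChannelImage, ChannelRole

_MAX_TRIES = 2000


@dataclass
class SceneParams:
    """Ground-truth scene description for one nucleus.

    Notes
    -----
    * ``placement='preferential'``: each focus lands on a random blob center
      with probability ``p_het`` and otherwise at a uniform in-nucleus spot
      at least ``off_blob_margin_sigma * blob_sigma_px`` away from every
      blob center, so ``p_het`` cleanly separates the two regimes.
    * ``placement='independent'``: foci are uniform in the nucleus
      regardless of blobs (placement probability proportional to area);
      the truth records on-blob membership by proximity.
    * Blobs are kept >= 3 blob sigmas apart and off-blob foci >= 4 focus
      sigmas from other foci (bounded retries). On-blob foci sit at blob
      centers, so raise ``min_blob_sep_px`` when exact focus counting
      matters.
    * Identical params + seed give bit-identical images.
    """

    nucleus_axes_px: tuple[float, float] = (48.0, 38.0)
    n_blobs: int = 13
    blob_sigma_px: float = 3.0
    blob_contrast: float = 5.0
    n_foci: int = 8
    focus_sigma_px: float = 4.0
    focus_amplitude: float = 3.0
    p_het: float = 0.5
    placement: Literal["preferential", "independent"] = "preferential"
    psf_sigma_px: float = 2.0
    photons_per_unit: float = 1000.0
    background_offset: float = 2.0
    seed: int = 0
    off_blob_margin_sigma: float = 3.0
    # None -> 3*blob_sigma and 4*focus_sigma. On-blob foci sit at blob
    # centers, so their pairwise distance is governed by the blob
    # separation; raise min_blob_sep_px when exact focus counting matters.
    min_blob_sep_px: float | None = None
    min_focus_sep_px: float | None = None
    pixel_size_nm: float = 45.0

    def __post_init__(self) -> None:
        a, b = self.nucleus_axes_px
        if a <= 0 or b <= 0:
            raise ValueError("nucleus semi-axes must be > 0")
        if self.n_blobs < 0 or self.n_foci < 0:
            raise ValueError("counts must be >= 0")
        if self.blob_sigma_px <= 0 or self.focus_sigma_px <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("sigmas must be > 0")
        if self.blob_contrast <= 1:
            raise ValueError("blob_contrast must be > 1")
        if self.focus_amplitude <= 0:
            raise ValueError("focus_amplitude must be > 0")
        if not 0.0 <= self.p_het <= 1.0:
            raise ValueError("p_het must be in [0, 1]")
        if self.placement not in ("preferential", "independent"):
            raise ValueError("placement must be 'preferential' or 'independent'")
        if self.photons_per_unit <= 0:
            raise ValueError("photons_per_unit must be > 0")
        if self.background_offset < 0:
            raise ValueError("background_offset must be >= 0")
        if self.min_blob_sep_px is not None and self.min_blob_sep_px <= 0:
            raise ValueError("min_blob_sep_px must be > 0")
        if self.min_focus_sep_px is not None and self.min_focus_sep_px <= 0:
            raise ValueError("min_focus_sep_px must be > 0")

    @property
    def extent_px(self) -> int:
        """Side of the square tile that comfortably holds one nucleus."""
        margin = 4.0 * self.psf_sigma_px + 4.0
        return int(np.ceil(2.0 * (max(self.nucleus_axes_px) + margin)))


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated nucleus (field coordinates)."""

    blob_centers: np.ndarray  # (n_blobs, 2) row/col
    foci_centers: np.ndarray  # (n_foci, 2) row/col
    foci_on_blob: np.ndarray  # (n_foci,) bool
    p_het: float
    nucleus_mask_true: BinaryMask
    nucleus_center: tuple[float, float] = (0.0, 0.0)
    cell_id: int = 1
    seed: int = 0


def simulate_nucleus(
    params: SceneParams,
) -> tuple[ChannelImage, ChannelImage, SyntheticTruth]:
    """Simulate one centred nucleus; returns (damage ch1, DNA ch2, truth)."""
    rng = np.random.default_rng(params.seed)
    side = params.extent_px
    shape = (side, side)
    center = ((side - 1) / 2.0, (side - 1) / 2.0)

    ch1_clean = np.zeros(shape)
    ch2_clean = np.zeros(shape)
    truth = _render_cell(ch1_clean, ch2_clean, params, center, shape, rng, cell_id=1)
    ch1, ch2 = _image_noise(ch1_clean, ch2_clean, params, rng)
    return ch1, ch2, truth


def simulate_field(
    n_cells: int,
    image_shape: tuple[int, int] | None = None,
    params: SceneParams | Sequence[SceneParams] | None = None,
    seed: int = 0,
) -> tuple[ChannelImage, ChannelImage, list[SyntheticTruth]]:
    """Simulate a multi-nucleus field suitable for the full batch pipeline.

    Nuclei occupy randomly-ordered, jittered grid tiles so they never
    overlap; ``params`` may be a single SceneParams applied to every cell
    or one per cell. Raises with the achieved count when the field cannot
    hold ``n_cells`` nuclei.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if params is None:
        params = SceneParams()
    per_cell = (
        list(params) if isinstance(params, Sequence) else [params] * n_cells
    )
    if len(per_cell) != n_cells:
        raise ValueError("need one SceneParams per cell")
    rng = np.random.default_rng(seed)

    jitter = 4.0
    ext = max((p.extent_px for p in per_cell), default=SceneParams().extent_px)
    tile = ext + 2 * int(jitter)
    if image_shape is None:
        tiles = max(1, int(np.ceil(np.sqrt(max(n_cells, 1)))))
        image_shape = (tiles * tile + 2, tiles * tile + 2)
    shape = (int(image_shape[0]), int(image_shape[1]))

    ch1_clean = np.zeros(shape)
    ch2_clean = np.zeros(shape)
    truths: list[SyntheticTruth] = []
    n_rows, n_cols = shape[0] // tile, shape[1] // tile
    slots = list(rng.permutation(n_rows * n_cols)) if n_rows * n_cols else []
    y0 = (shape[0] - n_rows * tile) / 2.0
    x0 = (shape[1] - n_cols * tile) / 2.0
    for i, p in enumerate(per_cell):
        if not slots:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n_cells}; placed {len(truths)} cells"
            )
        slot = int(slots.pop(0))
        cy = y0 + (slot // n_cols) * tile + tile / 2.0 + rng.uniform(-jitter, jitter)
        cx = x0 + (slot % n_cols) * tile + tile / 2.0 + rng.uniform(-jitter, jitter)
        truth = _render_cell(ch1_clean, ch2_clean, p, (cy, cx), shape, rng, cell_id=i + 1)
        truths.append(truth)

    noise_params = per_cell[0] if per_cell else SceneParams()
    ch1, ch2 = _image_noise(ch1_clean, ch2_clean, noise_params, rng)
    return ch1, ch2, truths


def truths_to_dataframe(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    """Flatten ground truth into one row per focus (plus cell metadata)."""
    rows = []
    for t in truths:
        if len(t.foci_centers) == 0:
            rows.append(
                dict(cell_id=t.cell_id, p_het=t.p_het, focus_row=np.nan,
                     focus_col=np.nan, on_blob=np.nan,
                     n_foci=0, n_blobs=len(t.blob_centers))
            )
            continue
        for (fr, fc), on in zip(t.foci_centers, t.foci_on_blob):
            rows.append(
                dict(cell_id=t.cell_id, p_het=t.p_het, focus_row=float(fr),
                     focus_col=float(fc), on_blob=bool(on),
                     n_foci=len(t.foci_centers), n_blobs=len(t.blob_centers))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- internals


def _render_cell(ch1, ch2, params, center, shape, rng, cell_id):
    ay, ax = params.nucleus_axes_px
    cy, cx = center
    if not (
        cy - ay >= params.psf_sigma_px and cy + ay < shape[0] - params.psf_sigma_px
        and cx - ax >= params.psf_sigma_px and cx + ax < shape[1] - params.psf_sigma_px
    ):
        raise ValueError("nucleus does not fit inside the image with a PSF margin")

    blob_centers = _sample_blob_centers(params, center, rng)
    foci_centers, foci_on_blob = _sample_foci(params, center, blob_centers, rng)

    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    ellipse = (((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2) <= 1.0
    ch2 += ellipse.astype(np.float64)  # euchromatin baseline = 1 unit
    for by, bx in blob_centers:
        _add_gaussian(ch2, (by, bx), params.blob_sigma_px, params.blob_contrast - 1.0)
    for fy, fx in foci_centers:
        _add_gaussian(ch1, (fy, fx), params.focus_sigma_px, params.focus_amplitude)

    return SyntheticTruth(
        blob_centers=np.asarray(blob_centers, dtype=np.float64).reshape(-1, 2),
        foci_centers=np.asarray(foci_centers, dtype=np.float64).reshape(-1, 2),
        foci_on_blob=np.asarray(foci_on_blob, dtype=bool),
        p_het=params.p_het,
        nucleus_mask_true=BinaryMask(ellipse),
        nucleus_center=(float(cy), float(cx)),
        cell_id=cell_id,
        seed=params.seed,
    )


def _sample_in_ellipse(center, axes, rng, shrink=0.8):
    while True:
        u = rng.uniform(-1.0, 1.0, size=2)
        if u @ u <= 1.0:
            return (center[0] + shrink * axes[0] * u[0], center[1] + shrink * axes[1] * u[1])


def _sample_blob_centers(params, center, rng):
    min_sep = (
        params.min_blob_sep_px
        if params.min_blob_sep_px is not None
        else 3.0 * params.blob_sigma_px
    )
    centers: list[tuple[float, float]] = []
    for _ in range(params.n_blobs):
        for _ in range(_MAX_TRIES):
            cand = _sample_in_ellipse(center, params.nucleus_axes_px, rng)
            if all(np.hypot(cand[0] - y, cand[1] - x) >= min_sep for y, x in centers):
                centers.append(cand)
                break
        else:
            raise RuntimeError("infeasible geometry: cannot place heterochromatin blobs")
    return centers


def _sample_foci(params, center, blob_centers, rng):
    min_sep = (
        params.min_focus_sep_px
        if params.min_focus_sep_px is not None
        else 4.0 * params.focus_sigma_px
    )
    margin = params.off_blob_margin_sigma * params.blob_sigma_px
    centers: list[tuple[float, float]] = []
    on_blob: list[bool] = []
    free_blobs = list(rng.permutation(len(blob_centers))) if blob_centers else []

    for _ in range(params.n_foci):
        if params.placement == "independent":
            cand = _place_with_sep(
                lambda: _sample_in_ellipse(center, params.nucleus_axes_px, rng),
                centers, min_sep,
            )
            centers.append(cand)
            near = (
                min(np.hypot(cand[0] - y, cand[1] - x) for y, x in blob_centers)
                if blob_centers else np.inf
            )
            on_blob.append(near <= params.blob_sigma_px)
            continue
        if blob_centers and rng.uniform() < params.p_het:
            idx = free_blobs.pop(0) if free_blobs else int(rng.integers(len(blob_centers)))
            cand = tuple(blob_centers[idx])
            if any(np.hypot(cand[0] - y, cand[1] - x) < 1e-9 for y, x in centers):
                # same blob drawn twice: fall back to another random blob
                idx = int(rng.integers(len(blob_centers)))
                cand = tuple(blob_centers[idx])
            centers.append(cand)
            on_blob.append(True)
        else:
            def off_blob_draw():
                c = _sample_in_ellipse(center, params.nucleus_axes_px, rng)
                if blob_centers and min(
                    np.hypot(c[0] - y, c[1] - x) for y, x in blob_centers
                ) < margin:
                    return None
                return c

            cand = _place_with_sep(off_blob_draw, centers, min_sep)
            centers.append(cand)
            on_blob.append(False)
    return centers, on_blob


def _place_with_sep(draw, existing, min_sep):
    for _ in range(_MAX_TRIES):
        cand = draw()
        if cand is None:
            continue
        if all(np.hypot(cand[0] - y, cand[1] - x) >= min_sep for y, x in existing):
            return cand
    raise RuntimeError("infeasible geometry: cannot place damage foci")


def _add_gaussian(canvas, center, sigma, amplitude, n_sigma=5.0):
    cy, cx = center
    r0 = max(0, int(np.floor(cy - n_sigma * sigma)))
    r1 = min(canvas.shape[0], int(np.ceil(cy + n_sigma * sigma)) + 1)
    c0 = max(0, int(np.floor(cx - n_sigma * sigma)))
    c1 = min(canvas.shape[1], int(np.ceil(cx + n_sigma * sigma)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1)[:, None]
    xx = np.arange(c0, c1)[None, :]
    canvas[r0:r1, c0:c1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma * sigma)
    )


def _image_noise(ch1_clean, ch2_clean, params, rng):
    out = []
    for clean, role in ((ch1_clean, ChannelRole.DAMAGE), (ch2_clean, ChannelRole.DNA)):
        blurred = gaussian_filter(clean, params.psf_sigma_px)
        expected = np.clip(blurred, 0.0, None) * params.photons_per_unit
        noisy = rng.poisson(expected).astype(np.float64) + params.background_offset
        out.append(ChannelImage(noisy, pixel_size_nm=params.pixel_size_nm, role=role))
    return out[0], out[1]
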