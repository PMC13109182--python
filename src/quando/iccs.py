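"""Image cross-correlation spectroscopy (ICCS) on single nuclei.

Colocalization between two channels is quantified without object
segmentation, from the amplitudes of the spatial auto- and cross-correlation
functions computed over an irregular region (the nucleus mask):

    G_ab(xi, eta) = < dI_a(x, y) * dI_b(x + xi, y + eta) > / (<I_a> <I_b>)

with ``dI = I - <I>`` and every average restricted to in-region pixels; each
lag is normalized by the number of pixel pairs whose BOTH endpoints fall in
the region, so the region silhouette does not leak into the correlation.
A 2D Gaussian is fitted to each correlation function; the zero lag is
excluded from the autocorrelation fits (it carries the uncorrelated
shot/detector-noise spike) so their amplitude is the value extrapolated to
zero lag, and included for the cross-correlation. The colocalization
fractions are amplitude ratios

    f1 = G0_cross / G0_auto2      f2 = G0_cross / G0_auto1

ranging from 1 (complete colocalization) through 0 (independence) to -1
(maximum repulsion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.signal import fftconvolve

from .types import BinaryMask, ChannelImage, CountMask

DEFAULT_MIN_OVERLAP = 100


@dataclass
class CorrelationFunction:
    """Spatial correlation values over integer lags (xi, eta) in [-L, L].

    ``values[L + xi, L + eta]`` is G(xi, eta); lags whose in-region pixel-pair
    count falls below ``min_overlap`` are unusable (NaN where the count is
    zero). ``overlap_counts[L, L] == n_pixels_used`` by construction, and
    autocorrelations satisfy G(xi, eta) == G(-xi, -eta) exactly.
    """

    values: np.ndarray
    overlap_counts: np.ndarray
    pair: str  # 'auto1' | 'auto2' | 'cross'
    max_lag: int
    n_pixels_used: int
    min_overlap: int = DEFAULT_MIN_OVERLAP

    @property
    def usable(self) -> np.ndarray:
        return (self.overlap_counts >= self.min_overlap) & np.isfinite(self.values)

    def lag_grids(self) -> tuple[np.ndarray, np.ndarray]:
        L = self.max_lag
        return np.mgrid[-L : L + 1, -L : L + 1]


@dataclass
class GaussianFit:
    """Isotropic 2D Gaussian fit ``G0 * exp(-(xi^2+eta^2)/w^2) + Ginf``."""

    amplitude_g0: float
    width_w_px: float
    offset_ginf: float
    fit_range_px: float
    residual_norm: float
    converged: bool
    n_points: int = 0
    reason: str = ""


@dataclass
class IccsParams:
    """Tuning constants for the per-cell iterative ICCS extraction."""

    max_lag: int = 32
    min_overlap: int = DEFAULT_MIN_OVERLAP
    range_factor: float = 3.0  # next fit range = factor * fitted width
    range_tol_px: float = 0.5
    max_fit_iter: int = 10
    width_bounds_px: tuple[float, float] = (0.5, 30.0)
    f_limit: float = 1.2
    min_range_px: float = 2.0
    # Fit the cross amplitude with its width pinned to the auto widths
    # (w_c^2 = (w1^2 + w2^2)/2). A free-width cross fit is degenerate when
    # the true cross amplitude is ~0 (independence), which would silently
    # bias the surviving-cell statistics.
    cross_width_from_autos: bool = True


@dataclass
class ColocalizationResult:
    """Per-nucleus colocalization fractions with their three fits and QC."""

    cell_id: int
    f1: float
    f2: float
    fit_cross: GaussianFit | None = None
    fit_auto1: GaussianFit | None = None
    fit_auto2: GaussianFit | None = None
    valid: bool = False
    reason: str = ""


def masked_correlation(
    imgA: ChannelImage | np.ndarray,
    imgB: ChannelImage | np.ndarray,
    region: BinaryMask | np.ndarray,
    max_lag: int = 32,
    pair: str = "cross",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CorrelationFunction:
    """Masked spatial correlation of two images over an irregular region.

    Parameters
    ----------
    imgA, imgB
        Images of identical shape. Pass the same image twice (and
        ``pair='auto1'`` or ``'auto2'``) for an autocorrelation.
    region
        Boolean mask restricting all averages; only pixel pairs with both
        endpoints in the region contribute to a lag.
    max_lag
        Half-width L of the lag window; must be smaller than half the
        region bounding-box extent.
    pair
        One of ``'auto1'``, ``'auto2'``, ``'cross'``; autocorrelations are
        symmetrized exactly.
    min_overlap
        Minimum in-region pixel pairs for a lag to be usable.

    Raises
    ------
    ValueError
        If the region is smaller than ``min_overlap`` ("region too small
        for ICCS"), the means vanish, or ``max_lag`` is too large.
    """
    a = imgA.pixels if isinstance(imgA, ChannelImage) else np.asarray(imgA, dtype=np.float64)
    b = imgB.pixels if isinstance(imgB, ChannelImage) else np.asarray(imgB, dtype=np.float64)
    m = region.mask if isinstance(region, BinaryMask) else np.asarray(region, dtype=bool)
    if a.shape != b.shape or a.shape != m.shape:
        raise ValueError("images and region must share shape")
    if pair not in ("auto1", "auto2", "cross"):
        raise ValueError(f"unknown pair {pair!r}")
    n = int(m.sum())
    if n < min_overlap:
        raise ValueError("region too small for ICCS")
    rows, cols = np.nonzero(m)
    bbox_h = int(rows.max() - rows.min() + 1)
    bbox_w = int(cols.max() - cols.min() + 1)
    if max_lag < 1 or 2 * max_lag >= min(bbox_h, bbox_w):
        raise ValueError("max_lag must be < half the region bounding-box extent")

    mean_a = float(a[m].mean())
    mean_b = float(b[m].mean())
    if mean_a == 0.0 or mean_b == 0.0:
        raise ValueError("zero mean intensity in region")
    da = np.where(m, a - mean_a, 0.0)
    db = np.where(m, b - mean_b, 0.0)

    # conv(flip(da), db)[c + lag] = sum_x da(x) * db(x + lag), c = (H-1, W-1)
    num = fftconvolve(da[::-1, ::-1], db, mode="full")
    cnt = np.rint(fftconvolve(m[::-1, ::-1].astype(np.float64), m.astype(np.float64), mode="full"))
    H, W = a.shape
    L = max_lag
    sl = (slice(H - 1 - L, H + L), slice(W - 1 - L, W + L))
    num = num[sl]
    cnt = cnt[sl].astype(np.int64)
    cnt[L, L] = n  # exact by definition

    with np.errstate(invalid="ignore", divide="ignore"):
        values = num / cnt / (mean_a * mean_b)
    values[cnt <= 0] = np.nan

    if pair != "cross":
        # the estimator is symmetric under (xi,eta) -> (-xi,-eta); enforce
        # the identity bit-exactly against FFT round-off
        values = 0.5 * (values + values[::-1, ::-1])

    return CorrelationFunction(
        values=values,
        overlap_counts=cnt,
        pair=pair,
        max_lag=L,
        n_pixels_used=n,
        min_overlap=min_overlap,
    )


def fit_gaussian(
    corr: CorrelationFunction,
    exclude_zero_lag: bool,
    initial_range_px: float,
) -> GaussianFit:
    """Least-squares fit of an isotropic Gaussian to a correlation function.

    Only usable lags with radius <= ``initial_range_px`` enter the fit; the
    (0, 0) lag is dropped when ``exclude_zero_lag`` so the amplitude is the
    noise-free value extrapolated to zero lag.
    """
    xi, eta = corr.lag_grids()
    r = np.hypot(xi, eta)
    sel = corr.usable & (r <= initial_range_px)
    if exclude_zero_lag:
        sel &= ~((xi == 0) & (eta == 0))
    n_pts = int(sel.sum())
    if n_pts < 8:
        return GaussianFit(
            amplitude_g0=np.nan, width_w_px=np.nan, offset_ginf=np.nan,
            fit_range_px=float(initial_range_px), residual_norm=np.nan,
            converged=False, n_points=n_pts, reason="insufficient usable lags",
        )
    g = corr.values[sel]
    r2 = (xi.astype(np.float64) ** 2 + eta.astype(np.float64) ** 2)[sel]

    outer = g[r[sel] >= 0.8 * initial_range_px]
    ginf0 = float(np.median(outer)) if outer.size else 0.0
    g00 = float(g[np.argmin(r2)]) - ginf0
    w0 = max(initial_range_px / 3.0, 1.0)

    def residuals(p: np.ndarray) -> np.ndarray:
        g0, w, ginf = p
        return g0 * np.exp(-r2 / (w * w)) + ginf - g

    try:
        res = optimize.least_squares(
            residuals,
            x0=np.array([g00, w0, ginf0]),
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
            method="trf",
        )
    except Exception as exc:  # pragma: no cover - defensive
        return GaussianFit(
            amplitude_g0=np.nan, width_w_px=np.nan, offset_ginf=np.nan,
            fit_range_px=float(initial_range_px), residual_norm=np.nan,
            converged=False, n_points=n_pts, reason=f"solver failure: {exc}",
        )
    g0, w, ginf = (float(v) for v in res.x)
    ok = bool(res.success) and np.isfinite([g0, w, ginf]).all() and w > 0
    return GaussianFit(
        amplitude_g0=g0,
        width_w_px=w,
        offset_ginf=ginf,
        fit_range_px=float(initial_range_px),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=ok,
        n_points=n_pts,
        reason="" if ok else "solver did not converge",
    )


def fit_gaussian_fixed_width(
    corr: CorrelationFunction,
    width_px: float,
    fit_range_px: float,
    exclude_zero_lag: bool = False,
) -> GaussianFit:
    """Fit amplitude and offset only, with the Gaussian width held fixed.

    Linear least squares on ``[exp(-r^2/w^2), 1]``; always well-posed, so
    it is the stable route for cross-correlations of nearly independent
    channels where a free-width fit is degenerate.
    """
    xi, eta = corr.lag_grids()
    r = np.hypot(xi, eta)
    sel = corr.usable & (r <= fit_range_px)
    if exclude_zero_lag:
        sel &= ~((xi == 0) & (eta == 0))
    n_pts = int(sel.sum())
    if n_pts < 8 or not np.isfinite(width_px) or width_px <= 0:
        return GaussianFit(
            amplitude_g0=np.nan, width_w_px=float(width_px), offset_ginf=np.nan,
            fit_range_px=float(fit_range_px), residual_norm=np.nan,
            converged=False, n_points=n_pts, reason="insufficient usable lags",
        )
    g = corr.values[sel]
    r2 = (xi.astype(np.float64) ** 2 + eta.astype(np.float64) ** 2)[sel]
    design = np.column_stack([np.exp(-r2 / (width_px * width_px)), np.ones_like(r2)])
    (g0, ginf), *_ = np.linalg.lstsq(design, g, rcond=None)
    resid = design @ np.array([g0, ginf]) - g
    return GaussianFit(
        amplitude_g0=float(g0),
        width_w_px=float(width_px),
        offset_ginf=float(ginf),
        fit_range_px=float(fit_range_px),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
        n_points=n_pts,
        reason="width fixed from autocorrelations",
    )


def iterative_fit(
    corr: CorrelationFunction, exclude_zero_lag: bool, params: IccsParams
) -> GaussianFit:
    """Fit with a self-adjusting range: range <- factor * fitted width,
    stopping when the range moves less than ``range_tol_px`` (or after
    ``max_fit_iter`` rounds)."""
    fit_range = float(corr.max_lag)
    fit = fit_gaussian(corr, exclude_zero_lag, fit_range)
    for _ in range(params.max_fit_iter - 1):
        if not fit.converged:
            return fit
        new_range = float(
            np.clip(params.range_factor * fit.width_w_px, params.min_range_px, corr.max_lag)
        )
        if abs(new_range - fit_range) < params.range_tol_px:
            break
        fit_range = new_range
        fit = fit_gaussian(corr, exclude_zero_lag, fit_range)
    return fit


def colocalization_fractions(
    fit_cross: GaussianFit, fit_auto1: GaussianFit, fit_auto2: GaussianFit
) -> tuple[float, float]:
    """Amplitude-ratio colocalization fractions (f1, f2).

    f1 = G0_cross / G0_auto2 is the fraction of channel-1 signal
    cross-correlated with channel 2; f2 = G0_cross / G0_auto1 the converse.
    The sign follows the cross-correlation amplitude; no clamping.
    """
    for fit in (fit_cross, fit_auto1, fit_auto2):
        if not fit.converged:
            raise ValueError("all three fits must be converged")
    if fit_auto1.amplitude_g0 <= 0 or fit_auto2.amplitude_g0 <= 0:
        raise ValueError("autocorrelation amplitudes must be > 0")
    f1 = fit_cross.amplitude_g0 / fit_auto2.amplitude_g0
    f2 = fit_cross.amplitude_g0 / fit_auto1.amplitude_g0
    return float(f1), float(f2)


def per_cell_iccs(
    ch1: ChannelImage,
    ch2: ChannelImage,
    nuclei: CountMask,
    params: IccsParams | None = None,
) -> list[ColocalizationResult]:
    """Run the full ICCS extraction on every nucleus of a field.

    For each nucleus: crop its bounding box, compute the two auto- and the
    cross-correlation functions over the nucleus mask, run the iterative
    Gaussian fits (zero lag excluded for autos, included for cross) and form
    f1/f2. Failures are recorded per cell (``valid=False`` with a reason)
    and never abort the batch. Validity requires converged fits, positive
    auto amplitudes, widths inside ``params.width_bounds_px`` and
    ``|f| <= params.f_limit``.
    """
    params = params or IccsParams()
    if ch1.shape != ch2.shape or ch1.shape != nuclei.shape:
        raise ValueError("channels and count mask must share shape")
    results: list[ColocalizationResult] = []
    for cell_id, region in nuclei.iter_regions():
        results.append(_one_cell(ch1.pixels, ch2.pixels, region, cell_id, params))
    return results


def _one_cell(
    a: np.ndarray, b: np.ndarray, region: np.ndarray, cell_id: int, params: IccsParams
) -> ColocalizationResult:
    rows, cols = np.nonzero(region)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    sub_a = a[r0:r1, c0:c1]
    sub_b = b[r0:r1, c0:c1]
    sub_m = region[r0:r1, c0:c1]

    lag = min(params.max_lag, (min(r1 - r0, c1 - c0) - 1) // 2)
    invalid = ColocalizationResult(cell_id=cell_id, f1=np.nan, f2=np.nan)
    if lag < 3:
        invalid.reason = "nucleus too small for correlation analysis"
        return invalid
    try:
        corr11 = masked_correlation(sub_a, sub_a, sub_m, lag, "auto1", params.min_overlap)
        corr22 = masked_correlation(sub_b, sub_b, sub_m, lag, "auto2", params.min_overlap)
        corr12 = masked_correlation(sub_a, sub_b, sub_m, lag, "cross", params.min_overlap)
    except ValueError as exc:
        invalid.reason = str(exc)
        return invalid

    fit_auto1 = iterative_fit(corr11, exclude_zero_lag=True, params=params)
    fit_auto2 = iterative_fit(corr22, exclude_zero_lag=True, params=params)
    if (
        params.cross_width_from_autos
        and fit_auto1.converged
        and fit_auto2.converged
    ):
        w_c = float(np.sqrt(0.5 * (fit_auto1.width_w_px**2 + fit_auto2.width_w_px**2)))
        cross_range = float(
            np.clip(params.range_factor * w_c, params.min_range_px, corr12.max_lag)
        )
        fit_cross = fit_gaussian_fixed_width(corr12, w_c, cross_range, exclude_zero_lag=False)
    else:
        fit_cross = iterative_fit(corr12, exclude_zero_lag=False, params=params)

    result = ColocalizationResult(
        cell_id=cell_id, f1=np.nan, f2=np.nan,
        fit_cross=fit_cross, fit_auto1=fit_auto1, fit_auto2=fit_auto2,
    )
    reasons: list[str] = []
    for name, fit in (("cross", fit_cross), ("auto1", fit_auto1), ("auto2", fit_auto2)):
        if not fit.converged:
            reasons.append(f"{name} fit failed: {fit.reason}")
    if not reasons:
        lo, hi = params.width_bounds_px
        for name, fit in (("cross", fit_cross), ("auto1", fit_auto1), ("auto2", fit_auto2)):
            if not lo <= fit.width_w_px <= hi:
                reasons.append(f"{name} width {fit.width_w_px:.2f} px outside [{lo}, {hi}]")
        if fit_auto1.amplitude_g0 <= 0:
            reasons.append("auto1 amplitude <= 0")
        if fit_auto2.amplitude_g0 <= 0:
            reasons.append("auto2 amplitude <= 0")
    if not reasons:
        result.f1, result.f2 = colocalization_fractions(fit_cross, fit_auto1, fit_auto2)
        if abs(result.f1) > params.f_limit or abs(result.f2) > params.f_limit:
            reasons.append(f"|f| exceeds {params.f_limit}")
    result.valid = not reasons
    result.reason = "; ".join(reasons)
    return result
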