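import numpy as np
import pytest

from quando.types import BinaryMask, ChannelImage, ChannelRole


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dna(pixels, pixel_size_nm=45.0):
    return ChannelImage(pixels, pixel_size_nm=pixel_size_nm, role=ChannelRole.DNA)


def make_damage(pixels, pixel_size_nm=45.0):
    return ChannelImage(pixels, pixel_size_nm=pixel_size_nm, role=ChannelRole.DAMAGE)


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture
def three_disc_scene():
    """Dark background with three disjoint bright discs (radius 6)."""
    img = np.full((96, 96), 10.0)
    for c in [(20, 20), (20, 70), (70, 45)]:
        img[disc_mask((96, 96), c, 6)] = 200.0
    return make_dna(img)


# ------------------------------------------------------- independent oracles


def brute_force_masked_correlation(a, b, mask, max_lag):
    """Direct double-loop masked correlation (the test oracle; no FFT)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m = np.asarray(mask, bool)
    H, W = a.shape
    mean_a = a[m].mean()
    mean_b = b[m].mean()
    L = max_lag
    G = np.full((2 * L + 1, 2 * L + 1), np.nan)
    counts = np.zeros((2 * L + 1, 2 * L + 1), dtype=int)
    for xi in range(-L, L + 1):
        for eta in range(-L, L + 1):
            s = 0.0
            n = 0
            for x in range(H):
                for y in range(W):
                    x2, y2 = x + xi, y + eta
                    if 0 <= x2 < H and 0 <= y2 < W and m[x, y] and m[x2, y2]:
                        s += (a[x, y] - mean_a) * (b[x2, y2] - mean_b)
                        n += 1
            counts[L + xi, L + eta] = n
            if n:
                G[L + xi, L + eta] = s / n / (mean_a * mean_b)
    return G, counts


def flood_fill_labels(binary):
    """BFS 8-connected labeling oracle (no scipy/skimage)."""
    binary = np.asarray(binary, bool)
    labels = np.zeros(binary.shape, dtype=int)
    next_label = 0
    H, W = binary.shape
    for i in range(H):
        for j in range(W):
            if binary[i, j] and labels[i, j] == 0:
                next_label += 1
                stack = [(i, j)]
                labels[i, j] = next_label
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < H and 0 <= xx < W
                                and binary[yy, xx] and labels[yy, xx] == 0
                            ):
                                labels[yy, xx] = next_label
                                stack.append((yy, xx))
    return labels, next_label


def isodata_fixed_points(pixels, n_bins=256):
    """All thresholds t (scanned over bin boundaries) satisfying the isodata
    fixed point t = (mean(<=t) + mean(>t))/2 within one bin width."""
    pixels = np.asarray(pixels, float).ravel()
    lo, hi = pixels.min(), pixels.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    width = edges[1] - edges[0]
    hits = []
    for t in edges[1:-1]:
        low = pixels[pixels <= t]
        high = pixels[pixels > t]
        if low.size == 0 or high.size == 0:
            continue
        if abs(0.5 * (low.mean() + high.mean()) - t) <= width:
            hits.append(float(t))
    return hits, float(width)
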