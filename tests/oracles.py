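"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is implemented per pixel / per element with explicit loops
or direct definitions, deliberately avoiding the vectorised code paths of
the package.
"""

import itertools

import numpy as np


def gaussian_kernel(sigma: float) -> np.ndarray:
    radius = int(np.ceil(4.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_spectrum_brute(spectrum: np.ndarray, sigma: float) -> np.ndarray:
    """Per-spectrum direct convolution with symmetric (reflect) padding."""
    kernel = gaussian_kernel(sigma)
    radius = (len(kernel) - 1) // 2
    padded = np.pad(spectrum.astype(float), radius, mode="symmetric")
    return np.convolve(padded, kernel, mode="valid")


def smooth_cube_brute(data: np.ndarray, sigma: float) -> np.ndarray:
    out = np.empty_like(data, dtype=float)
    for r in range(data.shape[0]):
        for c in range(data.shape[1]):
            out[r, c] = smooth_spectrum_brute(data[r, c], sigma)
    return out


def second_derivative_brute(data: np.ndarray, step_nm: float) -> np.ndarray:
    out = np.empty_like(data, dtype=float)
    for r in range(data.shape[0]):
        for c in range(data.shape[1]):
            s = data[r, c].astype(float)
            out[r, c, 1:-1] = (s[:-2] - 2 * s[1:-1] + s[2:]) / step_nm**2
            out[r, c, 0] = out[r, c, 1]
            out[r, c, -1] = out[r, c, -2]
    return out


def median_filter_brute(image: np.ndarray, size: int) -> np.ndarray:
    """Median filter with symmetric (reflect) padding, window size x size."""
    radius = size // 2
    padded = np.pad(image, radius, mode="symmetric")
    out = np.empty_like(image, dtype=float)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = np.median(padded[r : r + size, c : c + size])
    return out


def reconstruct_brute(
    data: np.ndarray,
    wavelengths: np.ndarray,
    sigma: float = 4.44,
    window=(790.0, 810.0),
    median_size: int = 7,
    percentile: float = 99.0,
) -> np.ndarray:
    """Stage-by-stage single-pixel reimplementation of the reconstruction."""
    step = wavelengths[1] - wavelengths[0]
    smoothed = smooth_cube_brute(data, sigma)
    curv = second_derivative_brute(smoothed, step)
    members = [k for k, wl in enumerate(wavelengths) if window[0] <= wl <= window[1]]
    score = np.zeros(data.shape[:2])
    for r in range(data.shape[0]):
        for c in range(data.shape[1]):
            score[r, c] = max(0.0, sum(curv[r, c, k] for k in members) / len(members))
    filtered = median_filter_brute(score, median_size)
    denom = np.percentile(filtered, percentile)
    if denom <= 1e-12:
        return np.zeros_like(filtered)
    return np.clip(filtered / denom, 0.0, 1.0)


def roi_mean_brute(image2d_or_cube: np.ndarray, cx: float, cy: float, r: float):
    """Mean over the disc by explicit pixel scan; works per band for cubes."""
    values = []
    height, width = image2d_or_cube.shape[:2]
    for y in range(height):
        for x in range(width):
            if (x - cx) ** 2 + (y - cy) ** 2 <= r**2:
                values.append(image2d_or_cube[y, x])
    return np.mean(values, axis=0)


def movmean_brute(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        out[i] = np.mean(x[i - h : i + h + 1])
    return out


def bilinear_brute(image: np.ndarray, x: float, y: float) -> float:
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x0 = min(max(x0, 0), image.shape[1] - 2) if image.shape[1] > 1 else 0
    y0 = min(max(y0, 0), image.shape[0] - 2) if image.shape[0] > 1 else 0
    fx, fy = x - x0, y - y0
    return float(
        image[y0, x0] * (1 - fx) * (1 - fy)
        + image[y0, x0 + 1] * fx * (1 - fy)
        + image[y0 + 1, x0] * (1 - fx) * fy
        + image[y0 + 1, x0 + 1] * fx * fy
    )


def wilcoxon_exact_brute(differences: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of the 2^n sign assignments."""
    d = np.asarray(differences, dtype=float)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s > 0) for signs in itertools.product([-1, 1], repeat=n)]
    )
    return float(min(1.0, 2.0 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())))
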