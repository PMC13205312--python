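"""ICG fluorescence inflow quantification per ROI.

The fluorescence video starts with ICG administration. Per ROI the pipeline
is: mean disc intensity per frame -> division by the per-frame laser
excitation level (read off a rendered indicator by template matching) ->
centred moving-average smoothing (3 s window) -> background noise B (maximum
of the smoothed curve 3-6 s after administration) -> objective T0 (first
time from which the curve stays above B) -> slope (ordinary least squares
over the contiguous segment of highest local slopes).

Slopes are reported in laser-normalised intensity units per second;
literature thresholds for anastomotic risk (slope < 2.1 units/s, T0 > 60 s,
T0 > 40 s) can be evaluated against the computed metrics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import (
    IndicatorUnreadableError,
    NoInflowDetectedError,
    RangeError,
    ValidationError,
)
from .hsi_cube import CircularROI, roi_mask

__all__ = [
    "FrameStack",
    "InflowCurve",
    "InflowMetrics",
    "DEFAULT_THRESHOLDS",
    "extract_roi_series",
    "estimate_laser_intensity",
    "laser_levels",
    "movmean",
    "build_curve",
    "background_noise",
    "t0_objective",
    "inflow_slope",
    "time_to_peak",
    "classify_thresholds",
    "read_frame_stack",
    "load_template_bank",
]

DEFAULT_THRESHOLDS = {"wada_slope": 2.1, "hayami_t0": 60.0, "kim_t0": 40.0}
NCC_FLOOR = 0.2
NOISE_WINDOW_S = (3.0, 6.0)


@dataclass
class FrameStack:
    """Time-ordered grayscale frames with a uniform frame interval."""

    frames: np.ndarray  # (T, H, W)
    frame_rate_hz: float
    t0_admin_s: float = 0.0  # administration time on the stack clock

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValidationError("frame stack must be (T>=2, H, W)")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times_s(self) -> np.ndarray:
        """Frame times relative to ICG administration."""
        return np.arange(self.n_frames) / self.frame_rate_hz - self.t0_admin_s


@dataclass
class InflowCurve:
    """Per-ROI fluorescence time series through the normalisation stages."""

    t_s: np.ndarray
    raw: np.ndarray
    laser: np.ndarray
    normalized: np.ndarray
    smoothed: np.ndarray
    smooth_window_frames: int = 1

    def __post_init__(self) -> None:
        arrays = [self.t_s, self.raw, self.laser, self.normalized, self.smoothed]
        n = len(self.t_s)
        if any(len(a) != n for a in arrays):
            raise ValidationError("curve arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.laser <= 0):
            raise ValidationError("laser levels must be positive")


@dataclass
class InflowMetrics:
    background_noise_B: float
    t0_objective_s: float
    slope_units_per_s: float
    ttp_s: float | None = None
    threshold_flags: dict[str, bool] = field(default_factory=dict)


def extract_roi_series(stack: FrameStack, roi: CircularROI) -> np.ndarray:
    """Mean intensity over the ROI disc, one value per frame."""
    _, height, width = stack.frames.shape
    mask = roi_mask(roi, height, width)
    return stack.frames[:, mask].mean(axis=1).astype(float)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equally-shaped patches."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return 1.0 if na < 1e-12 and nb < 1e-12 else 0.0
    return float(a @ b / (na * nb))


def estimate_laser_intensity(
    frame: np.ndarray,
    indicator: tuple[int, int, int, int],
    templates: list[tuple[float, np.ndarray]],
) -> float:
    """Laser level in (0, 1] read from the indicator region of one frame.

    ``indicator`` is ``(x, y, w, h)``; each template in the bank is a
    ``(level, image)`` pair of the indicator's appearance at that level. The
    best normalized cross-correlation wins, ties going to the higher level;
    if no template scores above 0.2 the indicator is declared unreadable.
    """
    if not templates:
        raise ValidationError("template bank is empty")
    x, y, w, h = indicator
    frame = np.asarray(frame)
    if x < 0 or y < 0 or x + w > frame.shape[1] or y + h > frame.shape[0]:
        raise RangeError("indicator region outside frame bounds")
    crop = frame[y : y + h, x : x + w]
    best_level, best_score = None, -np.inf
    for level, template in templates:
        if template.shape != crop.shape:
            raise ValidationError(
                f"template shape {template.shape} != indicator shape {crop.shape}"
            )
        score = _ncc(crop, template)
        if score > best_score or (score == best_score and (best_level is None or level > best_level)):
            best_level, best_score = level, score
    if best_score < NCC_FLOOR:
        raise IndicatorUnreadableError(f"best template score {best_score:.3f} below {NCC_FLOOR}")
    return float(best_level)


def laser_levels(
    stack: FrameStack,
    indicator: tuple[int, int, int, int] | None,
    templates: list[tuple[float, np.ndarray]] | None,
) -> np.ndarray:
    """Per-frame laser level; unreadable frames interpolated from neighbours.

    Without an indicator/template bank the laser is taken as constant 1.
    """
    if indicator is None or templates is None:
        return np.ones(stack.n_frames)
    x, y, w, h = indicator
    if x < 0 or y < 0 or x + w > stack.frames.shape[2] or y + h > stack.frames.shape[1]:
        raise RangeError("indicator region outside frame bounds")
    # vectorised NCC of every frame crop against every template
    crops = stack.frames[:, y : y + h, x : x + w].reshape(stack.n_frames, -1).astype(float)
    crops = crops - crops.mean(axis=1, keepdims=True)
    crop_norm = np.linalg.norm(crops, axis=1)
    bank_levels = np.array([level for level, _ in templates])
    tmpl = np.stack([t.ravel() for _, t in templates]).astype(float)
    if tmpl.shape[1] != crops.shape[1]:
        raise ValidationError("template shape does not match the indicator shape")
    tmpl = tmpl - tmpl.mean(axis=1, keepdims=True)
    tmpl_norm = np.linalg.norm(tmpl, axis=1)
    scores = crops @ tmpl.T / np.outer(np.maximum(crop_norm, 1e-12), np.maximum(tmpl_norm, 1e-12))
    scores[crop_norm < 1e-12, :] = 0.0
    scores[:, tmpl_norm < 1e-12] = 0.0
    scores[np.ix_(crop_norm < 1e-12, tmpl_norm < 1e-12)] = 1.0
    # per frame: best score, ties to the higher level
    order = np.lexsort((bank_levels[None, :].repeat(len(scores), 0), scores), axis=1)[:, -1]
    best_scores = scores[np.arange(len(scores)), order]
    levels = np.where(best_scores >= NCC_FLOOR, bank_levels[order], np.nan)
    readable = np.isfinite(levels)
    if not readable.any():
        raise IndicatorUnreadableError("laser indicator unreadable in every frame")
    if not readable.all():
        idx = np.arange(stack.n_frames)
        levels = np.interp(idx, idx[readable], levels[readable])
    return levels


def movmean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with a symmetric window that shrinks at the ends.

    ``window`` must be odd; at index i the half-width is
    ``min(i, n-1-i, window//2)``.
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValidationError("moving-average window must be a positive odd integer")
    n = len(x)
    idx = np.arange(n)
    half = np.minimum(np.minimum(idx, n - 1 - idx), window // 2)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo, hi = idx - half, idx + half
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def smoothing_window_frames(window_s: float, frame_rate_hz: float) -> int:
    """Frame count of the moving-average window, forced odd (+1 if even)."""
    frames = int(round(window_s * frame_rate_hz))
    frames = max(frames, 1)
    if frames % 2 == 0:
        frames += 1
    return frames


def build_curve(
    stack: FrameStack,
    roi: CircularROI,
    indicator: tuple[int, int, int, int] | None = None,
    templates: list[tuple[float, np.ndarray]] | None = None,
    window_s: float = 3.0,
) -> InflowCurve:
    """Raw -> laser-normalised -> smoothed inflow curve for one ROI."""
    if window_s <= 0:
        raise ValidationError("smoothing window must be positive")
    raw = extract_roi_series(stack, roi)
    laser = laser_levels(stack, indicator, templates)
    normalized = raw / laser
    window = smoothing_window_frames(window_s, stack.frame_rate_hz)
    smoothed = movmean(normalized, window)
    return InflowCurve(
        t_s=stack.times_s(),
        raw=raw,
        laser=laser,
        normalized=normalized,
        smoothed=smoothed,
        smooth_window_frames=window,
    )


def background_noise(curve: InflowCurve, window_s: tuple[float, float] = NOISE_WINDOW_S) -> float:
    """Maximum of the smoothed curve in the background window after administration."""
    lo, hi = window_s
    if curve.t_s[0] > lo or curve.t_s[-1] < hi:
        raise RangeError(f"curve [{curve.t_s[0]}, {curve.t_s[-1]}] s does not cover [{lo}, {hi}] s")
    in_window = (curve.t_s >= lo) & (curve.t_s <= hi)
    return float(curve.smoothed[in_window].max())


def t0_objective(
    curve: InflowCurve, B: float, search_from_s: float = NOISE_WINDOW_S[1]
) -> float:
    """Objective time to first fluorescence.

    The earliest sample time t* (at or after the end of the background
    window) such that the smoothed curve exceeds B at every sample from t*
    onward.
    """
    above = curve.smoothed > B
    if not above[-1]:
        raise NoInflowDetectedError("signal does not stay above background noise")
    below = np.nonzero(~above)[0]
    first_ok = below[-1] + 1 if len(below) else 0
    candidates = np.nonzero(curve.t_s >= search_from_s)[0]
    if len(candidates) == 0:
        raise NoInflowDetectedError("curve ends before the background window")
    start = max(first_ok, candidates[0])
    if start >= len(curve.t_s):
        raise NoInflowDetectedError("signal never rises above background noise in time")
    return float(curve.t_s[start])


def inflow_slope(curve: InflowCurve, t0_s: float | None = None, fraction: float = 0.5) -> float:
    """OLS rise rate over the contiguous segment of highest local slopes.

    Local slopes are central differences of the smoothed curve taken at a
    stencil of half the smoothing window (plain one-sample differences when
    smoothing is off), so the slope estimates average over the same time
    scale the curve was smoothed on. The fit segment is the maximal
    contiguous run around the global-maximum local slope where the local
    slope stays >= ``fraction`` of that maximum; the half-window margins at
    both record ends, where the shrinking moving-average window leaves the
    curve under-smoothed, are excluded from the search.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if t0_s is not None and int(np.sum(curve.t_s >= t0_s)) < 5:
        raise ValidationError("need at least 5 samples after T0 for a slope fit")
    y, t = curve.smoothed, curve.t_s
    margin = curve.smooth_window_frames // 2
    k = max(1, margin)
    if len(y) < 2 * k + 2 * margin + 3:
        raise ValidationError("curve too short for its smoothing window")
    # slopes[j] is the local slope at sample j + k
    slopes = (y[2 * k :] - y[: -2 * k]) / (t[2 * k :] - t[: -2 * k])
    first, last = margin, len(slopes) - 1 - margin
    peak = first + int(np.argmax(slopes[first : last + 1]))
    if slopes[peak] <= 0:
        raise NoInflowDetectedError("maximum local slope is not positive")
    keep = slopes >= fraction * slopes[peak]
    lo = peak
    while lo > first and keep[lo - 1]:
        lo -= 1
    hi = peak
    while hi < last and keep[hi + 1]:
        hi += 1
    if hi - lo < 2:  # isolated noise spike: fall back to the minimal 3-sample window
        lo, hi = max(first, peak - 1), min(last, peak + 1)
    coeffs = np.polyfit(t[lo + k : hi + k + 1], y[lo + k : hi + k + 1], 1)
    return float(coeffs[0])


def time_to_peak(t_s: np.ndarray, laser: np.ndarray, hold_s: float = 1.0) -> float | None:
    """Onset of the laser-intensity plateau, the proxy for maximum fluorescence.

    The laser auto-gain lowers the excitation level while fluorescence
    rises; once it stops dropping for more than ``hold_s`` the maximum
    fluorescence is presumed. Returns the earliest time t at which the laser
    has already dropped below its running maximum and does not fall below
    laser(t) - 1e-9 throughout [t, t + hold_s]; None if it never stabilises
    within the record.
    """
    t_s = np.asarray(t_s, dtype=float)
    laser = np.asarray(laser, dtype=float)
    if t_s[-1] - t_s[0] < hold_s:
        raise ValidationError("laser series shorter than the hold window")
    running_max = np.maximum.accumulate(laser)
    for i in range(len(t_s)):
        if t_s[i] + hold_s > t_s[-1] + 1e-12:
            break
        if running_max[i] <= laser[i] + 1e-9:
            continue  # the gain loop has not dropped yet
        in_hold = (t_s >= t_s[i]) & (t_s <= t_s[i] + hold_s)
        if np.all(laser[in_hold] >= laser[i] - 1e-9):
            return float(t_s[i])
    return None


def classify_thresholds(
    metrics: InflowMetrics, thresholds: dict[str, float] | None = None
) -> dict[str, bool]:
    """Literature risk flags: slope < 2.1 units/s; T0 > 60 s; T0 > 40 s."""
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    flags = {
        f"wada_slope_lt_{thr['wada_slope']:g}": metrics.slope_units_per_s < thr["wada_slope"],
        f"hayami_t0_gt_{thr['hayami_t0']:g}": metrics.t0_objective_s > thr["hayami_t0"],
        f"kim_t0_gt_{thr['kim_t0']:g}": metrics.t0_objective_s > thr["kim_t0"],
    }
    metrics.threshold_flags = flags
    return flags


# --------------------------------------------------------------------------
# Frame-stack and template-bank I/O
# --------------------------------------------------------------------------

_FRAME_NUMBER = re.compile(r"(\d+)")


def read_frame_stack(
    path: str | Path, frame_rate_hz: float, t0_admin_s: float = 0.0
) -> FrameStack:
    """Read a stack from a directory of numbered PNG/TIFF frames or a multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")),
            key=lambda p: int(_FRAME_NUMBER.findall(p.stem)[-1]) if _FRAME_NUMBER.findall(p.stem) else 0,
        )
        if len(files) < 2:
            raise ValidationError(f"{path} holds fewer than 2 frames")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    else:
        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    if frames.ndim == 4:  # collapse an RGB axis if present
        frames = frames.mean(axis=-1)
    return FrameStack(frames=frames, frame_rate_hz=frame_rate_hz, t0_admin_s=t0_admin_s)


def load_template_bank(directory: str | Path) -> list[tuple[float, np.ndarray]]:
    """Load (level, image) templates from files named like ``level_0.50.png``."""
    directory = Path(directory)
    bank = []
    for p in sorted(directory.glob("level_*.png")) + sorted(directory.glob("level_*.tif")):
        level = float(p.stem.split("_", 1)[1])
        bank.append((level, np.asarray(iio.imread(p), dtype=float)))
    if not bank:
        raise ValidationError(f"no level_*.png templates found in {directory}")
    return bank
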