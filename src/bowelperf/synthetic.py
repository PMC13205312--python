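"""Synthetic acquisition generator with ground truth.

No clinical data ships with the package, so every pipeline input is
emulated: reflectance cubes with a proximal-to-distal perfusion gradient and
an injected ICG absorption dip centred at 805 nm, ICG fluorescence frame
stacks with a known inflow onset/slope and a rendered laser-intensity
indicator, border images with a falling logistic profile of known
inflection, and cohorts of per-case border distances with built-in
modality offsets. All generators are deterministic under their seed.

The ICG feature is modelled as a multiplicative Gaussian dip
``1 - depth * c(x, y) * exp(-(lambda - 805)**2 / (2 * 25**2))`` where
``c`` is the per-pixel concentration (high proximally, zero distally): the
reconstruction responds to spectral curvature near 805 nm, so the exact wing
shape of in-vivo ICG absorption is immaterial here. Default noise levels are
modest by design - 0.5 % multiplicative reflectance noise for the
integrating HSI camera, and fluorescence noise at one tenth of the inflow
plateau (SNR 10) for the video.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hsi_cube import CircularROI, HSCube
from .inflow import FrameStack

__all__ = [
    "CubeScenario",
    "InflowScenario",
    "BorderScenario",
    "CohortScenario",
    "CubeTruth",
    "InflowTruth",
    "icg_absorption_factor",
    "simulate_cube",
    "simulate_inflow_stack",
    "simulate_border_image",
    "simulate_cohort",
    "render_indicator",
    "make_template_bank",
]

NOMINAL_WAVELENGTHS_NM = 500.0 + 5.0 * np.arange(100)
GLARE_REFLECTANCE = 1.5
INDICATOR_SHAPE = (12, 28)  # (h, w) of the rendered laser indicator
TEMPLATE_LEVELS = np.round(np.arange(0.05, 1.0001, 0.05), 2)


# --------------------------------------------------------------------------
# scenario configurations
# --------------------------------------------------------------------------


@dataclass
class CubeScenario:
    """Hyperspectral acquisition scenario (test-scale spatial default)."""

    seed: int = 0
    height: int = 120
    width: int = 160
    wavelengths_nm: np.ndarray = field(default_factory=lambda: NOMINAL_WAVELENGTHS_NM.copy())
    baseline_reflectance: float = 0.6
    border_x0_px: float | None = None  # default: image centre
    border_width_px: float = 8.0
    perfusion_floor: float = 0.7  # distal multiplicative reflectance level
    icg_present: bool = True
    icg_depth: float = 0.2
    icg_center_nm: float = 805.0
    icg_sigma_nm: float = 25.0
    # extra haemoglobin-band absorption on the devascularised (distal) side,
    # so oxygenation-sensitive band ratios see the border too
    deoxy_depth: float = 0.15
    deoxy_center_nm: float = 560.0
    deoxy_sigma_nm: float = 30.0
    glare_spots: int = 0
    glare_radius_px: int = 2
    noise_sd: float = 0.005  # multiplicative reflectance noise
    acquisition_tag: str = "intra"

    def __post_init__(self) -> None:
        if not 0 <= self.icg_depth < 1:
            raise ValidationError("icg depth must be in [0, 1)")
        if self.noise_sd < 0 or self.border_width_px < 0:
            raise ValidationError("noise_sd and border width must be non-negative")
        if not 0 < self.perfusion_floor <= 1:
            raise ValidationError("perfusion floor must be in (0, 1]")
        if self.border_x0_px is None:
            self.border_x0_px = self.width / 2.0


@dataclass
class InflowScenario:
    """ICG video scenario: fluorescence ramp of known onset and slope."""

    seed: int = 0
    frame_height: int = 48
    frame_width: int = 48
    frame_rate_hz: float = 5.0
    duration_s: float = 60.0
    t0_true_s: float = 20.0
    slope_true: float = 25.0  # laser-normalised units per second
    rise_duration_s: float = 8.0  # plateau = slope * rise duration
    noise_sd_curve: float | None = None  # sd of the ROI-mean raw signal; default plateau/10
    background_level: float = 2.0
    roi: CircularROI = field(
        default_factory=lambda: CircularROI(center_xy=(20.0, 30.0), radius_px=8.0, label="perfused")
    )
    laser_floor: float = 0.5  # level the laser settles at when fluorescence peaks
    indicator_noise_sd: float = 2.0  # gray levels on the rendered indicator

    def __post_init__(self) -> None:
        if self.t0_true_s >= self.duration_s:
            raise ValidationError("onset must lie inside the recording")
        if self.slope_true <= 0 or self.rise_duration_s <= 0:
            raise ValidationError("slope and rise duration must be positive")
        if not 0 < self.laser_floor <= 1:
            raise ValidationError("laser floor must be in (0, 1]")

    @property
    def plateau(self) -> float:
        return self.slope_true * self.rise_duration_s

    @property
    def indicator_region(self) -> tuple[int, int, int, int]:
        h, w = INDICATOR_SHAPE
        return (self.frame_width - w - 1, 1, w, h)


@dataclass
class BorderScenario:
    """Single-modality border image: falling logistic along x plus noise."""

    seed: int = 0
    height: int = 120
    width: int = 160
    x0_px: float = 80.0
    width_px: float = 6.0  # logistic width; 0 gives a step edge
    high: float = 1.0
    low: float = 0.0
    noise_sd: float = 0.05  # in units of (high - low)

    def __post_init__(self) -> None:
        if not 0 <= self.x0_px <= self.width - 1:
            raise ValidationError("border centre outside image")
        if self.high <= self.low:
            raise ValidationError("high plateau must exceed low plateau")
        if self.width_px < 0 or self.noise_sd < 0:
            raise ValidationError("width and noise must be non-negative")


@dataclass
class CohortScenario:
    """Cohort of per-case signed border distances (cm) per modality."""

    seed: int = 0
    n_cases: int = 30
    offsets_cm: dict[str, float] = field(
        default_factory=lambda: {"icg": 0.0, "recicg": 0.0, "sto2": 0.0}
    )
    sd_paired_diff_cm: float = 0.2  # sd of paired differences between modalities

    def __post_init__(self) -> None:
        if self.n_cases < 3:
            raise ValidationError("a cohort needs at least 3 cases")
        if self.sd_paired_diff_cm <= 0:
            raise ValidationError("paired-difference sd must be positive")
        if len(self.offsets_cm) < 2:
            raise ValidationError("a cohort needs at least 2 modalities")


# --------------------------------------------------------------------------
# ground-truth containers
# --------------------------------------------------------------------------


@dataclass
class CubeTruth:
    border_x0_px: float
    concentration: np.ndarray  # per-pixel ICG concentration in [0, 1]
    glare_mask: np.ndarray


@dataclass
class InflowTruth:
    t0_true_s: float
    slope_true: float
    plateau: float
    ttp_true_s: float
    laser_series: np.ndarray
    fluorescence: np.ndarray  # noiseless normalised signal per frame


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def icg_absorption_factor(
    wavelengths_nm: np.ndarray, depth: float, center_nm: float = 805.0, sigma_nm: float = 25.0
) -> np.ndarray:
    """Multiplicative reflectance factor of the ICG dip, minimum at the centre."""
    if not 0 <= depth < 1:
        raise ValidationError("depth must be in [0, 1)")
    wl = np.asarray(wavelengths_nm, dtype=float)
    return 1.0 - depth * np.exp(-((wl - center_nm) ** 2) / (2.0 * sigma_nm**2))


def _falling_sigmoid(x: np.ndarray, x0: float, width: float) -> np.ndarray:
    """1 proximal (small x) -> 0 distal; a step edge when width == 0."""
    if width == 0:
        return (x < x0).astype(float)
    return 1.0 / (1.0 + np.exp(np.clip((x - x0) / width, -60, 60)))


def simulate_cube(config: CubeScenario) -> tuple[HSCube, CubeTruth]:
    """Reflectance cube with perfusion gradient, ICG dip, glare and noise.

    With the same seed, the ICG-off cube is bit-identical to the ICG-on cube
    wherever the concentration is zero (noise is drawn before the ICG factor
    is applied).
    """
    rng = np.random.default_rng(config.seed)
    x = np.arange(config.width, dtype=float)
    sig = _falling_sigmoid(x, config.border_x0_px, config.border_width_px)
    sig[sig < 1e-12] = 0.0
    modulation = config.perfusion_floor + (1.0 - config.perfusion_floor) * sig
    concentration = np.broadcast_to(sig, (config.height, config.width)).copy()

    base = config.baseline_reflectance * modulation[None, :, None]
    noise = rng.normal(0.0, config.noise_sd, (config.height, config.width, len(config.wavelengths_nm)))
    factor = np.ones((config.height, config.width, len(config.wavelengths_nm)))
    if config.icg_present and config.icg_depth > 0:
        dip = icg_absorption_factor(
            config.wavelengths_nm, config.icg_depth, config.icg_center_nm, config.icg_sigma_nm
        )
        factor = 1.0 - concentration[:, :, None] * (1.0 - dip[None, None, :])
    deoxy = np.ones_like(factor)
    if config.deoxy_depth > 0:
        deoxy_dip = icg_absorption_factor(
            config.wavelengths_nm, config.deoxy_depth, config.deoxy_center_nm, config.deoxy_sigma_nm
        )
        deoxy = 1.0 - (1.0 - concentration)[:, :, None] * (1.0 - deoxy_dip[None, None, :])
    data = np.clip(base * factor * deoxy * (1.0 + noise), 0.0, None)

    glare_mask = np.zeros((config.height, config.width), dtype=bool)
    yy, xx = np.mgrid[0 : config.height, 0 : config.width]
    for _ in range(config.glare_spots):
        cx = rng.uniform(config.glare_radius_px, config.width - 1 - config.glare_radius_px)
        cy = rng.uniform(config.glare_radius_px, config.height - 1 - config.glare_radius_px)
        glare_mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= config.glare_radius_px**2
    data[glare_mask] = GLARE_REFLECTANCE

    cube = HSCube(
        data=data,
        wavelengths_nm=np.asarray(config.wavelengths_nm, dtype=float),
        acquisition_tag=config.acquisition_tag,
        meta={"distance_cm": "50", "dose_mg_per_kg": "0.1"},
    )
    return cube, CubeTruth(
        border_x0_px=float(config.border_x0_px),
        concentration=concentration,
        glare_mask=glare_mask,
    )


def render_indicator(level: float, noise_sd: float = 0.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """Render the laser-intensity indicator: a framed bar filled to ``level``."""
    h, w = INDICATOR_SHAPE
    img = np.zeros((h, w))
    img[0, :] = img[-1, :] = img[:, 0] = img[:, -1] = 255.0
    fill = int(round(level * (w - 2)))
    img[1 : h - 1, 1 : 1 + fill] = 200.0
    if noise_sd > 0 and rng is not None:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def make_template_bank(levels: np.ndarray = TEMPLATE_LEVELS) -> list[tuple[float, np.ndarray]]:
    """Noise-free indicator templates, one per discrete laser level."""
    return [(float(level), render_indicator(float(level))) for level in levels]


def _quantize_level(level: float) -> float:
    return float(TEMPLATE_LEVELS[np.argmin(np.abs(TEMPLATE_LEVELS - level))])


def simulate_inflow_stack(config: InflowScenario) -> tuple[FrameStack, InflowTruth]:
    """Fluorescence frame stack with rendered laser indicator and known truth.

    The noiseless normalised fluorescence is a ramp: background until the
    onset, then ``slope_true`` units/s up to the plateau. The laser level
    starts at 1, falls linearly during the rise and settles at
    ``laser_floor`` when fluorescence peaks (that settling time is the
    ground-truth time to peak); levels are quantised to the template bank.
    Raw pixel intensity is fluorescence times laser level plus noise.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration_s * config.frame_rate_hz)) + 1
    t = np.arange(n_frames) / config.frame_rate_hz
    plateau = config.plateau
    fluor = np.clip((t - config.t0_true_s) * config.slope_true, 0.0, plateau)
    ttp_true = config.t0_true_s + config.rise_duration_s

    laser_raw = np.where(
        t < config.t0_true_s,
        1.0,
        np.where(
            t < ttp_true,
            1.0 - (1.0 - config.laser_floor) * (t - config.t0_true_s) / config.rise_duration_s,
            config.laser_floor,
        ),
    )
    laser = np.array([_quantize_level(v) for v in laser_raw])
    # quantisation moves the observable plateau onset slightly before t0 + rise
    floor_q = _quantize_level(config.laser_floor)
    ttp_true = float(t[np.argmax(laser <= floor_q + 1e-12)])

    noise_sd_curve = config.noise_sd_curve if config.noise_sd_curve is not None else plateau / 10.0
    h, w = config.frame_height, config.frame_width
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = config.roi.center_xy
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= config.roi.radius_px**2
    pixel_sd = noise_sd_curve * np.sqrt(disc.sum())

    # background is residual laser-excited signal, so it scales with the
    # excitation level and divides out in the normalisation
    frames = np.broadcast_to(config.background_level * laser[:, None, None], (n_frames, h, w)).astype(float)
    frames = frames.copy()
    frames[:, disc] += fluor[:, None] * laser[:, None]
    if pixel_sd > 0:
        frames += rng.normal(0.0, pixel_sd, frames.shape)
    ix, iy, iw, ih = config.indicator_region
    for k in range(n_frames):
        frames[k, iy : iy + ih, ix : ix + iw] = render_indicator(
            laser[k], config.indicator_noise_sd, rng
        )
    stack = FrameStack(frames=frames, frame_rate_hz=config.frame_rate_hz, t0_admin_s=0.0)
    truth = InflowTruth(
        t0_true_s=config.t0_true_s,
        slope_true=config.slope_true,
        plateau=plateau,
        ttp_true_s=ttp_true,
        laser_series=laser,
        fluorescence=fluor + config.background_level,
    )
    return stack, truth


def simulate_border_image(config: BorderScenario) -> tuple[np.ndarray, float]:
    """Falling logistic border image; returns the image and the true x0."""
    rng = np.random.default_rng(config.seed)
    x = np.arange(config.width, dtype=float)
    profile = config.low + (config.high - config.low) * _falling_sigmoid(x, config.x0_px, config.width_px)
    image = np.broadcast_to(profile, (config.height, config.width)).copy()
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd * (config.high - config.low), image.shape)
    return image, float(config.x0_px)


@dataclass
class CaseScenario:
    """One complete synthetic surgical case (cubes + video + annotations).

    The pre-cube is ICG-free; the intra-cube carries the absorption dip on
    the perfused (proximal) side. Fluorescence in the video scales with the
    same proximal-to-distal concentration profile, so perfused ROIs show a
    full inflow, ischemic ROIs none. The clinical marker may be offset from
    the true border to emulate a clinician's deviation.
    """

    seed: int = 0
    height: int = 120
    width: int = 160
    border_x0_px: float = 80.0
    border_width_px: float = 8.0
    marker_offset_px: float = 0.0
    t0_true_s: float = 20.0
    slope_true: float = 25.0
    rise_duration_s: float = 8.0
    frame_rate_hz: float = 5.0
    duration_s: float = 60.0
    pixel_noise_sd: float = 8.0  # gray levels per video pixel
    laser_floor: float = 0.5
    case_id: str = "case"


def simulate_case(directory, config: CaseScenario) -> dict:
    """Write a full case directory consumable by the pipeline; returns truth.

    Layout: ``pre.hdr/.raw``, ``intra.hdr/.raw``, ``frames.tiff``,
    ``frames.yaml``, ``templates/``, ``annotations.json``, ``truth.json``.
    """
    import json
    from pathlib import Path

    import imageio.v3 as iio
    import tifffile
    import yaml

    from .annotations import AnnotationSet, write_annotations
    from .hsi_cube import write_cube

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = dict(
        height=config.height,
        width=config.width,
        border_x0_px=config.border_x0_px,
        border_width_px=config.border_width_px,
    )
    pre_cube, _ = simulate_cube(
        CubeScenario(seed=config.seed, icg_present=False, acquisition_tag="pre", **base)
    )
    intra_cube, cube_truth = simulate_cube(
        CubeScenario(seed=config.seed + 1, icg_present=True, acquisition_tag="intra", **base)
    )
    write_cube(pre_cube, directory / "pre.hdr")
    write_cube(intra_cube, directory / "intra.hdr")

    # fluorescence video: inflow ramp scaled by the proximal concentration
    rng = np.random.default_rng(config.seed + 2)
    n_frames = int(round(config.duration_s * config.frame_rate_hz)) + 1
    t = np.arange(n_frames) / config.frame_rate_hz
    plateau = config.slope_true * config.rise_duration_s
    fluor = np.clip((t - config.t0_true_s) * config.slope_true, 0.0, plateau)
    ttp = config.t0_true_s + config.rise_duration_s
    laser_raw = np.where(
        t < config.t0_true_s,
        1.0,
        np.where(t < ttp, 1.0 - (1.0 - config.laser_floor) * (t - config.t0_true_s) / config.rise_duration_s, config.laser_floor),
    )
    laser = np.array([_quantize_level(v) for v in laser_raw])
    conc_x = _falling_sigmoid(np.arange(config.width, dtype=float), config.border_x0_px, config.border_width_px)
    signal = 2.0 * laser[:, None, None] + fluor[:, None, None] * laser[:, None, None] * conc_x[None, None, :]
    frames = np.broadcast_to(signal, (n_frames, config.height, config.width)).astype(float)
    frames = frames + rng.normal(0.0, config.pixel_noise_sd, frames.shape)
    ih, iw = INDICATOR_SHAPE
    ix, iy = config.width - iw - 1, 1
    for k in range(n_frames):
        frames[k, iy : iy + ih, ix : ix + iw] = render_indicator(laser[k], 2.0, rng)
    frames = np.clip(frames, 0, 255).astype(np.uint8)
    tifffile.imwrite(directory / "frames.tiff", frames)

    templates_dir = directory / "templates"
    templates_dir.mkdir(exist_ok=True)
    for level, template in make_template_bank():
        iio.imwrite(templates_dir / f"level_{level:.2f}.png", np.clip(template, 0, 255).astype(np.uint8))
    with open(directory / "frames.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "frame_rate_hz": config.frame_rate_hz,
                "indicator": {"x": int(ix), "y": int(iy), "w": int(iw), "h": int(ih)},
                "templates_dir": str(templates_dir),
            },
            fh,
        )

    y_mid = config.height / 2.0
    rois = [
        CircularROI((config.border_x0_px - 50.0, y_mid), 8.0, "proximal", "perfused"),
        CircularROI((config.border_x0_px, y_mid), 8.0, "border", "transition"),
        CircularROI((config.border_x0_px + 50.0, y_mid), 8.0, "distal", "ischemic"),
    ]
    marker = (config.border_x0_px + config.marker_offset_px, y_mid)
    lines = [
        ((10.0, y_mid - 30.0), (config.width - 10.0, y_mid - 30.0)),
        ((10.0, y_mid), (config.width - 10.0, y_mid)),
        ((10.0, y_mid + 30.0), (config.width - 10.0, y_mid + 30.0)),
    ]
    write_annotations(
        AnnotationSet(
            rois=rois,
            ruler=((10.0, 10.0), (110.0, 10.0), 1.0),  # 100 px = 1 cm
            clinical_marker=marker,
            profile_lines=lines,
        ),
        directory / "annotations.json",
    )
    truth = {
        "case_id": config.case_id,
        "border_x0_px": config.border_x0_px,
        "marker_offset_px": config.marker_offset_px,
        "t0_true_s": config.t0_true_s,
        "slope_true": config.slope_true,
        "ttp_true_s": ttp,
        "scale_cm_per_px": 0.01,
        "n_glare_px": int(cube_truth.glare_mask.sum()),
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth


def simulate_cohort(config: CohortScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case signed border distances (cm) per modality, plus a truth table.

    Each modality's distance is its true offset plus independent Gaussian
    noise with sd ``sd_paired_diff_cm / sqrt(2)``, so differences between any
    two modalities have sd ``sd_paired_diff_cm``.
    """
    rng = np.random.default_rng(config.seed)
    per_modality_sd = config.sd_paired_diff_cm / np.sqrt(2.0)
    modalities = sorted(config.offsets_cm)
    data = {
        m: config.offsets_cm[m] + rng.normal(0.0, per_modality_sd, config.n_cases)
        for m in modalities
    }
    distances = pd.DataFrame(data, index=pd.RangeIndex(config.n_cases, name="case"))
    truth = pd.DataFrame(
        {
            "modality": modalities,
            "offset_cm": [config.offsets_cm[m] for m in modalities],
            "per_modality_sd_cm": per_modality_sd,
        }
    )
    return distances, truth
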