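"""Band-ratio engine for HSI tissue parameter maps on the 0-100 scale.

Clinical HSI cameras derive false-colour tissue parameters - StO2
(superficial tissue oxygenation), NIR PI (near-infrared perfusion index),
OHI (organ haemoglobin index) and TWI (tissue water index) - from
reflectance ratios within selected spectral ranges. The vendor formulas are
proprietary; this engine is fully configuration-driven and ships plausible
default window pairs that are explicitly NON-authoritative approximations,
useful for pipeline exercise but not as validated clinical formulas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigError, RangeError, ValidationError
from .hsi_cube import HSCube

__all__ = [
    "IndexDefinition",
    "ParameterMap",
    "DEFAULT_DEFINITIONS",
    "compute_index_map",
    "compute_all",
    "load_definitions",
]

log = logging.getLogger(__name__)

TRANSFORMS = ("reflectance", "absorbance")
_LOG_FLOOR = 1e-6  # reflectance floor before -log in the absorbance transform


@dataclass(frozen=True)
class IndexDefinition:
    """One band-ratio tissue index: ratio of window means, affinely scaled."""

    name: str
    numerator_window_nm: tuple[float, float]
    denominator_window_nm: tuple[float, float]
    transform: str = "reflectance"
    gain: float = 100.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        for lo, hi in (self.numerator_window_nm, self.denominator_window_nm):
            if not lo < hi:
                raise ValidationError(f"index {self.name!r}: window must satisfy lo < hi")
        if self.transform not in TRANSFORMS:
            raise ValidationError(f"index {self.name!r}: unknown transform {self.transform!r}")
        if self.gain == 0:
            raise ValidationError(f"index {self.name!r}: gain must be nonzero")


@dataclass
class ParameterMap:
    """A 2-D tissue-parameter image clipped to [0, 100]."""

    values: np.ndarray
    name: str
    acquisition_tag: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("parameter map must be 2-D")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValidationError("parameter values must lie in [0, 100]")


# Approximate window pairs; the vendor's exact formulas are unpublished.
# Gains/offsets place typical tissue ratios mid-scale: oxygenation varies
# inversely with the 570-590 nm haemoglobin absorbance, hence the negative
# StO2 gain.
DEFAULT_DEFINITIONS: dict[str, IndexDefinition] = {
    "StO2": IndexDefinition("StO2", (570.0, 590.0), (740.0, 780.0), "absorbance", -150.0, 240.0),
    "NIR_PI": IndexDefinition("NIR_PI", (655.0, 735.0), (825.0, 925.0), "absorbance", 50.0, 0.0),
    "OHI": IndexDefinition("OHI", (530.0, 590.0), (785.0, 825.0), "absorbance", 60.0, 0.0),
    "TWI": IndexDefinition("TWI", (880.0, 900.0), (955.0, 980.0), "absorbance", 70.0, 0.0),
}


def _window_mean(cube: HSCube, window: tuple[float, float], transform: str, name: str) -> np.ndarray:
    lo, hi = window
    wl = cube.wavelengths_nm
    if lo < wl[0] or hi > wl[-1]:
        raise RangeError(f"index {name!r}: window [{lo}, {hi}] nm outside grid [{wl[0]}, {wl[-1]}] nm")
    members = (wl >= lo) & (wl <= hi)
    if not members.any():
        raise RangeError(f"index {name!r}: no band centres inside [{lo}, {hi}] nm")
    block = cube.data[:, :, members].astype(float)
    if transform == "absorbance":
        block = -np.log(np.maximum(block, _LOG_FLOOR))
    return block.mean(axis=2)


def compute_index_map(cube: HSCube, definition: IndexDefinition) -> ParameterMap:
    """Per-pixel ratio of window means, affinely mapped and clipped to [0, 100].

    Pixels whose denominator mean has magnitude <= 1e-12 get value 0; their
    count is reported through a warning log record.
    """
    num = _window_mean(cube, definition.numerator_window_nm, definition.transform, definition.name)
    den = _window_mean(cube, definition.denominator_window_nm, definition.transform, definition.name)
    degenerate = np.abs(den) <= 1e-12
    n_bad = int(degenerate.sum())
    if n_bad:
        log.warning("index %s: %d pixels with degenerate denominator set to 0", definition.name, n_bad)
    ratio = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    values = np.clip(definition.gain * ratio + definition.offset, 0.0, 100.0)
    values[degenerate] = 0.0
    return ParameterMap(values=values, name=definition.name, acquisition_tag=cube.acquisition_tag)


def compute_all(cube: HSCube, definitions: dict[str, IndexDefinition]) -> dict[str, ParameterMap]:
    """Compute one map per definition, ordered deterministically by name."""
    names = [d.name for d in definitions.values()]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate index names in definition set")
    return {name: compute_index_map(cube, definitions[name]) for name in sorted(definitions)}


def load_definitions(path) -> dict[str, IndexDefinition]:
    """Load index definitions from a YAML file mirroring IndexDefinition fields."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    defs: dict[str, IndexDefinition] = {}
    for name, spec in doc.items():
        if name in defs:
            raise ConfigError(f"duplicate index name {name!r}")
        try:
            defs[name] = IndexDefinition(
                name=name,
                numerator_window_nm=tuple(spec["numerator_window_nm"]),
                denominator_window_nm=tuple(spec["denominator_window_nm"]),
                transform=spec.get("transform", "reflectance"),
                gain=float(spec.get("gain", 100.0)),
                offset=float(spec.get("offset", 0.0)),
            )
        except KeyError as exc:
            raise ConfigError(f"index {name!r} missing field {exc}") from exc
    return defs
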