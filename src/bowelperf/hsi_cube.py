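"""Hyperspectral reflectance cubes: data model, ENVI/raw I/O and ROI spectra.

The camera emulated here covers 500-995 nm at 5 nm steps (100 bands) and
delivers reflectance-calibrated cubes of 640 x 480 pixels, but any uniform
grid covering the near-infrared ICG window (750-850 nm) is accepted.

Coordinate convention: 0-based pixels, ``x`` is the column and ``y`` the row.
A circular ROI contains every pixel whose centre satisfies
``(px - x)**2 + (py - y)**2 <= r**2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, RangeError, ShapeError, ValidationError

__all__ = [
    "HSCube",
    "CircularROI",
    "read_cube",
    "write_cube",
    "band_index",
    "extract_mean_spectrum",
    "roi_mask",
]

ACQUISITION_TAGS = ("pre", "intra", "post")

# ENVI data-type codes for the dtypes we round-trip.
_ENVI_DTYPES = {4: np.dtype("float32"), 5: np.dtype("float64")}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}
_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class HSCube:
    """A reflectance image cube indexed ``(row, col, band)``."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    acquisition_tag: str | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.validate()

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(f"cube data must be 3-D (row, col, band), got ndim={self.data.ndim}")
        if self.data.shape[2] == 0:
            raise ValidationError("cube has zero bands")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise ValidationError(
                f"wavelength count {len(self.wavelengths_nm)} != band dimension {self.data.shape[2]}"
            )
        if len(self.wavelengths_nm) > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("reflectance values must be finite")
        if np.any(self.data < 0):
            raise ValidationError("negative reflectance values are not allowed")
        if self.acquisition_tag is not None and self.acquisition_tag not in ACQUISITION_TAGS:
            raise ValidationError(
                f"acquisition_tag must be one of {ACQUISITION_TAGS}, got {self.acquisition_tag!r}"
            )

    def grid_spacing_nm(self) -> float:
        """Uniform wavelength spacing; raises if the grid is non-uniform."""
        steps = np.diff(self.wavelengths_nm)
        if len(steps) == 0:
            raise ValidationError("single-band cube has no spacing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValidationError("wavelength grid is not uniform; resample before derivative analysis")
        return float(steps[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HSCube):
            return NotImplemented
        return (
            self.data.dtype == other.data.dtype
            and self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and self.acquisition_tag == other.acquisition_tag
            and self.meta == other.meta
        )


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest with a perfusion-class label."""

    center_xy: tuple[float, float]
    radius_px: float
    label: str = ""
    perfusion_class: str | None = None

    PERFUSION_CLASSES = ("perfused", "transition", "ischemic")

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValidationError(f"ROI radius must be >= 1 px, got {self.radius_px}")
        if self.perfusion_class is not None and self.perfusion_class not in self.PERFUSION_CLASSES:
            raise ValidationError(f"unknown perfusion class {self.perfusion_class!r}")

    def check_inside(self, height: int, width: int) -> None:
        x, y = self.center_xy
        r = self.radius_px
        if x - r < 0 or y - r < 0 or x + r > width - 1 or y + r > height - 1:
            raise ValidationError(
                f"ROI at ({x}, {y}) r={r} touches or exceeds the {width}x{height} image bounds"
            )


def roi_mask(roi: CircularROI, height: int, width: int) -> np.ndarray:
    """Boolean membership mask of the ROI disc on pixel centres."""
    roi.check_inside(height, width)
    yy, xx = np.mgrid[0:height, 0:width]
    cx, cy = roi.center_xy
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= roi.radius_px**2


# --------------------------------------------------------------------------
# ENVI header + binary I/O
# --------------------------------------------------------------------------


_HEADER_FIELD = re.compile(r"^[ \t]*([^=\n]+?)[ \t]*=[ \t]*(\{[^}]*\}|[^\n]*)", re.M | re.S)


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing 'ENVI' magic line in header")
    fields: dict[str, str] = {}
    body = text.lstrip()[4:]
    for match in _HEADER_FIELD.finditer(body):
        key = match.group(1).strip().lower()
        value = match.group(2).strip()
        if value.startswith("{"):
            if not value.endswith("}"):
                raise FormatError(f"unterminated brace value for header field {key!r}")
            value = value[1:-1].strip()
        fields[key] = value
    return fields


def _require(fields: dict[str, str], name: str) -> str:
    if name not in fields:
        raise FormatError(f"ENVI header missing required field {name!r}")
    return fields[name]


def _read_envi(hdr_path: Path) -> HSCube:
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        lines = int(_require(fields, "lines"))
        samples = int(_require(fields, "samples"))
        bands = int(_require(fields, "bands"))
        dtype_code = int(_require(fields, "data type"))
        byte_order = int(fields.get("byte order", "0"))
        offset = int(fields.get("header offset", "0"))
    except ValueError as exc:
        raise FormatError(f"non-numeric ENVI header field: {exc}") from exc
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    wl_text = _require(fields, "wavelength")
    try:
        wavelengths = np.array([float(w) for w in wl_text.replace("\n", " ").split(",") if w.strip()])
    except ValueError as exc:
        raise FormatError(f"garbled wavelength list: {exc}") from exc

    dtype = _ENVI_DTYPES[dtype_code].newbyteorder(">" if byte_order == 1 else "<")
    bin_path = _binary_for_header(hdr_path)
    payload = bin_path.read_bytes()[offset:]
    expected = lines * samples * bands * dtype.itemsize
    if len(payload) != expected:
        raise ShapeError(
            f"{bin_path} holds {len(payload)} bytes, expected {expected} "
            f"for {lines}x{samples}x{bands} {dtype}"
        )
    flat = np.frombuffer(payload, dtype=dtype)
    data = _deinterleave(flat, lines, samples, bands, interleave)
    meta = {
        k: v
        for k, v in fields.items()
        if k.startswith("bowelperf ") and k != "bowelperf acquisition tag"
    }
    meta = {k.removeprefix("bowelperf "): v for k, v in meta.items()}
    tag = fields.get("bowelperf acquisition tag") or None
    return HSCube(
        data=np.ascontiguousarray(data).astype(_ENVI_DTYPES[dtype_code], copy=False),
        wavelengths_nm=wavelengths,
        acquisition_tag=tag,
        meta=meta,
    )


def _binary_for_header(hdr_path: Path) -> Path:
    for suffix in (".raw", ".img", ".dat", ""):
        cand = hdr_path.with_suffix(suffix)
        if cand != hdr_path and cand.exists():
            return cand
    raise FormatError(f"no binary companion found for {hdr_path}")


def _deinterleave(flat: np.ndarray, lines: int, samples: int, bands: int, interleave: str) -> np.ndarray:
    if interleave == "bsq":
        return flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    if interleave == "bil":
        return flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    return flat.reshape(lines, samples, bands)  # bip


def _interleave(data: np.ndarray, interleave: str) -> np.ndarray:
    if interleave == "bsq":
        return data.transpose(2, 0, 1)
    if interleave == "bil":
        return data.transpose(0, 2, 1)
    return data  # bip


def write_cube(cube: HSCube, path: str | Path, interleave: str = "bsq") -> None:
    """Write an ENVI header/binary pair such that :func:`read_cube` inverts it.

    ``path`` may point at either member of the pair; ``.hdr`` and ``.raw``
    siblings are written.
    """
    cube.validate()
    if interleave not in _INTERLEAVES:
        raise ValidationError(f"interleave must be one of {_INTERLEAVES}")
    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        raise ValidationError(f"only float32/float64 cubes are written, got {dtype}")
    path = Path(path)
    hdr_path, bin_path = path.with_suffix(".hdr"), path.with_suffix(".raw")
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths_nm)
    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {cube.width}",
        f"lines = {cube.height}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"wavelength = {{ {wl} }}",
        "wavelength units = Nanometers",
    ]
    if cube.acquisition_tag:
        lines.append(f"bowelperf acquisition tag = {cube.acquisition_tag}")
    for key, value in sorted(cube.meta.items()):
        lines.append(f"bowelperf {key} = {value}")
    hdr_path.write_text("\n".join(lines) + "\n")
    payload = _interleave(np.ascontiguousarray(cube.data), interleave)
    bin_path.write_bytes(np.ascontiguousarray(payload).astype(dtype.newbyteorder("<")).tobytes())


def _read_raw(path: Path, layout: dict) -> HSCube:
    for key in ("height", "width", "bands"):
        if key not in layout:
            raise FormatError(f"raw layout missing {key!r}")
    height, width, bands = int(layout["height"]), int(layout["width"]), int(layout["bands"])
    interleave = str(layout.get("interleave", "bsq")).lower()
    if interleave not in _INTERLEAVES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    byte_order = str(layout.get("byte_order", "little")).lower()
    if byte_order not in ("little", "big"):
        raise FormatError(f"byte_order must be 'little' or 'big', got {byte_order!r}")
    dtype = np.dtype("float32").newbyteorder("<" if byte_order == "little" else ">")
    if "wavelengths" in layout:
        wavelengths = np.asarray(layout["wavelengths"], dtype=float)
    elif "wavelength_start_nm" in layout and "wavelength_step_nm" in layout:
        start, step = float(layout["wavelength_start_nm"]), float(layout["wavelength_step_nm"])
        wavelengths = start + step * np.arange(bands)
    else:
        raise FormatError("raw layout must give 'wavelengths' or wavelength_start_nm/step_nm")
    payload = path.read_bytes()
    expected = height * width * bands * 4
    if len(payload) != expected:
        raise ShapeError(f"{path} holds {len(payload)} bytes, expected {expected}")
    data = _deinterleave(np.frombuffer(payload, dtype=dtype), height, width, bands, interleave)
    return HSCube(
        data=np.ascontiguousarray(data).astype(np.float32, copy=False),
        wavelengths_nm=wavelengths,
        acquisition_tag=layout.get("acquisition_tag"),
        meta={str(k): str(v) for k, v in layout.get("meta", {}).items()},
    )


def read_cube(path: str | Path, layout: dict | None = None) -> HSCube:
    """Read a cube from an ENVI pair or a raw float32 file.

    ``layout`` selects the format: ``{"format": "envi"}`` (default when the
    path ends in ``.hdr``) or ``{"format": "raw_float32", ...}`` with
    height/width/bands, interleave, byte order and the wavelength grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (layout or {}).get("format", "envi" if path.suffix == ".hdr" else None)
    if fmt == "envi" or fmt is None and path.suffix == ".hdr":
        return _read_envi(path)
    if fmt == "raw_float32":
        return _read_raw(path, layout or {})
    raise FormatError(f"unknown cube format {fmt!r}; use 'envi' or 'raw_float32'")


def band_index(cube: HSCube, wavelength_nm: float) -> int:
    """Index of the band centre nearest ``wavelength_nm``; ties go lower.

    Raises :class:`RangeError` for wavelengths outside the grid span.
    """
    wl = cube.wavelengths_nm
    if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
        raise RangeError(f"{wavelength_nm} nm outside grid [{wl[0]}, {wl[-1]}] nm")
    # argmin returns the first (lower-wavelength) index on exact ties
    return int(np.argmin(np.abs(wl - wavelength_nm)))


def extract_mean_spectrum(cube: HSCube, roi: CircularROI) -> np.ndarray:
    """Arithmetic mean spectrum over the pixels of the ROI disc."""
    mask = roi_mask(roi, cube.height, cube.width)
    return cube.data[mask].mean(axis=0)
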