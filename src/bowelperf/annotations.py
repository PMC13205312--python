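"""Annotation files: circular ROIs, ruler calibration, clinical marker, profiles.

JSON schema::

    {
      "rois": [{"x": .., "y": .., "r": .., "label": "..", "class": "perfused"}],
      "ruler": {"p0": [x, y], "p1": [x, y], "cm": 1.0},
      "clinical_marker": [x, y],
      "profile_lines": [{"p0": [x, y], "p1": [x, y]}]
    }

All coordinates are 0-based pixels (x = column, y = row). Profile lines run
proximal (well-perfused, ``p0``) to distal (``p1``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError
from .hsi_cube import CircularROI

__all__ = ["AnnotationSet", "read_annotations", "write_annotations"]

Point = tuple[float, float]


@dataclass
class AnnotationSet:
    rois: list[CircularROI] = field(default_factory=list)
    ruler: tuple[Point, Point, float] | None = None  # (p0, p1, known length in cm)
    clinical_marker: Point | None = None
    profile_lines: list[tuple[Point, Point]] = field(default_factory=list)


def _point(obj, where: str) -> Point:
    try:
        x, y = obj
        return (float(x), float(y))
    except (TypeError, ValueError) as exc:
        raise FormatError(f"bad point in {where}: {obj!r}") from exc


def read_annotations(path: str | Path) -> AnnotationSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"annotation file is not valid JSON: {exc}") from exc
    rois = []
    for entry in doc.get("rois", []):
        try:
            rois.append(
                CircularROI(
                    center_xy=(float(entry["x"]), float(entry["y"])),
                    radius_px=float(entry["r"]),
                    label=str(entry.get("label", "")),
                    perfusion_class=entry.get("class"),
                )
            )
        except KeyError as exc:
            raise FormatError(f"ROI entry missing field {exc}") from exc
    ruler = None
    if "ruler" in doc and doc["ruler"] is not None:
        r = doc["ruler"]
        ruler = (_point(r["p0"], "ruler"), _point(r["p1"], "ruler"), float(r["cm"]))
    marker = _point(doc["clinical_marker"], "clinical_marker") if doc.get("clinical_marker") else None
    profiles = [
        (_point(line["p0"], "profile_lines"), _point(line["p1"], "profile_lines"))
        for line in doc.get("profile_lines", [])
    ]
    return AnnotationSet(rois=rois, ruler=ruler, clinical_marker=marker, profile_lines=profiles)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    doc: dict = {
        "rois": [
            {
                "x": roi.center_xy[0],
                "y": roi.center_xy[1],
                "r": roi.radius_px,
                "label": roi.label,
                "class": roi.perfusion_class,
            }
            for roi in ann.rois
        ],
        "profile_lines": [{"p0": list(p0), "p1": list(p1)} for p0, p1 in ann.profile_lines],
    }
    if ann.ruler is not None:
        p0, p1, cm = ann.ruler
        doc["ruler"] = {"p0": list(p0), "p1": list(p1), "cm": cm}
    if ann.clinical_marker is not None:
        doc["clinical_marker"] = list(ann.clinical_marker)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
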