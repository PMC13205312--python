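"""Pre/intra/post shift of HSI tissue parameters per perfusion class.

ICG absorbs within the spectral windows some tissue indices use, so its
presence could distort them. The shift analysis takes ROI means of each
parameter map before (pre) and after (intra, post) ICG administration and
summarises the differences intra-pre and post-pre per perfusion class with
median and interquartile range. Output is purely descriptive: with this
acquisition protocol, temporal drift and ICG presence cannot be separated,
so no hypothesis tests are attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hsi_cube import CircularROI, roi_mask
from .tissue_indices import ParameterMap

__all__ = ["ShiftSummary", "roi_parameter_value", "shift_summary"]

log = logging.getLogger(__name__)

COMPARISONS = ("intra-pre", "post-pre")


def roi_parameter_value(pmap: ParameterMap, roi: CircularROI) -> float:
    """Mean parameter value over the ROI disc."""
    height, width = pmap.values.shape
    mask = roi_mask(roi, height, width)
    return float(pmap.values[mask].mean())


@dataclass
class ShiftSummary:
    """Median/IQR of parameter differences per (parameter, comparison, class)."""

    table: pd.DataFrame  # columns: parameter, comparison, perfusion_class, median, iqr, n_rois

    def cell(self, parameter: str, comparison: str, perfusion_class: str) -> pd.Series:
        t = self.table
        match = t[
            (t.parameter == parameter)
            & (t.comparison == comparison)
            & (t.perfusion_class == perfusion_class)
        ]
        if match.empty:
            raise KeyError((parameter, comparison, perfusion_class))
        return match.iloc[0]


def shift_summary(
    maps: dict[str, dict[str, ParameterMap]], rois: list[CircularROI]
) -> ShiftSummary:
    """Summarise parameter shifts on ROI means.

    ``maps`` is keyed by acquisition tag ('pre' mandatory, 'intra'/'post'
    optional) then parameter name; ROI geometry is shared across
    acquisitions. Classes without any ROI are omitted with a warning.
    """
    if "pre" not in maps:
        raise ValidationError("shift analysis requires the pre-administration maps")
    if not any(tag in maps for tag in ("intra", "post")):
        raise ValidationError("shift analysis requires an intra or post acquisition")
    classed = [r for r in rois if r.perfusion_class is not None]
    if not classed:
        raise ValidationError("no ROI carries a perfusion class")
    present = {r.perfusion_class for r in classed}
    for cls in CircularROI.PERFUSION_CLASSES:
        if cls not in present:
            log.warning("perfusion class %r has no ROIs; cells omitted", cls)

    rows = []
    for comparison in COMPARISONS:
        later = comparison.split("-")[0]
        if later not in maps:
            continue
        for parameter in sorted(maps["pre"]):
            if parameter not in maps[later]:
                raise ValidationError(f"parameter {parameter!r} missing from {later} maps")
            for cls in CircularROI.PERFUSION_CLASSES:
                cls_rois = [r for r in classed if r.perfusion_class == cls]
                if not cls_rois:
                    continue
                diffs = np.array(
                    [
                        roi_parameter_value(maps[later][parameter], r)
                        - roi_parameter_value(maps["pre"][parameter], r)
                        for r in cls_rois
                    ]
                )
                q1, q3 = np.percentile(diffs, [25, 75])
                rows.append(
                    {
                        "parameter": parameter,
                        "comparison": comparison,
                        "perfusion_class": cls,
                        "median": float(np.median(diffs)),
                        "iqr": float(q3 - q1),
                        "n_rois": len(diffs),
                    }
                )
    return ShiftSummary(table=pd.DataFrame(rows))
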