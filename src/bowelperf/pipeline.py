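"""End-to-end case and cohort orchestration.

A case bundles up to three hyperspectral acquisitions (pre-administration
cube mandatory; intra- and/or post-cube for reconstruction and shift
analysis), an optional ICG fluorescence frame stack, and an annotation file
(ROIs, ruler, clinical marker, profile lines). ``run_case`` produces tissue
index maps, the reconstructed ICG image, per-ROI inflow metrics, border
distances per modality and the parameter-shift table; ``run_cohort``
aggregates per-case border distances into the paired modality comparison.
Stages with missing inputs are recorded as skipped and do not block the
rest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import border_geometry, cohort_stats, icg_reconstruction, inflow, parameter_shift, tissue_indices
from .annotations import AnnotationSet, read_annotations
from .errors import InsufficientCasesError, ValidationError
from .hsi_cube import HSCube, read_cube

__all__ = ["CaseBundle", "PipelineConfig", "run_case", "run_cohort"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the study replica with its standard default."""

    sigma_bands: float = 4.44
    band_window_nm: tuple[float, float] = (790.0, 810.0)
    median_kernel: int = 7
    percentile: float = 99.0
    movmean_window_s: float = 3.0
    noise_window_s: tuple[float, float] = (3.0, 6.0)
    slope_fraction: float = 0.5
    profile_step_px: float = 0.5
    profile_smooth_window: int = 5
    delta_cm: float = 0.5
    alpha: float = 0.05
    thresholds: dict = field(default_factory=lambda: dict(inflow.DEFAULT_THRESHOLDS))
    index_definitions: dict = field(default_factory=lambda: dict(tissue_indices.DEFAULT_DEFINITIONS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "sigma_bands",
            "median_kernel",
            "percentile",
            "movmean_window_s",
            "slope_fraction",
            "profile_step_px",
            "profile_smooth_window",
            "delta_cm",
            "alpha",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        if "band_window_nm" in doc:
            kwargs["band_window_nm"] = tuple(doc["band_window_nm"])
        if "noise_window_s" in doc:
            kwargs["noise_window_s"] = tuple(doc["noise_window_s"])
        if "thresholds" in doc:
            kwargs["thresholds"] = dict(doc["thresholds"])
        return cls(**kwargs)

    def reconstruction_params(self) -> icg_reconstruction.ReconstructionParams:
        return icg_reconstruction.ReconstructionParams(
            sigma_bands=self.sigma_bands,
            band_window_nm=self.band_window_nm,
            median_kernel=self.median_kernel,
            percentile=self.percentile,
        )


@dataclass
class CaseBundle:
    """Paths of one case's acquisitions; pre-cube and annotations mandatory."""

    case_id: str
    annotations: str | Path
    pre_cube: str | Path
    intra_cube: str | Path | None = None
    post_cube: str | Path | None = None
    frames: str | Path | None = None
    frame_rate_hz: float | None = None
    indicator: tuple[int, int, int, int] | None = None
    templates_dir: str | Path | None = None
    truth: str | Path | None = None

    def validate(self) -> None:
        if not Path(self.annotations).exists():
            raise ValidationError(f"case {self.case_id}: annotation file missing")
        if not Path(self.pre_cube).exists():
            raise ValidationError(f"case {self.case_id}: pre-cube missing")
        if self.intra_cube is None and self.post_cube is None:
            raise ValidationError(f"case {self.case_id}: need an intra or post cube for reconstruction")
        if self.frames is not None and self.frame_rate_hz is None:
            raise ValidationError(f"case {self.case_id}: frame stack given without frame rate")

    @classmethod
    def from_dir(cls, directory: str | Path) -> "CaseBundle":
        """Assemble a bundle from a case directory written by the simulator/CLI.

        Expects ``annotations.json``, ``pre.hdr`` and optionally
        ``intra.hdr``/``post.hdr``, ``frames/`` with ``frames.yaml`` metadata,
        and ``truth.json``.
        """
        d = Path(directory)
        meta = {}
        meta_path = d / "frames.yaml"
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = yaml.safe_load(fh) or {}
        indicator = meta.get("indicator")
        return cls(
            case_id=d.name,
            annotations=d / "annotations.json",
            pre_cube=d / "pre.hdr",
            intra_cube=(d / "intra.hdr") if (d / "intra.hdr").exists() else None,
            post_cube=(d / "post.hdr") if (d / "post.hdr").exists() else None,
            frames=next((p for p in (d / "frames", d / "frames.tiff", d / "frames.tif") if p.exists()), None),
            frame_rate_hz=meta.get("frame_rate_hz"),
            indicator=tuple(indicator[k] for k in ("x", "y", "w", "h")) if indicator else None,
            templates_dir=meta.get("templates_dir"),
            truth=(d / "truth.json") if (d / "truth.json").exists() else None,
        )


def _inflow_table(
    stack: inflow.FrameStack,
    ann: AnnotationSet,
    bundle: CaseBundle,
    config: PipelineConfig,
) -> pd.DataFrame:
    templates = (
        inflow.load_template_bank(bundle.templates_dir) if bundle.templates_dir else None
    )
    laser = inflow.laser_levels(stack, bundle.indicator, templates)
    ttp = inflow.time_to_peak(stack.times_s(), laser)
    rows = []
    for roi in ann.rois:
        curve = inflow.build_curve(
            stack, roi, bundle.indicator, templates, window_s=config.movmean_window_s
        )
        b = inflow.background_noise(curve, config.noise_window_s)
        try:
            t0 = inflow.t0_objective(curve, b, search_from_s=config.noise_window_s[1])
            slope = inflow.inflow_slope(curve, t0, fraction=config.slope_fraction)
        except Exception as exc:  # per-ROI failure must not sink the case
            log.warning("ROI %r inflow failed: %s", roi.label, exc)
            rows.append(
                {"label": roi.label, "class": roi.perfusion_class, "B": b, "t0_s": np.nan,
                 "slope_units_per_s": np.nan, "ttp_s": ttp, "error": str(exc)}
            )
            continue
        metrics = inflow.InflowMetrics(
            background_noise_B=b, t0_objective_s=t0, slope_units_per_s=slope, ttp_s=ttp
        )
        flags = inflow.classify_thresholds(metrics, config.thresholds)
        row = {
            "label": roi.label,
            "class": roi.perfusion_class,
            "B": b,
            "t0_s": t0,
            "slope_units_per_s": slope,
            "ttp_s": ttp,
            "error": "",
        }
        row.update(flags)
        rows.append(row)
    return pd.DataFrame(rows)


def run_case(bundle: CaseBundle, config: PipelineConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run every stage of the study replica for one case.

    Returns a report dict with DataFrames/arrays per stage and a
    ``skipped`` list naming stages that lacked inputs. With ``out_dir`` set,
    CSVs, float TIFF maps and a log of stage parameters are written.
    """
    config = config or PipelineConfig()
    bundle.validate()
    report: dict = {"case_id": bundle.case_id, "skipped": [], "params": {}}
    ann = read_annotations(bundle.annotations)

    cubes: dict[str, HSCube] = {"pre": read_cube(bundle.pre_cube)}
    if bundle.intra_cube is not None:
        cubes["intra"] = read_cube(bundle.intra_cube)
    if bundle.post_cube is not None:
        cubes["post"] = read_cube(bundle.post_cube)

    # tissue index maps per acquisition
    maps = {tag: tissue_indices.compute_all(cube, config.index_definitions) for tag, cube in cubes.items()}
    report["index_maps"] = maps

    # ICG reconstruction on the intra-cube (fallback post)
    rec_source = "intra" if "intra" in cubes else "post"
    rec = icg_reconstruction.reconstruct_icg(cubes[rec_source], config.reconstruction_params())
    report["reconstruction"] = rec
    report["params"]["reconstruction"] = vars(config.reconstruction_params())

    # inflow metrics per ROI
    if bundle.frames is not None:
        stack = inflow.read_frame_stack(bundle.frames, bundle.frame_rate_hz)
        report["inflow"] = _inflow_table(stack, ann, bundle, config)
    else:
        report["skipped"].append("inflow")
        stack = None

    # border distances across modalities
    if ann.ruler is not None and ann.clinical_marker is not None and ann.profile_lines:
        scale = border_geometry.calibrate_scale(*ann.ruler)
        images: dict[str, np.ndarray] = {"recicg": rec.values}
        if "StO2" in maps["pre"]:
            images["sto2"] = maps["pre"]["StO2"].values
        if stack is not None:
            tail = max(1, stack.n_frames // 10)
            images["icg"] = stack.frames[-tail:].mean(axis=0)
        estimates = border_geometry.border_distances(
            images,
            ann.profile_lines,
            ann.clinical_marker,
            scale,
            step_px=config.profile_step_px,
            smooth_window=config.profile_smooth_window,
        )
        report["border"] = pd.DataFrame(
            [
                {
                    "modality": m,
                    "distance_cm": est.signed_distance_cm,
                    **{f"inflection_px_{i}": v for i, v in enumerate(est.inflections_px)},
                }
                for m, est in estimates.items()
            ]
        )
        report["scale_cm_per_px"] = scale
    else:
        report["skipped"].append("border")

    # parameter shift pre -> intra/post
    classed = [r for r in ann.rois if r.perfusion_class is not None]
    if len(maps) > 1 and classed:
        report["shift"] = parameter_shift.shift_summary(maps, ann.rois).table
    else:
        report["skipped"].append("shift")

    if out_dir is not None:
        _write_case_report(report, bundle, config, Path(out_dir))
    return report


def _write_case_report(report: dict, bundle: CaseBundle, config: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "recicg.tiff", report["reconstruction"].values.astype(np.float32))
    for tag, tag_maps in report["index_maps"].items():
        for name, pmap in tag_maps.items():
            tifffile.imwrite(out_dir / f"{tag}_{name}.tiff", pmap.values.astype(np.float32))
    for key in ("inflow", "border", "shift"):
        if key in report:
            report[key].to_csv(out_dir / f"{key}.csv", index=False)
    log_doc = {
        "case_id": bundle.case_id,
        "skipped": report["skipped"],
        "config": {
            "sigma_bands": config.sigma_bands,
            "band_window_nm": list(config.band_window_nm),
            "median_kernel": config.median_kernel,
            "percentile": config.percentile,
            "movmean_window_s": config.movmean_window_s,
            "noise_window_s": list(config.noise_window_s),
            "slope_fraction": config.slope_fraction,
            "profile_step_px": config.profile_step_px,
            "profile_smooth_window": config.profile_smooth_window,
            "delta_cm": config.delta_cm,
            "alpha": config.alpha,
            "thresholds": config.thresholds,
        },
    }
    (out_dir / "case_log.json").write_text(json.dumps(log_doc, indent=2, sort_keys=True) + "\n")
    log.info("case %s written to %s (skipped: %s)", bundle.case_id, out_dir, report["skipped"])


def run_cohort(
    case_dirs: list[str | Path],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Aggregate per-case border distances and run the modality comparison."""
    config = config or PipelineConfig()
    if len(case_dirs) < 3:
        raise InsufficientCasesError(f"cohort needs >= 3 cases, got {len(case_dirs)}")
    rows = []
    n_failed = 0
    for directory in case_dirs:
        try:
            bundle = CaseBundle.from_dir(directory)
            report = run_case(bundle, config)
            if "border" not in report:
                raise ValidationError("border stage skipped")
            row = {"case_id": bundle.case_id}
            for _, rec in report["border"].iterrows():
                row[rec["modality"]] = rec["distance_cm"]
            rows.append(row)
        except Exception as exc:
            n_failed += 1
            log.warning("case %s dropped: %s", directory, exc)
    if len(rows) < 3:
        raise InsufficientCasesError(f"only {len(rows)} complete cases after dropping {n_failed}")
    distances = pd.DataFrame(rows).set_index("case_id")
    report = cohort_stats.modality_comparison_report(
        distances, delta_cm=config.delta_cm, alpha=config.alpha
    )
    report.attrs["n_failed_cases"] = n_failed
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        distances.to_csv(out_dir / "border_distances.csv")
        report.to_csv(out_dir / "cohort_report.csv", index=False)
    return report
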