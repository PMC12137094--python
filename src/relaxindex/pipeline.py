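"""End-to-end orchestration: split -> segment -> project -> measure -> stats.

A run consumes a manifest (per-eye composite paths, marker CSV, metadata),
executes every stage per eye and timepoint, isolates per-eye failures, and
writes all artifacts plus the effective configuration into a run directory
so the run can be reproduced bit-identically.

Cross-visit registration is assumed to have been done by the acquisition
device's fundus-tracking follow-up mode; the pipeline does not re-register
IR images between visits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composite_io, ir_registration, relaxation, stats_models
from .bscan_segmentation import LayerSegmentation, segment_bscan, segmentation_to_dict
from .config import RunConfig
from .errors import RelaxIndexError

logger = logging.getLogger(__name__)


@dataclass
class EyeInputs:
    """One eye's entry in the run manifest."""

    eye_id: str
    composites: dict[str, Path]        # timepoint -> composite image path
    markers: Path
    axial_length_mm: float | None = None


@dataclass
class RunResult:
    """Outcome of a pipeline run."""

    out_dir: Path
    table: pd.DataFrame                # per-marker displacements, all eyes
    summary: pd.DataFrame              # per-eye RI
    stats: stats_models.MixedModelResult | None
    failures: dict[str, str]           # eye_id -> error message
    segmentations: dict[tuple[str, str], LayerSegmentation]


def load_manifest(path: str | Path) -> list[EyeInputs]:
    """Parse a manifest YAML into validated per-eye inputs."""
    doc = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    eyes = []
    for entry in doc["eyes"]:
        eyes.append(EyeInputs(
            eye_id=str(entry["eye_id"]),
            composites={tp: base / p for tp, p in entry["timepoints"].items()},
            markers=base / entry["markers"],
            axial_length_mm=entry.get("axial_length_mm"),
        ))
    return eyes


def process_eye_timepoint(
    composite: np.ndarray,
    markers_df: pd.DataFrame,
    eye_id: str,
    timepoint: str,
    config: RunConfig,
    axial_length_mm: float | None,
) -> tuple[LayerSegmentation, list[ir_registration.MarkerProjection]]:
    """All image stages for one (eye, timepoint): returns segmentation + projections."""
    panel = composite_io.split_composite(composite, config.split)
    if panel.ir_color is None:
        raise RelaxIndexError("composite is grayscale; the IR panel needs color "
                              "planes for scan-line detection")
    seg = segment_bscan(panel.bscan, config.segmentation)
    scanline = ir_registration.detect_scan_line(
        panel.ir_color, config.registration.green_margin, config.registration.min_run)
    sub = markers_df[(markers_df["eye_id"].astype(str) == eye_id)
                     & (markers_df["timepoint"] == timepoint)]
    markers = ir_registration.load_markers(sub, panel.ir.pixels.shape, scanline)
    scales = ir_registration.compute_scales(
        scanline, panel.bscan.n_cols, panel.ir.n_cols,
        axial_length_mm=axial_length_mm,
        fov_deg=config.registration.fov_deg,
        bscan_axial_um_per_px=config.registration.axial_um_per_px,
    )
    projections = [
        ir_registration.project_marker(m, scanline, seg, scales, panel.bscan.n_cols)
        for m in markers
    ]
    return seg, projections


def measure_composites(
    composites: dict[str, np.ndarray],
    markers_df: pd.DataFrame,
    eye_id: str,
    config: RunConfig | None = None,
    axial_length_mm: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-memory convenience: displacement table + per-eye RI for one eye.

    ``composites`` maps timepoint labels to composite rasters (as produced
    by the phantom generator or loaded from exports).
    """
    config = config or RunConfig()
    projections = []
    for tp, comp in composites.items():
        _seg, projs = process_eye_timepoint(comp, markers_df, eye_id, tp,
                                            config, axial_length_mm)
        projections.extend(projs)
    table = relaxation.build_longitudinal_table(projections,
                                                mode=config.displacement.mode)
    summary = relaxation.summarize_ri(
        table, nominal_markers=config.displacement.nominal_markers)
    return table, summary


def run_pipeline(
    config: RunConfig,
    eyes: list[EyeInputs],
    out_dir: str | Path,
) -> RunResult:
    """Execute the full pipeline for every eye in the manifest.

    Per-eye failures are caught, logged and reported in ``failures``; the
    run continues for the remaining eyes.  The mixed-model stage runs only
    when at least two eyes with two pair levels survive.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("relaxindex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    failures: dict[str, str] = {}
    all_projections = []
    segmentations: dict[tuple[str, str], LayerSegmentation] = {}
    try:
        for eye in eyes:
            try:
                markers_df = pd.read_csv(eye.markers)
                for tp, comp_path in eye.composites.items():
                    t0 = time.perf_counter()
                    composite = composite_io.read_image(comp_path)
                    seg, projections = process_eye_timepoint(
                        composite, markers_df, eye.eye_id, tp, config,
                        eye.axial_length_mm)
                    segmentations[(eye.eye_id, tp)] = seg
                    all_projections.extend(projections)
                    seg_path = out_dir / f"{eye.eye_id}_{tp}_seg.json"
                    seg_path.write_text(json.dumps(segmentation_to_dict(seg)))
                    logger.info("eye %s %s: %d markers projected in %.2fs",
                                eye.eye_id, tp, len(projections),
                                time.perf_counter() - t0)
            except Exception as exc:
                logger.error("eye %s failed: %s", eye.eye_id, exc)
                failures[eye.eye_id] = str(exc)
                all_projections = [p for p in all_projections
                                   if p.marker.eye_id != eye.eye_id]

        table = relaxation.build_longitudinal_table(
            all_projections, mode=config.displacement.mode)
        summary = relaxation.summarize_ri(
            table, nominal_markers=config.displacement.nominal_markers) \
            if len(table) else pd.DataFrame(columns=["eye_id", "pair", "ri_mm", "n_markers"])

        stats = None
        if len(table) and table["eye_id"].nunique() >= 2 and table["pair"].nunique() >= 2:
            try:
                stats = stats_models.fit_ri_model(table, reml=config.stats.reml)
            except RelaxIndexError as exc:
                logger.warning("mixed-model stage skipped: %s", exc)

        table.to_csv(out_dir / "ri.csv", index=False)
        summary.to_csv(out_dir / "ri_summary.csv", index=False)
        if stats is not None:
            (out_dir / "stats.json").write_text(
                json.dumps(stats_models.result_to_dict(stats), indent=2))
        config.to_yaml(out_dir / "config.yaml")
        if failures:
            (out_dir / "failures.json").write_text(json.dumps(failures, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()

    return RunResult(out_dir=out_dir, table=table, summary=summary, stats=stats,
                     failures=failures, segmentations=segmentations)
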