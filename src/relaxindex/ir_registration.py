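"""IR fundus panel registration: arrow detection, markers, and scales.

The acquisition draws a horizontal green arrow on the infrared (IR) fundus
panel marking where the paired B-scan was taken.  Because the arrow and the
B-scan cover the same retinal extent, the arrow length in IR pixels and the
B-scan width in columns describe the same physical distance — this equality
is the bridge that maps a vessel-crossing click on the IR panel to a
(fractional) B-scan column, and from there onto the segmented ERM and RPE
traces.

Physical scaling of the IR panel uses Bennett-style small-angle scaling of
the retinal image: q [mm/deg] = 0.01306 x (axial length [mm] - 1.82), with a
documented emmetropic fallback when no biometry is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bscan_segmentation import LayerSegmentation
from .config import (
    BENNETT_OFFSET_MM,
    BENNETT_SLOPE,
    DEFAULT_AXIAL_UM_PER_PX,
    DEFAULT_FOV_DEG,
    EMMETROPIC_AXIAL_LENGTH_MM,
)
from .errors import (
    MarkerValidationError,
    ParameterError,
    ProjectionError,
    ScanLineNotFoundError,
)

VALID_TIMEPOINTS = ("T1", "T2", "POST")


@dataclass
class ScanLine:
    """Detected green scan-position arrow on the IR panel."""

    row: int
    col_start: int
    col_end: int        # inclusive

    @property
    def length_px(self) -> int:
        return self.col_end - self.col_start + 1


@dataclass
class Marker:
    """One manually identified vessel crossing on the IR panel."""

    eye_id: str
    timepoint: str
    marker_id: int
    x_ir: float
    y_ir: float
    l_r_ir: float       # lateral distance from the start of the IR scan (px)


@dataclass
class PixelScales:
    """Physical pixel scales tying IR and B-scan panels together (um/px)."""

    bscan_axial_um_per_px: float = DEFAULT_AXIAL_UM_PER_PX
    bscan_lateral_um_per_px: float | None = None
    ir_lateral_um_per_px: float | None = None
    axial_length_mm: float | None = None
    fov_deg: float = DEFAULT_FOV_DEG

    def __post_init__(self) -> None:
        for name in ("bscan_axial_um_per_px", "bscan_lateral_um_per_px",
                     "ir_lateral_um_per_px", "fov_deg"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ParameterError(f"{name} must be strictly positive, got {v}")


@dataclass
class MarkerProjection:
    """A marker's position mapped onto the B-scan and its layer traces.

    ``erm_point`` is the marker's projection on the epiretinal membrane;
    ``rpe_anchor`` the vertical projection onto the retinal pigmented
    epithelium — the immobile reference from which displacement is measured.
    Coordinates are (col, row) pixels and (lateral, axial) micrometres.
    """

    marker: Marker
    l_r_bmode: float
    erm_point_px: tuple[float, float]
    rpe_anchor_px: tuple[float, float]
    erm_point_um: tuple[float, float]
    rpe_anchor_um: tuple[float, float]
    scales: PixelScales


def bennett_q_mm_per_deg(axial_length_mm: float) -> float:
    """Retinal scaling factor q in mm/degree for a given axial length."""
    return BENNETT_SLOPE * (axial_length_mm - BENNETT_OFFSET_MM)


def detect_scan_line(
    ir_color: np.ndarray,
    green_margin: float = 0.2,
    min_run: int = 32,
) -> ScanLine:
    """Locate the green scan-position arrow as the longest horizontal run.

    A pixel is classified green when its green plane exceeds both the red
    and blue planes by ``green_margin`` (intensities in [0, 1]).  The arrow
    is the longest run of consecutive green pixels on a single row; ties go
    to the topmost row.
    """
    arr = np.asarray(ir_color, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ScanLineNotFoundError("scan line not found: IR panel has no color planes")
    green = (arr[:, :, 1] - arr[:, :, 0] > green_margin) & \
            (arr[:, :, 1] - arr[:, :, 2] > green_margin)
    best = None  # (length, row, col_start)
    for r in np.flatnonzero(green.any(axis=1)):
        mask = green[r]
        # run-length encode the boolean row
        edges = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        lengths = ends - starts
        j = int(np.argmax(lengths))
        if best is None or lengths[j] > best[0]:
            best = (int(lengths[j]), int(r), int(starts[j]))
    if best is None or best[0] < min_run:
        raise ScanLineNotFoundError(
            f"scan line not found: no green run of >= {min_run} px"
        )
    length, row, col_start = best
    return ScanLine(row=row, col_start=col_start, col_end=col_start + length - 1)


def load_markers(
    path: str | Path | pd.DataFrame,
    ir_shape: tuple[int, int],
    scanline: ScanLine,
) -> list[Marker]:
    """Load and validate the manual vessel-crossing marker table.

    The CSV (header ``eye_id,timepoint,marker_id,x_ir,y_ir``; 0-based pixel
    coordinates on the IR panel) replaces the interactive clicking step.
    Rows outside the panel or the arrow span, unknown timepoint labels, and
    duplicate (eye, timepoint, marker) keys are all reported together.
    """
    df = path.copy() if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    required = ["eye_id", "timepoint", "marker_id", "x_ir", "y_ir"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MarkerValidationError([f"missing columns: {missing}"])

    n_rows, n_cols = ir_shape
    problems: list[str] = []
    seen: set[tuple] = set()
    markers: list[Marker] = []
    for i, rec in df.iterrows():
        row_id = f"row {i} (eye={rec['eye_id']}, tp={rec['timepoint']}, marker={rec['marker_id']})"
        tp = str(rec["timepoint"])
        if tp not in VALID_TIMEPOINTS:
            problems.append(f"{row_id}: unknown timepoint label {tp!r}")
            continue
        x, y = float(rec["x_ir"]), float(rec["y_ir"])
        if not (0 <= x <= n_cols - 1 and 0 <= y <= n_rows - 1):
            problems.append(f"{row_id}: coordinates ({x}, {y}) outside IR panel "
                            f"{n_rows}x{n_cols}")
            continue
        if not (scanline.col_start <= x <= scanline.col_end):
            problems.append(f"{row_id}: x={x} outside scan-line span "
                            f"[{scanline.col_start}, {scanline.col_end}]")
            continue
        key = (str(rec["eye_id"]), tp, int(rec["marker_id"]))
        if key in seen:
            problems.append(f"{row_id}: duplicate (eye, timepoint, marker_id)")
            continue
        seen.add(key)
        markers.append(Marker(
            eye_id=key[0], timepoint=tp, marker_id=key[2],
            x_ir=x, y_ir=y, l_r_ir=x - scanline.col_start,
        ))
    if problems:
        raise MarkerValidationError(problems)
    return markers


def ir_to_bscan_column(l_r_ir: float, scanline: ScanLine, n_bscan_cols: int) -> float:
    """Map a distance along the IR arrow to a fractional B-scan column.

    The arrow's ``length_px - 1`` pixel intervals span the B-scan's
    ``n_bscan_cols - 1`` column intervals; endpoints map to endpoints and
    the map is strictly increasing and exactly invertible.
    """
    if scanline.length_px < 2:
        raise ParameterError("degenerate scan line: length_px < 2")
    if not (0 <= l_r_ir <= scanline.length_px - 1):
        raise ProjectionError(
            f"l_r_ir={l_r_ir} outside [0, {scanline.length_px - 1}]"
        )
    return l_r_ir * (n_bscan_cols - 1) / (scanline.length_px - 1)


def compute_scales(
    scanline: ScanLine,
    n_bscan_cols: int,
    ir_panel_width_px: int,
    axial_length_mm: float | None = None,
    fov_deg: float = DEFAULT_FOV_DEG,
    bscan_axial_um_per_px: float = DEFAULT_AXIAL_UM_PER_PX,
) -> PixelScales:
    """Derive physical pixel scales for the IR panel and the B-scan.

    The IR lateral scale comes from the field of view and Bennett-style
    degrees-to-mm conversion; the B-scan lateral scale then follows from the
    arrow-length/B-scan-width equality.
    """
    if axial_length_mm is not None and not (20.0 <= axial_length_mm <= 30.0):
        raise ParameterError(
            f"axial length {axial_length_mm} mm outside the plausible [20, 30] range"
        )
    al = axial_length_mm if axial_length_mm is not None else EMMETROPIC_AXIAL_LENGTH_MM
    q = bennett_q_mm_per_deg(al)
    ir_um_per_px = fov_deg * q * 1000.0 / ir_panel_width_px
    bscan_um_per_px = scanline.length_px * ir_um_per_px / (n_bscan_cols - 1)
    return PixelScales(
        bscan_axial_um_per_px=bscan_axial_um_per_px,
        bscan_lateral_um_per_px=bscan_um_per_px,
        ir_lateral_um_per_px=ir_um_per_px,
        axial_length_mm=axial_length_mm,
        fov_deg=fov_deg,
    )


def project_marker(
    marker: Marker,
    scanline: ScanLine,
    seg: LayerSegmentation,
    scales: PixelScales,
    n_bscan_cols: int,
) -> MarkerProjection:
    """Project a marker onto the segmented ERM and RPE traces.

    The marker's arrow distance is mapped to a fractional B-scan column and
    both traces are evaluated there by linear interpolation between their
    100 samples; micrometre coordinates are attached using the scales.
    """
    col = ir_to_bscan_column(marker.l_r_ir, scanline, n_bscan_cols)
    for trace in (seg.erm, seg.rpe):
        if not (trace.columns[0] <= col <= trace.columns[-1]):
            raise ProjectionError(
                f"projection outside segmentation: column {col:.2f} not in "
                f"[{trace.columns[0]:.2f}, {trace.columns[-1]:.2f}] ({trace.kind})"
            )
    erm_row = seg.erm.evaluate(col)
    rpe_row = seg.rpe.evaluate(col)
    lat = scales.bscan_lateral_um_per_px
    ax = scales.bscan_axial_um_per_px
    if lat is None:
        raise ParameterError("bscan_lateral_um_per_px is unset; run compute_scales first")
    return MarkerProjection(
        marker=marker,
        l_r_bmode=col,
        erm_point_px=(col, erm_row),
        rpe_anchor_px=(col, rpe_row),
        erm_point_um=(col * lat, erm_row * ax),
        rpe_anchor_um=(col * lat, rpe_row * ax),
        scales=scales,
    )
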