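"""Synthetic paired IR + B-scan phantoms with exact ground truth.

The phantom emulates the composite exports the pipeline consumes: an
infrared (IR) fundus panel with a gray textured background, a dark vascular
tree whose crossings are the trackable landmarks, and a horizontal green
scan-position arrow; next to it an OCT B-scan with a thin bright epiretinal
membrane (ERM) band above a brighter curved retinal-pigmented-epithelium
(RPE) band, optional vessel shadows, and seeded additive noise.  Vessel
crossings drift laterally between timepoints by programmed micrometre
amounts, so every quantity the pipeline estimates has an exact recorded
truth.

Drift is programmed in B-scan-plane micrometres: the IR pixel shift applied
to a crossing is chosen so that, after the arrow-length/B-scan-width
mapping, the lateral component of the recovered displacement equals the
programmed value exactly.  All randomness flows from one seeded generator
per spec (per-timepoint streams are spawned from it), so identical specs
produce byte-identical images and tables.

`simulate_cohort` is the statistics test bed: it draws displacement tables
directly from the nested random-effects model the analysis assumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .config import DEFAULT_AXIAL_UM_PER_PX, DEFAULT_FOV_DEG
from .errors import PhantomSpecError
from .ir_registration import ScanLine, compute_scales

TIMEPOINTS = ("T1", "T2", "POST")


@dataclass
class LayerProfile:
    """Layer row position as a smooth function of the B-scan column.

    rows(c) = const + linear*(c-cc) + quad*(c-cc)^2 + sin_amp*sin(2*pi*(c-cc)/sin_period + sin_phase),
    with cc the central column.
    """

    const: float
    linear: float = 0.0
    quad: float = 0.0
    sin_amp: float = 0.0
    sin_period: float = 160.0
    sin_phase: float = 0.0

    def __call__(self, cols: np.ndarray, center: float) -> np.ndarray:
        c = np.asarray(cols, dtype=float) - center
        rows = self.const + self.linear * c + self.quad * c ** 2
        if self.sin_amp:
            rows = rows + self.sin_amp * np.sin(2 * np.pi * c / self.sin_period
                                                + self.sin_phase)
        return rows


@dataclass
class PhantomSpec:
    """Full description of one synthetic eye across the three timepoints."""

    seed: int
    ir_width: int = 512
    ir_height: int = 320
    bscan_width: int = 512
    bscan_height: int = 320
    erm_profile: LayerProfile = field(
        default_factory=lambda: LayerProfile(const=120.0, quad=1.2e-4,
                                             sin_amp=3.0, sin_period=160.0))
    rpe_profile: LayerProfile = field(
        default_factory=lambda: LayerProfile(const=210.0, quad=2.2e-4))
    erm_sigma_px: float = 2.5
    rpe_sigma_px: float = 3.5
    erm_amplitude: float = 0.75
    rpe_amplitude: float = 1.0
    background: float = 0.03
    vessel_shadows: bool = True
    shadow_depth: float = 0.15
    shadow_sigma_px: float = 2.5
    noise_sigma: float = 0.05          # additive Gaussian sd, fraction of range
    arrow_row: int = 36
    arrow_col_start: int = 56
    arrow_col_end: int = 455
    arrow_color: tuple[float, float, float] = (0.05, 0.9, 0.05)
    n_markers: int = 10
    #: programmed lateral drift between successive visits, um (mean, sd)
    drift_t1t2_um: tuple[float, float] = (150.0, 10.0)
    drift_t2post_um: tuple[float, float] = (-120.0, 10.0)
    axial_length_mm: float = 24.0
    fov_deg: float = DEFAULT_FOV_DEG
    axial_um_per_px: float = DEFAULT_AXIAL_UM_PER_PX
    eye_id: str = "PH01"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PhantomSpecError("seed is mandatory")
        if self.ir_height != self.bscan_height:
            raise PhantomSpecError("IR and B-scan panels must share the row count")
        cols = np.arange(self.bscan_width)
        center = self.bscan_width / 2.0
        gap = self.rpe_profile(cols, center) - self.erm_profile(cols, center)
        if np.any(gap <= 0):
            raise PhantomSpecError("ERM profile must lie strictly above the RPE profile")
        rows = np.concatenate([self.erm_profile(cols, center),
                               self.rpe_profile(cols, center)])
        if rows.min() < 5 or rows.max() > self.bscan_height - 5:
            raise PhantomSpecError("layer profiles leave the B-scan image")
        for mean, _sd in (self.drift_t1t2_um, self.drift_t2post_um):
            if abs(mean) > 0.1 * self.scan_width_um():
                raise PhantomSpecError("drift magnitude exceeds 10% of the scan width")

    # --- derived geometry -------------------------------------------------
    def scanline(self) -> ScanLine:
        return ScanLine(row=self.arrow_row, col_start=self.arrow_col_start,
                        col_end=self.arrow_col_end)

    def scales(self):
        return compute_scales(
            self.scanline(), self.bscan_width, self.ir_width,
            axial_length_mm=self.axial_length_mm, fov_deg=self.fov_deg,
            bscan_axial_um_per_px=self.axial_um_per_px,
        )

    def scan_width_um(self) -> float:
        sl = ScanLine(row=self.arrow_row, col_start=self.arrow_col_start,
                      col_end=self.arrow_col_end)
        scales = compute_scales(sl, self.bscan_width, self.ir_width,
                                axial_length_mm=self.axial_length_mm,
                                fov_deg=self.fov_deg,
                                bscan_axial_um_per_px=self.axial_um_per_px)
        return (self.bscan_width - 1) * scales.bscan_lateral_um_per_px


@dataclass
class PhantomTruth:
    """Exact ground truth recorded at generation time."""

    erm_rows: np.ndarray               # true ERM row per B-scan column
    rpe_rows: np.ndarray
    marker_x_ir: dict[str, np.ndarray]   # timepoint -> IR x of each crossing
    marker_y_ir: np.ndarray
    l_r_bmode: dict[str, np.ndarray]     # timepoint -> fractional B-scan column
    rpe_anchor_um: dict[str, np.ndarray]  # timepoint -> (n_markers, 2) lateral/axial um
    displacement_um: dict[str, np.ndarray]  # pair -> per-marker total displacement
    programmed_drift_um: dict[str, np.ndarray]  # pair -> per-marker lateral drift
    seam_col: int
    scanline: ScanLine
    scales: object
    markers: pd.DataFrame              # CSV-ready marker table (all timepoints)

    def ri_mm(self, pair: str) -> float:
        """True Relaxation Index (mm) for a timepoint pair."""
        return float(np.mean(self.displacement_um[pair])) / 1000.0


def _rng(spec: PhantomSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(stream,)))


def _marker_geometry(spec: PhantomSpec):
    """Seeded marker base positions and per-timepoint drifted x (IR px)."""
    rng = _rng(spec, 1)
    sl = spec.scanline()
    scales = spec.scales()
    # IR px per programmed um so that the *recovered* lateral displacement
    # (after the arrow->B-scan mapping) equals the programmed value exactly
    px_per_um = (sl.length_px - 1) / (sl.length_px * scales.ir_lateral_um_per_px)

    margin = 30.0
    base = np.linspace(sl.col_start + margin, sl.col_end - margin, spec.n_markers)
    base = base + rng.uniform(-3.0, 3.0, spec.n_markers)
    y = rng.uniform(0.35 * spec.ir_height, 0.85 * spec.ir_height, spec.n_markers)

    d12 = rng.normal(spec.drift_t1t2_um[0], spec.drift_t1t2_um[1], spec.n_markers)
    d2p = rng.normal(spec.drift_t2post_um[0], spec.drift_t2post_um[1], spec.n_markers)
    x = {
        "T1": base,
        "T2": base + d12 * px_per_um,
        "POST": base + (d12 + d2p) * px_per_um,
    }
    for tp, xs in x.items():
        if np.any(xs < sl.col_start) or np.any(xs > sl.col_end):
            raise PhantomSpecError(f"markers at {tp} fall outside the arrow span")
    return x, y, {"T1T2": d12, "T2POST": d2p, "T1POST": d12 + d2p}


def render_bscan(spec: PhantomSpec, timepoint: str) -> np.ndarray:
    """Render the grayscale B-scan panel for one timepoint (floats in [0,1])."""
    if timepoint not in TIMEPOINTS:
        raise PhantomSpecError(f"unknown timepoint {timepoint!r}")
    h, w = spec.bscan_height, spec.bscan_width
    cols = np.arange(w)
    center = w / 2.0
    erm = spec.erm_profile(cols, center)
    rpe = spec.rpe_profile(cols, center)
    r = np.arange(h)[:, None]
    img = (spec.background
           + spec.erm_amplitude * np.exp(-0.5 * ((r - erm[None, :]) / spec.erm_sigma_px) ** 2)
           + spec.rpe_amplitude * np.exp(-0.5 * ((r - rpe[None, :]) / spec.rpe_sigma_px) ** 2))

    if spec.vessel_shadows:
        x, _y, _d = _marker_geometry(spec)
        sl = spec.scanline()
        bcols = (x[timepoint] - sl.col_start) * (w - 1) / (sl.length_px - 1)
        atten = np.ones(w)
        for c0 in bcols:
            atten *= 1.0 - spec.shadow_depth * np.exp(
                -0.5 * ((cols - c0) / spec.shadow_sigma_px) ** 2)
        img = spec.background + (img - spec.background) * atten[None, :]

    if spec.noise_sigma > 0:
        noise_rng = _rng(spec, 10 + TIMEPOINTS.index(timepoint))
        img = img + noise_rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _draw_cross(img: np.ndarray, x0: float, y0: float, half_len: float = 22.0,
                thickness: float = 1.3, value: float = 0.15) -> None:
    """Paint two crossing dark strokes centered at (x0, y0), in place."""
    h, w = img.shape[:2]
    r0, r1 = int(max(0, y0 - half_len - 3)), int(min(h, y0 + half_len + 4))
    c0, c1 = int(max(0, x0 - half_len - 3)), int(min(w, x0 + half_len + 4))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    px, py = xx - x0, yy - y0
    for theta in (np.deg2rad(38.0), np.deg2rad(-47.0)):
        ct, st = np.cos(theta), np.sin(theta)
        along = px * ct + py * st
        across = -px * st + py * ct
        mask = (np.abs(across) <= thickness) & (np.abs(along) <= half_len)
        img[r0:r1, c0:c1][mask] = value


def render_ir(spec: PhantomSpec, timepoint: str) -> np.ndarray:
    """Render the color IR fundus panel (H x W x 3 floats in [0,1])."""
    if timepoint not in TIMEPOINTS:
        raise PhantomSpecError(f"unknown timepoint {timepoint!r}")
    h, w = spec.ir_height, spec.ir_width
    tex_rng = _rng(spec, 0)  # static texture, identical across timepoints
    texture = ndimage.gaussian_filter(tex_rng.normal(0.0, 1.0, (h, w)), sigma=6.0)
    texture = texture / max(np.abs(texture).max(), 1e-12)
    gray = np.clip(0.5 + 0.05 * texture, 0.0, 1.0)

    x, y, _d = _marker_geometry(spec)
    for x0, y0 in zip(x[timepoint], y):
        _draw_cross(gray, x0, y0)

    ir = np.repeat(gray[:, :, None], 3, axis=2)
    ir[spec.arrow_row, spec.arrow_col_start:spec.arrow_col_end + 1, :] = spec.arrow_color
    return ir


def render_composite(spec: PhantomSpec, timepoint: str) -> np.ndarray:
    """IR and B-scan panels abutted: the export the pipeline ingests."""
    ir = render_ir(spec, timepoint)
    bscan = render_bscan(spec, timepoint)
    bscan_rgb = np.repeat(bscan[:, :, None], 3, axis=2)
    return np.concatenate([ir, bscan_rgb], axis=1)


@dataclass
class PhantomSeries:
    """Rendered composites for all timepoints plus the recorded truth."""

    spec: PhantomSpec
    composites: dict[str, np.ndarray]
    truth: PhantomTruth
    metadata: dict


def generate_series(spec: PhantomSpec, out_dir: str | Path | None = None) -> PhantomSeries:
    """Generate the three-timepoint series and its ground truth.

    When ``out_dir`` is given, writes per-timepoint composite PNGs, the
    marker CSV, a metadata YAML and a truth JSON, exactly in the formats the
    pipeline CLI consumes.
    """
    x, y, drifts = _marker_geometry(spec)
    sl = spec.scanline()
    scales = spec.scales()
    cols = np.arange(spec.bscan_width)
    center = spec.bscan_width / 2.0

    l_r_bmode = {}
    anchors_um = {}
    for tp in TIMEPOINTS:
        bcol = (x[tp] - sl.col_start) * (spec.bscan_width - 1) / (sl.length_px - 1)
        rpe_row = spec.rpe_profile(bcol, center)
        l_r_bmode[tp] = bcol
        anchors_um[tp] = np.column_stack([
            bcol * scales.bscan_lateral_um_per_px,
            rpe_row * scales.bscan_axial_um_per_px,
        ])

    displacement = {}
    for (a, b), pair in (("T1", "T2"), "T1T2"), (("T2", "POST"), "T2POST"), (("T1", "POST"), "T1POST"):
        diff = anchors_um[b] - anchors_um[a]
        displacement[pair] = np.hypot(diff[:, 0], diff[:, 1])

    marker_rows = []
    for tp in TIMEPOINTS:
        for i in range(spec.n_markers):
            marker_rows.append({
                "eye_id": spec.eye_id, "timepoint": tp, "marker_id": i + 1,
                "x_ir": float(x[tp][i]), "y_ir": float(y[i]),
            })
    markers = pd.DataFrame(marker_rows)

    truth = PhantomTruth(
        erm_rows=spec.erm_profile(cols, center),
        rpe_rows=spec.rpe_profile(cols, center),
        marker_x_ir=x, marker_y_ir=y,
        l_r_bmode=l_r_bmode,
        rpe_anchor_um=anchors_um,
        displacement_um=displacement,
        programmed_drift_um=drifts,
        seam_col=spec.ir_width,
        scanline=sl,
        scales=scales,
        markers=markers,
    )

    composites = {tp: render_composite(spec, tp) for tp in TIMEPOINTS}
    metadata = {
        "eye_id": spec.eye_id,
        "axial_length_mm": spec.axial_length_mm,
        "fov_deg": spec.fov_deg,
        "axial_um_per_px": spec.axial_um_per_px,
    }
    series = PhantomSeries(spec=spec, composites=composites, truth=truth,
                           metadata=metadata)
    if out_dir is not None:
        _write_series(series, Path(out_dir))
    return series


def _write_series(series: PhantomSeries, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = series.spec
    for tp, comp in series.composites.items():
        # 8-bit RGB: the interchange format of clinical exports
        iio.imwrite(out_dir / f"{spec.eye_id}_{tp}.png",
                    np.round(comp * 255).astype(np.uint8))
    series.truth.markers.to_csv(out_dir / f"{spec.eye_id}_markers.csv", index=False)
    (out_dir / f"{spec.eye_id}_meta.yaml").write_text(yaml.safe_dump(series.metadata))
    import json
    truth = series.truth
    (out_dir / f"{spec.eye_id}_truth.json").write_text(json.dumps({
        "seam_col": truth.seam_col,
        "arrow": dataclasses.asdict(truth.scanline),
        "displacement_um": {k: v.tolist() for k, v in truth.displacement_um.items()},
        "programmed_drift_um": {k: v.tolist() for k, v in truth.programmed_drift_um.items()},
        "ri_mm": {pair: truth.ri_mm(pair) for pair in truth.displacement_um},
    }, indent=2))


def simulate_cohort(
    n_eyes: int = 9,
    n_markers: int = 10,
    pair_effects_mm: dict[str, float] | None = None,
    sd_eye: float = 0.03,
    sd_marker: float = 0.02,
    sd_resid: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a statistics-ready displacement table from the assumed model.

    d_total_mm = pair effect + eye intercept + marker-in-eye intercept +
    residual, all Gaussian.  The true parameters are attached to the frame's
    ``attrs`` for recovery studies.  Defaults mirror the clinical design:
    9 eyes x 10 markers x 3 timepoint pairs.
    """
    if n_eyes < 1 or n_markers < 1:
        raise PhantomSpecError("need at least one eye and one marker")
    if min(sd_eye, sd_marker, sd_resid) < 0:
        raise PhantomSpecError("standard deviations must be non-negative")
    effects = pair_effects_mm or {"T1T2": 0.15, "T2POST": 0.12, "T1POST": 0.05}
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_eyes):
        b_eye = rng.normal(0.0, sd_eye)
        for m in range(n_markers):
            b_marker = rng.normal(0.0, sd_marker)
            for pair, eff in effects.items():
                rows.append({
                    "eye_id": f"E{e + 1:02d}",
                    "marker_id": m + 1,
                    "pair": pair,
                    "d_total_mm": eff + b_eye + b_marker + rng.normal(0.0, sd_resid),
                })
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "pair_effects_mm": dict(effects),
        "sd_eye": sd_eye, "sd_marker": sd_marker, "sd_resid": sd_resid,
        "seed": seed,
    }
    return df
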