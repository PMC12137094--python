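"""ERM / RPE boundary segmentation on the OCT B-scan panel.

The chain mirrors the standard envelope-threshold approach for hyper-
reflective retinal bands:

1. 5x5 uniform smoothing (speckle suppression);
2. edge enhancement by adding back a high-pass component (unsharp mask);
3. row-maximum envelope, normalized to [0, 1];
4. region of interest (ROI) between the outermost rows where the envelope
   exceeds 0.4 — the band that contains both bright layers;
5. per-column peak detection: the peaks closest to the ROI top and bottom
   are the epiretinal-membrane (ERM) and retinal-pigmented-epithelium (RPE)
   candidates;
6. median/MAD outlier rejection against neighboring columns;
7. trace fitting: smoothing spline for the (irregular) ERM, 2nd-order
   polynomial for the (smooth, roughly parabolic) RPE, both resampled at
   100 evenly spaced columns over the common candidate span.

All thresholds are relative to the image dynamic range, so the chain is
equivariant under multiplication of the input by a positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import UnivariateSpline

from .composite_io import ImageGrid
from .config import SegmentationParams
from .errors import (
    EmptyRoiError,
    ImageShapeError,
    LayerFitError,
    NormalizationError,
    ParameterError,
    RejectionSkippedWarning,
    SegmentationStageError,
)


@dataclass
class RowEnvelope:
    """Per-row maximum intensity profile, min-max normalized to [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class RoiBand:
    """Row band between the outermost envelope threshold crossings."""

    row_top: int
    row_bottom: int
    threshold: float


@dataclass
class LayerCandidates:
    """Per-column candidate rows for both layers (NaN where missing)."""

    columns: np.ndarray          # all B-scan column indices
    erm_rows: np.ndarray         # float, NaN = missing
    rpe_rows: np.ndarray
    erm_rejected: np.ndarray = field(default=None)  # bool masks, set by reject_outliers
    rpe_rejected: np.ndarray = field(default=None)

    def layer_rows(self, kind: str) -> np.ndarray:
        return self.erm_rows if kind == "ERM" else self.rpe_rows

    def layer_rejected(self, kind: str) -> np.ndarray:
        mask = self.erm_rejected if kind == "ERM" else self.rpe_rejected
        if mask is None:
            mask = np.zeros(self.columns.size, dtype=bool)
        return mask

    def surviving(self, kind: str) -> np.ndarray:
        """Indices of candidates that are present and not rejected."""
        rows = self.layer_rows(kind)
        return np.flatnonzero(np.isfinite(rows) & ~self.layer_rejected(kind))


@dataclass
class LayerTrace:
    """Fitted layer boundary resampled at ``n_samples`` columns."""

    kind: Literal["ERM", "RPE"]
    columns: np.ndarray          # lateral sample positions (fractional px)
    rows: np.ndarray             # fitted vertical positions (fractional px)
    raw_columns: np.ndarray      # candidate columns before rejection
    raw_rows: np.ndarray
    rejected_mask: np.ndarray    # True where a raw candidate was discarded

    def evaluate(self, col: float) -> float:
        """Linearly interpolate the trace at a (fractional) column."""
        if col < self.columns[0] or col > self.columns[-1]:
            raise ValueError(f"column {col} outside trace span "
                             f"[{self.columns[0]}, {self.columns[-1]}]")
        return float(np.interp(col, self.columns, self.rows))


@dataclass
class LayerSegmentation:
    """Full segmentation output with audit intermediates."""

    erm: LayerTrace
    rpe: LayerTrace
    roi: RoiBand
    envelope: RowEnvelope
    params: SegmentationParams


def smooth(bscan: ImageGrid, kernel: int = 5) -> ImageGrid:
    """Low-pass the B-scan with a ``kernel x kernel`` uniform average."""
    if min(bscan.pixels.shape) < kernel:
        raise ImageShapeError(f"image {bscan.pixels.shape} smaller than the "
                              f"{kernel}x{kernel} smoothing kernel")
    out = ndimage.uniform_filter(bscan.pixels, size=kernel, mode="reflect")
    return ImageGrid(out, bscan.row_scale_um, bscan.col_scale_um)


def enhance(smoothed: ImageGrid, sigma: float = 3.0, alpha: float = 1.0) -> ImageGrid:
    """Sharpen edges by adding back a Gaussian high-pass component.

    ``enhanced = s + alpha * (s - G_sigma * s)``, clipped to be non-negative.
    Flat inputs are returned unchanged (the high-pass term vanishes).
    """
    if not sigma > 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if not alpha > 0:
        raise ParameterError(f"alpha must be positive, got {alpha}")
    s = smoothed.pixels
    low = ndimage.gaussian_filter(s, sigma=sigma, mode="reflect")
    out = np.clip(s + alpha * (s - low), 0.0, None)
    return ImageGrid(out, smoothed.row_scale_um, smoothed.col_scale_um)


def row_envelope(enhanced: ImageGrid, smooth_window: int | None = 5) -> RowEnvelope:
    """Row-maximum envelope, optionally moving-averaged, normalized to [0,1]."""
    prof = enhanced.pixels.max(axis=1)
    if smooth_window and smooth_window > 1:
        prof = ndimage.uniform_filter1d(prof, size=smooth_window, mode="reflect")
    lo, hi = float(prof.min()), float(prof.max())
    if hi == lo:
        raise NormalizationError("row envelope is constant; cannot normalize")
    return RowEnvelope((prof - lo) / (hi - lo))


def detect_roi(envelope: RowEnvelope, threshold: float = 0.4) -> RoiBand:
    """Band between the outermost rows where the envelope exceeds ``threshold``.

    Interior dips below the threshold (the darker retina between the two
    bright layers) are deliberately tolerated.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must be in (0,1), got {threshold}")
    above = np.flatnonzero(envelope.values > threshold)
    if above.size == 0:
        raise EmptyRoiError(f"empty ROI: no row exceeds threshold {threshold}")
    return RoiBand(row_top=int(above[0]), row_bottom=int(above[-1]), threshold=threshold)


def detect_layer_candidates(
    enhanced: ImageGrid,
    roi: RoiBand,
    prominence_frac: float = 0.05,
    single_peak_is_rpe: bool = False,
) -> LayerCandidates:
    """Per-column intensity peaks closest to the ROI limits.

    Within each column's ROI segment, local maxima with prominence above
    ``prominence_frac`` of the column's dynamic range are detected; the peak
    closest to the ROI top is the ERM candidate and the one closest to the
    bottom is the RPE candidate.  Columns with fewer than two peaks yield
    missing candidates (NaN) rather than an error.
    """
    n_cols = enhanced.n_cols
    erm = np.full(n_cols, np.nan)
    rpe = np.full(n_cols, np.nan)
    top, bottom = roi.row_top, roi.row_bottom
    for c in range(n_cols):
        seg = enhanced.pixels[top:bottom + 1, c]
        dyn = float(seg.max() - seg.min())
        if dyn <= 0:
            continue
        peaks, _ = signal.find_peaks(seg, prominence=prominence_frac * dyn)
        if peaks.size >= 2:
            erm[c] = top + peaks.min()
            rpe[c] = top + peaks.max()
        elif peaks.size == 1 and single_peak_is_rpe:
            rpe[c] = top + peaks[0]
    return LayerCandidates(columns=np.arange(n_cols), erm_rows=erm, rpe_rows=rpe)


def _reject_layer(columns: np.ndarray, rows: np.ndarray, window: int, k: float,
                  mad_floor: float, layer: str) -> np.ndarray:
    """Return a rejection mask (over all columns) for one layer."""
    rejected = np.zeros(rows.size, dtype=bool)
    idx = np.flatnonzero(np.isfinite(rows))
    if idx.size < window + 1:
        warnings.warn(
            f"{layer}: {idx.size} candidates < window+1 ({window + 1}); "
            "outlier rejection skipped",
            RejectionSkippedWarning,
        )
        return rejected
    cols = columns[idx].astype(float)
    vals = rows[idx]
    for j in range(idx.size):
        order = np.argsort(np.abs(cols - cols[j]), kind="stable")
        neighbors = vals[order[1:window + 1]]  # self excluded
        med = np.median(neighbors)
        mad = np.median(np.abs(neighbors - med))
        if abs(vals[j] - med) > k * max(mad, mad_floor):
            rejected[idx[j]] = True
    return rejected


def reject_outliers(
    candidates: LayerCandidates,
    window: int = 7,
    k: float = 3.0,
    mad_floor: float = 2.0,
) -> LayerCandidates:
    """Discard candidates far from their column neighborhood.

    For each layer independently, a candidate is rejected when its vertical
    position deviates from the median of its (up to ``window``) nearest
    columns' candidates by more than ``k`` times their MAD, with an absolute
    floor on the MAD term so perfectly smooth neighborhoods do not reject
    everything.  Layers with fewer than ``window + 1`` candidates are left
    untouched (with a warning).
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if not k > 0:
        raise ParameterError(f"k must be positive, got {k}")
    erm_rej = _reject_layer(candidates.columns, candidates.erm_rows, window, k, mad_floor, "ERM")
    rpe_rej = _reject_layer(candidates.columns, candidates.rpe_rows, window, k, mad_floor, "RPE")
    # raw candidate rows are kept; fitting honors the rejection masks
    return LayerCandidates(candidates.columns, candidates.erm_rows.copy(),
                           candidates.rpe_rows.copy(),
                           erm_rejected=erm_rej, rpe_rejected=rpe_rej)


def _fit_one_layer(candidates: LayerCandidates, kind: str, n_samples: int,
                   span: tuple[float, float], spline_smoothing: float,
                   min_candidates: int) -> LayerTrace:
    rows = candidates.layer_rows(kind)
    idx = candidates.surviving(kind)
    x = candidates.columns[idx].astype(float)
    y = rows[idx]
    xs = np.linspace(span[0], span[1], n_samples)
    if kind == "RPE":
        coeffs = np.polyfit(x, y, deg=2)
        ys = np.polyval(coeffs, xs)
    else:
        # smoothing spline: s is a total squared-residual budget
        spl = UnivariateSpline(x, y, k=3, s=spline_smoothing * x.size)
        ys = spl(xs)
    return LayerTrace(
        kind=kind, columns=xs, rows=ys,
        raw_columns=candidates.columns.copy(),
        raw_rows=rows.copy(),
        rejected_mask=candidates.layer_rejected(kind).copy(),
    )


def fit_layers(
    candidates: LayerCandidates,
    n_samples: int = 100,
    spline_smoothing: float = 1.0,
    min_candidates: int = 10,
    min_span_frac: float = 0.5,
) -> tuple[LayerTrace, LayerTrace]:
    """Fit and resample both layer traces over the common candidate span.

    The ERM is fitted with a smoothing spline (it can be locally wrinkled by
    traction); the RPE with a least-squares 2nd-order polynomial (a smooth,
    approximately parabolic reference surface).  Both are evaluated at
    ``n_samples`` evenly spaced columns spanning the intersection of the two
    layers' candidate extents.
    """
    n_cols = candidates.columns.size
    spans = {}
    for kind in ("ERM", "RPE"):
        idx = candidates.surviving(kind)
        if idx.size < min_candidates:
            raise LayerFitError(kind, f"only {idx.size} candidates "
                                      f"(need >= {min_candidates})")
        span_px = candidates.columns[idx[-1]] - candidates.columns[idx[0]]
        if span_px < min_span_frac * n_cols:
            raise LayerFitError(kind, f"candidates span {span_px} px "
                                      f"< {min_span_frac:.0%} of {n_cols} columns")
        spans[kind] = (float(candidates.columns[idx[0]]), float(candidates.columns[idx[-1]]))
    lo = max(spans["ERM"][0], spans["RPE"][0])
    hi = min(spans["ERM"][1], spans["RPE"][1])
    if hi <= lo:
        raise LayerFitError("ERM", "ERM and RPE candidate spans do not overlap")
    erm = _fit_one_layer(candidates, "ERM", n_samples, (lo, hi), spline_smoothing, min_candidates)
    rpe = _fit_one_layer(candidates, "RPE", n_samples, (lo, hi), spline_smoothing, min_candidates)
    return erm, rpe


def segment_bscan(bscan: ImageGrid, params: SegmentationParams | None = None) -> LayerSegmentation:
    """Run the full segmentation chain on a B-scan panel.

    Stage failures are re-raised as :class:`SegmentationStageError` with the
    stage name attached; intermediates (envelope, ROI, raw and rejected
    candidates, parameters) are kept on the result for audit.
    """
    params = params or SegmentationParams()
    stage = "smooth"
    try:
        smoothed = smooth(bscan, params.smooth_kernel)
        stage = "enhance"
        enhanced = enhance(smoothed, params.enhance_sigma, params.enhance_alpha)
        stage = "row_envelope"
        env = row_envelope(
            enhanced,
            params.envelope_window if params.envelope_smooth else None,
        )
        stage = "detect_roi"
        roi = detect_roi(env, params.roi_threshold)
        stage = "detect_layer_candidates"
        cand = detect_layer_candidates(
            enhanced, roi,
            prominence_frac=params.peak_prominence_frac,
            single_peak_is_rpe=params.single_peak_is_rpe,
        )
        stage = "reject_outliers"
        cand = reject_outliers(cand, params.outlier_window, params.outlier_k,
                               params.mad_floor_px)
        stage = "fit_layers"
        erm, rpe = fit_layers(cand, params.n_samples, params.spline_smoothing,
                              params.min_candidates, params.min_span_frac)
    except Exception as exc:  # attach the stage name, keep the original as cause
        raise SegmentationStageError(stage, exc) from exc
    return LayerSegmentation(erm=erm, rpe=rpe, roi=roi, envelope=env, params=params)


def segmentation_to_dict(seg: LayerSegmentation) -> dict:
    """JSON-serializable view of a segmentation (traces, ROI, params)."""
    import dataclasses

    def trace(t: LayerTrace) -> dict:
        finite = np.isfinite(t.raw_rows)
        return {
            "kind": t.kind,
            "columns": t.columns.tolist(),
            "rows": t.rows.tolist(),
            "raw_columns": t.raw_columns[finite].tolist(),
            "raw_rows": t.raw_rows[finite].tolist(),
            "rejected_columns": t.raw_columns[t.rejected_mask].tolist(),
        }

    return {
        "erm": trace(seg.erm),
        "rpe": trace(seg.rpe),
        "roi": {"row_top": seg.roi.row_top, "row_bottom": seg.roi.row_bottom,
                "threshold": seg.roi.threshold},
        "envelope": seg.envelope.values.tolist(),
        "params": dataclasses.asdict(seg.params),
    }
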