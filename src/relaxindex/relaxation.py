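"""Relaxation Index: per-marker displacements and per-eye averages.

The Relaxation Index (RI) quantifies tangential epiretinal-membrane
traction as the shift of vessel-crossing reference points between two
visits.  Each crossing is projected vertically onto the retinal pigmented
epithelium (RPE) — assumed immobile — and the displacement is the Euclidean
distance, in the B-scan plane, between the two visits' RPE anchor points
(``rpe_anchored`` mode, the default).  An alternative reading measures from
the earlier visit's ERM point to the later visit's RPE anchor
(``erm_to_rpe``); both are available because the two are distinct published
descriptions of the same construct.

The per-eye RI for a timepoint pair is the arithmetic mean of its markers'
displacements, reported in millimetres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PairingError, RelaxIndexError, ShortMarkerCountWarning
from .ir_registration import MarkerProjection

logger = logging.getLogger(__name__)

#: The three analyzed timepoint contrasts, keyed by their (earlier, later) labels.
PAIRS: dict[tuple[str, str], str] = {
    ("T1", "T2"): "T1T2",
    ("T2", "POST"): "T2POST",
    ("T1", "POST"): "T1POST",
}

DISPLACEMENT_MODES = ("rpe_anchored", "erm_to_rpe")


@dataclass
class DisplacementRecord:
    """Displacement of one marker between two timepoints."""

    eye_id: str
    marker_id: int
    pair: str
    d_lateral_um: float
    d_axial_um: float
    d_total_mm: float
    mode: str


@dataclass
class RIMeasurement:
    """Per-eye Relaxation Index for one timepoint pair."""

    eye_id: str
    pair: str
    per_marker: list[DisplacementRecord]
    ri_mm: float
    n_markers: int


def _pair_label(tp_a: str, tp_b: str) -> str:
    if (tp_a, tp_b) in PAIRS:
        return PAIRS[(tp_a, tp_b)]
    if (tp_b, tp_a) in PAIRS:
        return PAIRS[(tp_b, tp_a)]
    raise PairingError(f"no defined contrast for timepoints ({tp_a}, {tp_b})")


def marker_displacement(
    proj_a: MarkerProjection,
    proj_b: MarkerProjection,
    mode: str = "rpe_anchored",
) -> DisplacementRecord:
    """Displacement (um components, mm total) of one marker between visits.

    ``rpe_anchored``: distance between the two RPE anchor points (symmetric
    in its arguments).  ``erm_to_rpe``: distance from the earlier visit's
    ERM point to the later visit's RPE anchor (order-dependent).
    """
    if mode not in DISPLACEMENT_MODES:
        raise ValueError(f"mode must be one of {DISPLACEMENT_MODES}, got {mode!r}")
    ma, mb = proj_a.marker, proj_b.marker
    if ma.eye_id != mb.eye_id or ma.marker_id != mb.marker_id:
        raise PairingError(
            f"cannot pair marker ({ma.eye_id}, {ma.marker_id}) with "
            f"({mb.eye_id}, {mb.marker_id})"
        )
    if ma.timepoint == mb.timepoint:
        raise PairingError(f"both projections are at timepoint {ma.timepoint}")

    a = np.asarray(proj_a.erm_point_um if mode == "erm_to_rpe" else proj_a.rpe_anchor_um)
    b = np.asarray(proj_b.rpe_anchor_um)
    d_lat, d_ax = (b - a).tolist()
    d_total_mm = float(np.hypot(d_lat, d_ax)) / 1000.0
    return DisplacementRecord(
        eye_id=ma.eye_id,
        marker_id=ma.marker_id,
        pair=_pair_label(ma.timepoint, mb.timepoint),
        d_lateral_um=float(d_lat),
        d_axial_um=float(d_ax),
        d_total_mm=d_total_mm,
        mode=mode,
    )


def eye_ri(records: list[DisplacementRecord], nominal_markers: int = 10) -> RIMeasurement:
    """Average the marker displacements of one eye/pair into its RI (mm)."""
    if not records:
        raise RelaxIndexError("cannot average an empty displacement list")
    eye_ids = {r.eye_id for r in records}
    pairs = {r.pair for r in records}
    if len(eye_ids) > 1 or len(pairs) > 1:
        raise PairingError(f"records mix eyes {eye_ids} / pairs {pairs}")
    n = len(records)
    if n != nominal_markers:
        warnings.warn(
            f"eye {records[0].eye_id} pair {records[0].pair}: {n} markers "
            f"instead of the nominal {nominal_markers}",
            ShortMarkerCountWarning,
        )
    return RIMeasurement(
        eye_id=records[0].eye_id,
        pair=records[0].pair,
        per_marker=list(records),
        ri_mm=float(np.mean([r.d_total_mm for r in records])),
        n_markers=n,
    )


def build_longitudinal_table(
    projections: list[MarkerProjection],
    mode: str = "rpe_anchored",
) -> pd.DataFrame:
    """Tidy per-marker displacement table across all eyes and defined pairs.

    One row per (eye, marker, pair); a pair is skipped (with a logged
    warning) for markers lacking one of its timepoints.  This is the input
    the mixed models consume.
    """
    by_key: dict[tuple[str, int], dict[str, MarkerProjection]] = {}
    for p in projections:
        by_key.setdefault((p.marker.eye_id, p.marker.marker_id), {})[p.marker.timepoint] = p

    rows = []
    for (eye, marker_id), tps in sorted(by_key.items()):
        for (tp_a, tp_b), pair in PAIRS.items():
            if tp_a not in tps or tp_b not in tps:
                logger.warning("eye %s marker %s: missing timepoint for pair %s; skipped",
                               eye, marker_id, pair)
                continue
            rec = marker_displacement(tps[tp_a], tps[tp_b], mode=mode)
            rows.append(vars(rec))
    return pd.DataFrame(
        rows, columns=["eye_id", "marker_id", "pair", "d_lateral_um",
                       "d_axial_um", "d_total_mm", "mode"],
    )


def summarize_ri(table: pd.DataFrame, nominal_markers: int = 10) -> pd.DataFrame:
    """Per-eye, per-pair RI summary from a longitudinal displacement table."""
    out = []
    for (eye, pair), grp in table.groupby(["eye_id", "pair"], sort=True):
        records = [DisplacementRecord(**rec) for rec in grp.to_dict("records")]
        m = eye_ri(records, nominal_markers=nominal_markers)
        out.append({"eye_id": eye, "pair": pair, "ri_mm": m.ri_mm,
                    "n_markers": m.n_markers})
    return pd.DataFrame(out, columns=["eye_id", "pair", "ri_mm", "n_markers"])
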