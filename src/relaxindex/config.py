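"""Pipeline configuration.

Every tunable of the processing chain lives here, with defaults matching the
published acquisition/processing constants where one exists (5x5 average
kernel, ROI threshold 0.4, 100 resample points, 3.9 um/px axial resolution,
30 degree field of view).  A :class:`RunConfig` is YAML-serializable so the
effective configuration of a run can be written next to its outputs and
replayed bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: ITU-R BT.601 luminance weights (R, G, B); they sum to 1 so constant color
#: images map to the same constant gray level.
GRAY_WEIGHTS: tuple[float, float, float] = (0.299, 0.587, 0.114)

#: Axial depth sampling of the B-scan, micrometres per pixel.
DEFAULT_AXIAL_UM_PER_PX: float = 3.9

#: Field of view of the acquisition, degrees.
DEFAULT_FOV_DEG: float = 30.0

#: Axial length assumed for the degrees-to-mm retinal scaling when no
#: biometry is available (emmetropic adult eye).
EMMETROPIC_AXIAL_LENGTH_MM: float = 23.3

#: Bennett-style scaling: q [mm/deg] = 0.01306 * (axial_length_mm - 1.82).
BENNETT_SLOPE: float = 0.01306
BENNETT_OFFSET_MM: float = 1.82


@dataclass
class SplitParams:
    """Panel separation of the composite export."""

    ir_side: str = "left"            # which side of the seam is the IR panel
    interior_lo: float = 0.2         # seam search window, fraction of width
    interior_hi: float = 0.8
    gradient_floor: float = 0.05     # min seam strength, fraction of n_rows * dynamic range


@dataclass
class SegmentationParams:
    """B-scan layer segmentation chain."""

    smooth_kernel: int = 5           # uniform average kernel (px)
    enhance_sigma: float = 3.0       # Gaussian sigma of the unsharp-mask low-pass (px)
    enhance_alpha: float = 1.0       # high-pass gain
    envelope_smooth: bool = True     # moving-average the row-max profile
    envelope_window: int = 5         # rows
    roi_threshold: float = 0.4       # on the normalized envelope
    peak_prominence_frac: float = 0.05   # of the column dynamic range inside the ROI
    single_peak_is_rpe: bool = False  # columns with one peak: treat it as RPE?
    outlier_window: int = 7          # neighbor columns for median/MAD rejection
    outlier_k: float = 3.0
    mad_floor_px: float = 2.0        # absolute floor on the MAD term
    spline_smoothing: float = 0.1    # per-point squared-residual budget (px^2)
    n_samples: int = 100             # resampled trace points
    min_candidates: int = 10         # per layer, post-rejection
    min_span_frac: float = 0.5       # of the B-scan width


@dataclass
class RegistrationParams:
    """IR arrow detection and IR -> B-scan coordinate mapping."""

    green_margin: float = 0.2        # green plane must exceed both others by this
    min_run: int = 32                # minimum arrow length (px)
    axial_um_per_px: float = DEFAULT_AXIAL_UM_PER_PX
    fov_deg: float = DEFAULT_FOV_DEG
    fallback_axial_length_mm: float = EMMETROPIC_AXIAL_LENGTH_MM


@dataclass
class DisplacementParams:
    """Relaxation Index computation."""

    mode: str = "rpe_anchored"       # or "erm_to_rpe"
    nominal_markers: int = 10


@dataclass
class StatsParams:
    """Mixed-model options."""

    reml: bool = True


@dataclass
class RunConfig:
    """Complete, serializable configuration of one pipeline run."""

    split: SplitParams = field(default_factory=SplitParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    displacement: DisplacementParams = field(default_factory=DisplacementParams)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            split=SplitParams(**d.get("split", {})),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            registration=RegistrationParams(**d.get("registration", {})),
            displacement=DisplacementParams(**d.get("displacement", {})),
            stats=StatsParams(**d.get("stats", {})),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
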