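"""Reading and splitting composite IR + B-scan exports.

Clinical OCT review software exports a single image holding the infrared
(IR) fundus picture and the OCT B-scan side by side.  This module converts
such exports to grayscale, finds the vertical seam between the two panels
from the horizontal intensity gradient, and returns the panels as
:class:`ImageGrid` objects ready for segmentation and registration.

Intensities are normalized to [0, 1] floats on load (8-bit and 16-bit
PNG/TIFF are accepted).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .config import GRAY_WEIGHTS, SplitParams
from .errors import BoundaryNotFoundError, ImageShapeError

MIN_PANEL_SIZE = 16


@dataclass
class ImageGrid:
    """2-D intensity raster with optional physical pixel scales.

    Rows are vertical (axial for a B-scan, row 0 at top), columns are
    horizontal (lateral).  ``row_scale_um``/``col_scale_um`` are micrometres
    per pixel and stay ``None`` until the registration stage assigns them.
    """

    pixels: np.ndarray
    row_scale_um: float | None = None
    col_scale_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ImageShapeError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < MIN_PANEL_SIZE:
            raise ImageShapeError(
                f"image {self.pixels.shape} smaller than {MIN_PANEL_SIZE}x{MIN_PANEL_SIZE}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ImageShapeError("image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ImageShapeError("image contains negative intensities")
        for name in ("row_scale_um", "col_scale_um"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ImageShapeError(f"{name} must be strictly positive, got {v}")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CompositePanel:
    """Result of splitting a composite export at the seam column.

    ``ir_color`` keeps the IR panel's color planes (needed for green-arrow
    detection); it is ``None`` when the composite was grayscale.  The seam
    column itself belongs to the right panel.
    """

    ir: ImageGrid
    bscan: ImageGrid
    boundary_col: int
    ir_color: np.ndarray | None = None


def normalize_intensities(raw: np.ndarray) -> np.ndarray:
    """Map integer images to [0, 1] floats; float input is passed through."""
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    return arr.astype(float)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF export, normalized to [0,1]; RGBA is reduced to RGB."""
    arr = iio.imread(Path(path))
    arr = normalize_intensities(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def to_grayscale(color_image: np.ndarray) -> ImageGrid:
    """Convert a 3-plane raster to luminance with ITU-style weights.

    The weights (:data:`relaxindex.config.GRAY_WEIGHTS`) sum to one, so a
    constant color image maps to the same constant gray value.
    """
    arr = np.asarray(color_image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageShapeError(f"expected an HxWx3 raster, got shape {arr.shape}")
    w = np.asarray(GRAY_WEIGHTS)
    return ImageGrid(arr @ w)


def _as_gray_array(composite: "ImageGrid | np.ndarray") -> tuple[np.ndarray, np.ndarray | None]:
    """Return (grayscale array, color array or None) for a composite input."""
    if isinstance(composite, ImageGrid):
        return composite.pixels, None
    arr = np.asarray(composite, dtype=float)
    if arr.ndim == 3:
        return to_grayscale(arr).pixels, arr
    return ImageGrid(arr).pixels, None


def split_composite(
    composite: "ImageGrid | np.ndarray",
    params: SplitParams | None = None,
) -> CompositePanel:
    """Split a composite export into IR and B-scan panels at the seam.

    The seam is located as the strongest vertical edge of the grayscale
    composite: the column-summed absolute horizontal (forward) gradient is
    maximized over the interior 20-80% of the width, and ``boundary_col`` is
    the first column to the right of that edge.  A configurable floor on the
    seam strength guards against constant or seamless images.
    """
    params = params or SplitParams()
    gray, color = _as_gray_array(composite)
    n_rows, n_cols = gray.shape
    if n_cols < 2 * MIN_PANEL_SIZE:
        raise ImageShapeError(f"composite width {n_cols} below the two-panel minimum")

    grad = np.abs(np.diff(gray, axis=1)).sum(axis=0)  # grad[c] = edge between c and c+1
    lo = int(np.floor(params.interior_lo * n_cols))
    hi = int(np.ceil(params.interior_hi * n_cols))
    interior = grad[lo:hi]

    dyn = float(gray.max() - gray.min())
    floor = params.gradient_floor * n_rows * dyn
    if dyn == 0 or interior.size == 0 or interior.max() <= floor:
        raise BoundaryNotFoundError(
            "no boundary found: no interior column exceeds the gradient floor"
        )

    boundary_col = lo + int(np.argmax(interior)) + 1  # seam column goes to the right panel
    left, right = gray[:, :boundary_col], gray[:, boundary_col:]
    if params.ir_side == "left":
        ir_gray, bscan = left, right
        ir_color = color[:, :boundary_col] if color is not None else None
    elif params.ir_side == "right":
        ir_gray, bscan = right, left
        ir_color = color[:, boundary_col:] if color is not None else None
    else:
        raise ValueError(f"ir_side must be 'left' or 'right', got {params.ir_side!r}")

    return CompositePanel(
        ir=ImageGrid(ir_gray.copy()),
        bscan=ImageGrid(bscan.copy()),
        boundary_col=boundary_col,
        ir_color=None if ir_color is None else ir_color.copy(),
    )


def write_panels(panel: CompositePanel, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Save split panels as ``<stem>_ir.png`` and ``<stem>_bscan.png`` (16-bit)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ir_path = out_dir / f"{stem}_ir.png"
    bscan_path = out_dir / f"{stem}_bscan.png"
    if panel.ir_color is not None:  # color stays 8-bit RGB; grayscale gets 16-bit depth
        iio.imwrite(ir_path, np.round(np.clip(panel.ir_color, 0, 1) * 255).astype(np.uint8))
    else:
        iio.imwrite(ir_path, np.round(np.clip(panel.ir.pixels, 0, 1) * 65535).astype(np.uint16))
    iio.imwrite(bscan_path, np.round(np.clip(panel.bscan.pixels, 0, 1) * 65535).astype(np.uint16))
    return ir_path, bscan_path
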