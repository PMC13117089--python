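"""Frame containers, ROI geometry, and intensity preprocessing.

A B-mode frame is stored row-major with row index = axial depth
(increasing downward, so a posterior shadow lies at *larger* row index)
and column index = lateral position.  All boxes are half-open,
0-based: ``[row0, row0 + n_rows) x [col0, col0 + n_cols)``.

Intensities are processed on a "scaled intensity unit" (SIU) scale:
after min-max normalization to [0, 1] the image is multiplied by
``scale_max`` (default 1000).  The empirical screening thresholds used
downstream (local contrast 300, shadow region 100) are expressed in
SIU and apply to this scale directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter

from .exceptions import FrameReadError, ValidationError

DEFAULT_PIXEL_SPACING_MM = 0.35
DEFAULT_SCALE_MAX = 1000.0


@dataclass(frozen=True)
class UltrasoundFrame:
    """A single grayscale B-mode frame.

    Parameters
    ----------
    pixels
        2-D float array of non-negative echo intensities; rows are axial
        depth (down = deeper), columns are lateral position.
    pixel_spacing_mm
        Physical size of one pixel in millimetres (isotropic).
    source_id
        Opaque identifier for provenance (file stem, phantom id, ...).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"frame must be a non-empty 2-D grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValidationError("frame contains non-finite intensities")
        if px.min() < 0:
            raise ValidationError("frame contains negative intensities")
        if not self.pixel_spacing_mm > 0:
            raise ValidationError(f"pixel_spacing_mm must be > 0, got {self.pixel_spacing_mm}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RoiBox:
    """Half-open rectangular box ``[row0, row0+n_rows) x [col0, col0+n_cols)``."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError(f"box extents must be >= 1, got {self.n_rows}x{self.n_cols}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValidationError(f"box origin must be non-negative, got ({self.row0},{self.col0})")

    @property
    def row_end(self) -> int:
        return self.row0 + self.n_rows

    @property
    def col_end(self) -> int:
        return self.col0 + self.n_cols

    def validate_within(self, height: int, width: int) -> None:
        if self.row_end > height:
            raise ValidationError(
                f"box bottom edge {self.row_end} exceeds frame height {height}"
            )
        if self.col_end > width:
            raise ValidationError(
                f"box right edge {self.col_end} exceeds frame width {width}"
            )

    def translated(self, d_row: int, d_col: int) -> "RoiBox":
        return RoiBox(self.row0 + d_row, self.col0 + d_col, self.n_rows, self.n_cols)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row_end), slice(self.col0, self.col_end)


@dataclass(frozen=True)
class NormalizedImage:
    """Min-max normalized image on the SIU scale ``[0, scale_max]``."""

    pixels: np.ndarray
    scale_max: float = DEFAULT_SCALE_MAX

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError(f"normalized image must be non-empty 2-D, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = np.asarray(ds.pixel_array, dtype=np.float64)
    elif suffix in {".tif", ".tiff"}:
        import tifffile

        arr = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    else:
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    return arr


def load_frame(
    path: str | Path,
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM,
) -> UltrasoundFrame:
    """Load a PNG/TIFF/DICOM raster as a grayscale frame.

    RGB(A) inputs are reduced to one plane by an unweighted channel
    mean (clinical B-mode exports are gray-in-RGB, so any channel
    convention is equivalent); the alpha channel, if present, is
    dropped first.
    """
    path = Path(path)
    if not path.exists():
        raise FrameReadError(f"no such file: {path}")
    try:
        arr = _read_raster(path)
    except FrameReadError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap reader-specific errors
        raise FrameReadError(f"could not read {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"{path}: expected a non-empty 2-D raster, got shape {arr.shape}")
    return UltrasoundFrame(arr, pixel_spacing_mm=pixel_spacing_mm, source_id=path.stem)


def crop_roi(frame: UltrasoundFrame, roi: RoiBox) -> UltrasoundFrame:
    """Extract the ROI as a new frame; pixel spacing is inherited."""
    roi.validate_within(frame.height, frame.width)
    sub = frame.pixels[roi.slices()].copy()
    return replace(frame, pixels=sub)


def normalize_minmax(
    frame: UltrasoundFrame, scale_max: float = DEFAULT_SCALE_MAX
) -> NormalizedImage:
    """Min-max normalize to [0, 1] and rescale to [0, scale_max] SIU.

    A constant input maps to all zeros (the degenerate case of the
    min-max map).
    """
    px = frame.pixels
    lo = px.min()
    hi = px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo) * scale_max
    return NormalizedImage(out, scale_max=scale_max)


def median_denoise(image: NormalizedImage, kernel: int = 3) -> NormalizedImage:
    """Median filter with a ``kernel x kernel`` window, edge-replicated borders."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValidationError(f"median kernel must be odd and >= 1, got {kernel}")
    out = median_filter(image.pixels, size=kernel, mode="nearest")
    return NormalizedImage(out, scale_max=image.scale_max)
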