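"""Stone candidate generation.

Locally hyperechoic, stone-like blobs are isolated with a white
top-hat transform (disk structuring element), thresholded at a high
percentile of the enhanced image, cleaned of small components, gated
to peak-like components via regional maxima, and packaged as
:class:`CandidateRegion` objects with region descriptors.

Two per-candidate features are computed here:

* ``brightness`` = mu * A, the integrated intensity of the candidate
  (mean SIU intensity times pixel area);
* ``shape_penalty`` = alpha*ecc + beta*max(0, 1 - solidity)
  + gamma*max(0, L_max/L_min - elong_tol), penalizing line-like,
  fragmented, or over-elongated shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import measure, morphology

from .exceptions import ValidationError
from .frame_io import NormalizedImage, RoiBox

#: Elongation-term value used when the minor axis degenerates to zero
#: (single-row/column components): the ratio is unbounded, so the term
#: saturates at this cap.
ELONGATION_CAP = 10.0


@dataclass(frozen=True)
class CandidateParams:
    """Tunable parameters of candidate generation.

    Defaults follow the reference operating point: disk radius 5 px,
    99th-percentile threshold, 20 px minimum area, at most 5 retained
    candidates, penalty weights (0.4, 0.3, 0.3).  ``elong_tol`` is the
    axis-ratio tolerance below which no elongation penalty is charged;
    setting it to 0 recovers a raw-ratio penalty.
    """

    se_radius: int = 5
    percentile_q: float = 99.0
    min_area: int = 20
    top_k: int = 5
    alpha: float = 0.4
    beta: float = 0.3
    gamma: float = 0.3
    elong_tol: float = 2.0
    brightness_mode: str = "product"  # "product" (mu*A) or "mean" (mu)

    def __post_init__(self) -> None:
        if self.se_radius < 1:
            raise ValidationError("se_radius must be >= 1")
        if not 0 < self.percentile_q < 100:
            raise ValidationError("percentile_q must be in (0, 100)")
        if self.min_area < 1:
            raise ValidationError("min_area must be >= 1")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValidationError("penalty weights must be non-negative")
        if self.elong_tol < 0:
            raise ValidationError("elong_tol must be >= 0")
        if self.brightness_mode not in {"product", "mean"}:
            raise ValidationError(f"unknown brightness_mode {self.brightness_mode!r}")


@dataclass(frozen=True)
class CandidateRegion:
    """One 8-connected candidate component with its region descriptors.

    ``centroid_x``/``centroid_y`` are real-valued pixel coordinates
    (x lateral = column, y axial = row).  ``coords`` is an (N, 2) array
    of (row, col) member pixels.  ``brightness`` and ``shape_penalty``
    are filled by :func:`featurize`.
    """

    label: int
    coords: np.ndarray
    area: int
    mean_intensity: float
    centroid_x: float
    centroid_y: float
    bbox: RoiBox
    eccentricity: float
    solidity: float
    axis_major: float
    axis_minor: float
    brightness: float = float("nan")
    shape_penalty: float = float("nan")

    def translated(self, d_row: int, d_col: int) -> "CandidateRegion":
        """Shift all coordinates by (d_row, d_col), e.g. ROI -> frame space."""
        return replace(
            self,
            coords=self.coords + np.array([d_row, d_col]),
            centroid_x=self.centroid_x + d_col,
            centroid_y=self.centroid_y + d_row,
            bbox=self.bbox.translated(d_row, d_col),
        )


def tophat_enhance(image: NormalizedImage, se_radius: int = 5) -> NormalizedImage:
    """White top-hat: image minus its opening with a disk of ``se_radius``.

    Bright structures too narrow to contain the disk are retained;
    wider structures and slowly varying background are suppressed
    toward zero.  Output is non-negative.
    """
    if se_radius < 1:
        raise ValidationError("se_radius must be >= 1")
    footprint = morphology.disk(se_radius)
    out = morphology.white_tophat(image.pixels, footprint=footprint)
    return NormalizedImage(out, scale_max=image.scale_max)


def threshold_candidates(enhanced: NormalizedImage, percentile_q: float = 99.0) -> np.ndarray:
    """Binary map of pixels *strictly above* the q-th percentile.

    The percentile is computed over all pixels with linear
    interpolation.  On an all-equal image the threshold equals every
    value and the map is empty ("no candidates").
    """
    if not 0 < percentile_q < 100:
        raise ValidationError("percentile_q must be in (0, 100)")
    thr = np.percentile(enhanced.pixels, percentile_q)
    return enhanced.pixels > thr


def remove_small(mask: np.ndarray, min_area: int = 20) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_area`` pixels."""
    if min_area < 1:
        raise ValidationError("min_area must be >= 1")
    # skimage >= 0.26 removes components with area <= max_size
    return morphology.remove_small_objects(
        np.asarray(mask, dtype=bool), max_size=min_area - 1, connectivity=2
    )


def regional_maxima_gate(mask: np.ndarray, enhanced: NormalizedImage) -> np.ndarray:
    """Keep only mask components that contain a regional maximum of ``enhanced``.

    A regional maximum is a connected plateau all of whose outside
    neighbors are strictly lower; requiring one inside each component
    enforces peak-like candidates and suppresses broad bright areas.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != enhanced.pixels.shape:
        raise ValidationError("mask and enhanced image shapes differ")
    if not mask.any():
        return mask.copy()
    maxima = morphology.local_maxima(enhanced.pixels, connectivity=2)
    labels = measure.label(mask, connectivity=2)
    keep_labels = np.unique(labels[maxima & mask])
    keep_labels = keep_labels[keep_labels != 0]
    return np.isin(labels, keep_labels)


def extract_regions(mask: np.ndarray, image: NormalizedImage) -> list[CandidateRegion]:
    """Describe every 8-connected component of ``mask``.

    Descriptors follow the moment-equivalent-ellipse convention:
    centroid is the pixel-coordinate mean, eccentricity and axis
    lengths come from the second central moments, and solidity is
    area over convex-hull area.  Mean intensity is taken from
    ``image`` (the denoised SIU image, not the top-hat response).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.pixels.shape:
        raise ValidationError("mask and image shapes differ")
    labels = measure.label(mask, connectivity=2)
    regions: list[CandidateRegion] = []
    for rp in measure.regionprops(labels, intensity_image=image.pixels):
        min_row, min_col, max_row, max_col = rp.bbox
        regions.append(
            CandidateRegion(
                label=int(rp.label),
                coords=np.asarray(rp.coords, dtype=np.int64),
                area=int(rp.area),
                mean_intensity=float(rp.intensity_mean),
                centroid_x=float(rp.centroid[1]),
                centroid_y=float(rp.centroid[0]),
                bbox=RoiBox(min_row, min_col, max_row - min_row, max_col - min_col),
                eccentricity=float(rp.eccentricity),
                solidity=float(rp.solidity),
                axis_major=float(rp.axis_major_length),
                axis_minor=float(rp.axis_minor_length),
            )
        )
    return regions


def shape_penalty(region: CandidateRegion, params: CandidateParams) -> float:
    """alpha*ecc + beta*max(0, 1-solidity) + gamma*max(0, L_max/L_min - tol).

    A degenerate minor axis (collinear pixels) means unbounded
    elongation; the ratio term then saturates at :data:`ELONGATION_CAP`.
    """
    if region.axis_minor <= 0.0:
        elong_term = ELONGATION_CAP
    else:
        elong_term = max(0.0, region.axis_major / region.axis_minor - params.elong_tol)
    return (
        params.alpha * region.eccentricity
        + params.beta * max(0.0, 1.0 - region.solidity)
        + params.gamma * elong_term
    )


def brightness(region: CandidateRegion, mode: str = "product") -> float:
    """Candidate salience: integrated intensity mu*A (or bare mu)."""
    if mode == "product":
        return region.mean_intensity * region.area
    if mode == "mean":
        return region.mean_intensity
    raise ValidationError(f"unknown brightness_mode {mode!r}")


def featurize(
    regions: list[CandidateRegion], params: CandidateParams
) -> list[CandidateRegion]:
    """Fill ``brightness`` and ``shape_penalty`` on each region."""
    return [
        replace(
            r,
            brightness=brightness(r, params.brightness_mode),
            shape_penalty=shape_penalty(r, params),
        )
        for r in regions
    ]


def select_top_k(regions: list[CandidateRegion], k: int = 5) -> list[CandidateRegion]:
    """Retain the ``k`` brightest candidates.

    Ties are broken deterministically: shallower centroid (smaller y)
    first, then smaller x.
    """
    if k < 1:
        raise ValidationError("top_k must be >= 1")
    ordered = sorted(
        regions, key=lambda r: (-r.brightness, r.centroid_y, r.centroid_x)
    )
    return ordered[:k]


def generate_candidates(
    image: NormalizedImage, params: CandidateParams
) -> list[CandidateRegion]:
    """Full candidate stage: enhance, threshold, clean, gate, describe, top-K."""
    enhanced = tophat_enhance(image, params.se_radius)
    mask = threshold_candidates(enhanced, params.percentile_q)
    mask = remove_small(mask, params.min_area)
    mask = regional_maxima_gate(mask, enhanced)
    regions = featurize(extract_regions(mask, image), params)
    return select_top_k(regions, params.top_k)
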