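"""Candidate screening: local contrast and posterior shadow region tests.

Each surviving candidate is screened twice.

1. *Local contrast*: mean intensity inside the candidate bounding box
   minus the mean over a surrounding ring (box expanded by
   ``ring_margin`` on every side, candidate box excluded, clipped to
   the image).  Candidates below ``tau_lc`` are rejected.

2. *Shadow region*: axial intensity profiles are taken beneath the
   candidate -- a center band of width ``2h+1`` columns around the
   candidate centroid (PC) and left/right reference bands offset
   laterally (PL), each averaged per row over ``depth`` rows.  The
   score is

       mean_y(PL - PC) + rho * (median(PCe) - median(PCl))

   where PCe is the profile segment up to the steepest decrease of PC
   and PCl the segment from just after it to the steepest subsequent
   increase.  The first term measures *selective* beam attenuation
   under the candidate relative to its flanks; the second rewards the
   bright-stone -> dark-shadow transition itself.  Candidates below
   ``tau_sr`` are rejected.

Both statistics are differences, hence invariant to adding a constant
to the image; they scale linearly with any intensity rescaling, which
is why they are defined on the fixed SIU scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .candidates import CandidateRegion
from .exceptions import (
    RingUndefinedError,
    ShadowNotEvaluableError,
    ValidationError,
)
from .frame_io import NormalizedImage, RoiBox

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenParams:
    """Screening parameters (SIU thresholds, band geometry in pixels).

    Defaults are the empirical operating point: ring margin 5 px,
    tau_lc = 300 SIU, center band width 5 px (halfwidth 2), analysis
    depth 30 px, lateral offset 10 px, rho = 0.5, tau_sr = 100 SIU.
    """

    ring_margin: int = 5
    tau_lc: float = 300.0
    band_halfwidth: int = 2
    depth: int = 30
    lateral_offset: int = 10
    rho: float = 0.5
    tau_sr: float = 100.0
    pce_mode: str = "segment"  # "segment" (medians of segments) or "value"

    def __post_init__(self) -> None:
        if self.ring_margin < 1 or self.depth < 1 or self.lateral_offset < 1:
            raise ValidationError("ring_margin, depth and lateral_offset must be >= 1")
        if self.band_halfwidth < 0:
            raise ValidationError("band_halfwidth must be >= 0")
        if self.pce_mode not in {"segment", "value"}:
            raise ValidationError(f"unknown pce_mode {self.pce_mode!r}")


@dataclass(frozen=True)
class ShadowProfilePair:
    """Axial center/lateral profiles beneath a candidate.

    ``y_start`` is the absolute row of PC[0] (first row below the
    candidate bounding box).  ``y_drop`` and ``y_rise`` are indices
    *into the profile*: y_drop marks the last row before the steepest
    forward decrease of PC, y_rise the last row before the steepest
    subsequent increase.  ``pce`` = PC[:y_drop+1] and
    ``pcl`` = PC[y_drop+1:y_rise+1]; both empty when no drop exists.
    """

    y_start: int
    pc: np.ndarray
    pl: np.ndarray
    y_drop: int | None
    y_rise: int | None
    pce: np.ndarray
    pcl: np.ndarray

    @property
    def valid_rows(self) -> int:
        return len(self.pc)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of both screens for one candidate."""

    local_contrast: float
    shadow_region: float
    passed_lc: bool
    passed_sr: bool
    profile: ShadowProfilePair | None
    reasons: tuple[str, ...] = ()


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def ring_means(
    image: NormalizedImage, bbox: RoiBox, ring_margin: int = 5
) -> tuple[float, float]:
    """Mean intensity inside ``bbox`` and over the surrounding ring.

    The ring is the box expanded by ``ring_margin`` on every side,
    clipped to the image, with the candidate box removed.  An empty
    ring (box spans the whole image) raises :class:`RingUndefinedError`.
    """
    h, w = image.pixels.shape
    bbox.validate_within(h, w)
    inner = image.pixels[bbox.slices()]
    is_bar = float(inner.mean())

    r0 = max(0, bbox.row0 - ring_margin)
    c0 = max(0, bbox.col0 - ring_margin)
    r1 = min(h, bbox.row_end + ring_margin)
    c1 = min(w, bbox.col_end + ring_margin)
    ring_mask = np.zeros((h, w), dtype=bool)
    ring_mask[r0:r1, c0:c1] = True
    ring_mask[bbox.slices()] = False
    if not ring_mask.any():
        raise RingUndefinedError("ring empty after clipping: box spans the image")
    ir_bar = float(image.pixels[ring_mask].mean())
    return is_bar, ir_bar


def local_contrast(is_bar: float, ir_bar: float) -> float:
    """Candidate-minus-ring mean intensity difference (may be negative)."""
    return is_bar - ir_bar


def _band_columns(center: int, halfwidth: int, width: int) -> np.ndarray:
    cols = np.arange(center - halfwidth, center + halfwidth + 1)
    return cols[(cols >= 0) & (cols < width)]


def axial_profiles(
    image: NormalizedImage, region: CandidateRegion, params: ScreenParams
) -> ShadowProfilePair:
    """Compute PC/PL beneath ``region`` and locate the drop/rise rows.

    Rows run from the first row below the candidate bounding box for
    up to ``depth`` rows (clipped to the image).  The center band is
    ``2h+1`` columns around the rounded centroid; the lateral
    reference is the union of the left and right offset bands (if one
    band is fully outside the image the other alone is used).
    """
    h, w = image.pixels.shape
    y_start = region.bbox.row_end
    y_end = min(y_start + params.depth, h)
    if y_start >= h:
        raise ShadowNotEvaluableError("no in-bounds rows below the candidate")

    cx = _round_half_away(region.centroid_x)
    center_cols = _band_columns(cx, params.band_halfwidth, w)
    if center_cols.size == 0:
        raise ShadowNotEvaluableError("center band fully outside the image")
    left_cols = _band_columns(cx - params.lateral_offset, params.band_halfwidth, w)
    right_cols = _band_columns(cx + params.lateral_offset, params.band_halfwidth, w)
    lateral_cols = np.union1d(left_cols, right_cols)
    if lateral_cols.size == 0:
        raise ShadowNotEvaluableError("both lateral bands fully outside the image")

    rows = image.pixels[y_start:y_end]
    pc = rows[:, center_cols].mean(axis=1)
    pl = rows[:, lateral_cols].mean(axis=1)

    diffs = np.diff(pc)
    if diffs.size == 0:
        y_drop: int | None = None
        y_rise: int | None = None
        pce = np.empty(0)
        pcl = np.empty(0)
    else:
        y_drop = int(np.argmin(diffs))
        pce = pc[: y_drop + 1]
        if y_drop + 1 <= diffs.size - 1:
            later = diffs[y_drop + 1 :]
            y_rise = y_drop + 1 + int(np.argmax(later))
            pcl = pc[y_drop + 1 : y_rise + 1]
        else:
            y_rise = None
            pcl = np.empty(0)
    return ShadowProfilePair(
        y_start=y_start, pc=pc, pl=pl, y_drop=y_drop, y_rise=y_rise, pce=pce, pcl=pcl
    )


def shadow_region_score(
    profile: ShadowProfilePair, rho: float = 0.5, pce_mode: str = "segment"
) -> float:
    """mean_y(PL - PC) + rho * (median(PCe) - median(PCl)).

    When the drop/rise segments are degenerate (no drop, or the drop
    sits at the last profile row) the second term is 0.
    """
    term1 = float(np.mean(profile.pl - profile.pc))
    if profile.y_drop is None or profile.pce.size == 0 or profile.pcl.size == 0:
        logger.debug("degenerate drop/rise segments; transition term set to 0")
        return term1
    if pce_mode == "segment":
        term2 = float(np.median(profile.pce) - np.median(profile.pcl))
    elif pce_mode == "value":
        term2 = float(profile.pc[profile.y_drop] - profile.pc[profile.y_rise])
    else:
        raise ValidationError(f"unknown pce_mode {pce_mode!r}")
    return term1 + rho * term2


def evaluate_candidate(
    image: NormalizedImage, region: CandidateRegion, params: ScreenParams
) -> ScreenResult:
    """Run both screens on one candidate; never raises for geometry issues.

    Non-evaluable statistics are recorded as NaN with a reason code
    (``ring_undefined`` / ``shadow_not_evaluable``); pass flags are
    False for non-evaluable screens.
    """
    reasons: list[str] = []
    try:
        is_bar, ir_bar = ring_means(image, region.bbox, params.ring_margin)
        lc = local_contrast(is_bar, ir_bar)
        passed_lc = lc >= params.tau_lc
        if not passed_lc:
            reasons.append("low_local_contrast")
    except RingUndefinedError:
        lc = float("nan")
        passed_lc = False
        reasons.append("ring_undefined")

    profile: ShadowProfilePair | None
    try:
        profile = axial_profiles(image, region, params)
        sr = shadow_region_score(profile, params.rho, params.pce_mode)
        passed_sr = sr >= params.tau_sr
        if not passed_sr:
            reasons.append("low_shadow_region")
    except ShadowNotEvaluableError:
        profile = None
        sr = float("nan")
        passed_sr = False
        reasons.append("shadow_not_evaluable")

    return ScreenResult(
        local_contrast=lc,
        shadow_region=sr,
        passed_lc=passed_lc,
        passed_sr=passed_sr,
        profile=profile,
        reasons=tuple(reasons),
    )


def screen(
    image: NormalizedImage,
    candidates: list[CandidateRegion],
    params: ScreenParams,
    enable_lc: bool = True,
    enable_sr: bool = True,
) -> list[tuple[CandidateRegion, ScreenResult]]:
    """Screen every candidate; return the survivors with their results.

    A disabled screen neither rejects nor contributes, but its value
    is still computed and recorded (for ablation reports).
    """
    survivors: list[tuple[CandidateRegion, ScreenResult]] = []
    for region in candidates:
        result = evaluate_candidate(image, region, params)
        if enable_lc and not result.passed_lc:
            logger.debug("candidate %d rejected: %s", region.label, result.reasons)
            continue
        if enable_sr and not result.passed_sr:
            logger.debug("candidate %d rejected: %s", region.label, result.reasons)
            continue
        survivors.append((region, result))
    return survivors
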