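"""Composite scoring, winner selection, and the full detection pipeline.

The total score of a screened candidate is

    w_B * brightness + w_C * local_contrast + w_S * shadow_region
    - w_P * shape_penalty.

The four features live on very different scales (integrated intensity
~1e3-1e4 SIU*px, contrasts ~1e2-1e3 SIU, penalty ~0-1), so each
feature is min-max normalized across the surviving candidates of the
image before weighting; winner selection is invariant to any common
monotone rescaling, and normalization makes the weights commensurate.
A ``raw`` mode (no normalization) is retained for sensitivity
experiments.

``detect`` chains the whole pipeline on one frame + ROI:
crop -> normalize -> denoise -> top-hat -> threshold -> clean ->
maxima gate -> describe -> top-K -> screens -> score -> select ->
shadow onset -> posterior shadow ROI.  It is a pure function of
(pixels, roi, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .candidates import CandidateRegion, generate_candidates
from .config import RunConfig, ScoreWeights
from .exceptions import ValidationError
from .frame_io import NormalizedImage, RoiBox, UltrasoundFrame, crop_roi, median_denoise, normalize_minmax
from .screening import ScreenResult, ShadowProfilePair, screen

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredCandidate:
    region: CandidateRegion
    screen_result: ScreenResult
    total: float
    normalized_features: tuple[float, float, float, float]  # (B, C, S, P)


@dataclass(frozen=True)
class DetectionResult:
    """Final detection output for one frame.

    All coordinates are in full-frame space.  ``status`` is
    ``"detected"`` or ``"no_candidate"``; in the latter case every
    other field is None/empty.
    """

    status: str
    winner: CandidateRegion | None = None
    total_score: float | None = None
    component_scores: dict[str, float] | None = None
    shadow_onset_row: int | None = None
    shadow_roi: RoiBox | None = None
    ranked_alternates: tuple[tuple[int, float], ...] = ()

    @property
    def detected(self) -> bool:
        return self.status == "detected"


def total_score(
    brightness: float,
    local_contrast: float,
    shadow_region: float,
    shape_penalty: float,
    weights: ScoreWeights,
) -> float:
    """Weighted combination of (already commensurate) features."""
    return (
        weights.w_brightness * brightness
        + weights.w_contrast * local_contrast
        + weights.w_shadow * shadow_region
        - weights.w_penalty * shape_penalty
    )


def _normalize_feature(values: np.ndarray, is_penalty: bool) -> np.ndarray:
    """Min-max normalize one feature column across candidates.

    Convention for a degenerate spread (single candidate or all-equal
    values): salience features map to 1 so they contribute fully; the
    penalty maps to 0 when its raw value is 0 (no shape defect should
    cost nothing) and to 1 otherwise.
    """
    values = np.where(np.isfinite(values), values, 0.0)
    lo, hi = values.min(), values.max()
    if hi > lo:
        return (values - lo) / (hi - lo)
    if is_penalty:
        return np.where(values == 0.0, 0.0, 1.0)
    return np.ones_like(values)


def score_candidates(
    survivors: list[tuple[CandidateRegion, ScreenResult]],
    weights: ScoreWeights,
    normalization: str = "minmax",
) -> list[ScoredCandidate]:
    """Normalize features across survivors and compute total scores."""
    if normalization not in {"minmax", "raw"}:
        raise ValidationError(f"unknown score normalization {normalization!r}")
    if not survivors:
        return []
    b = np.array([r.brightness for r, _ in survivors], dtype=float)
    c = np.array([s.local_contrast for _, s in survivors], dtype=float)
    s_ = np.array([s.shadow_region for _, s in survivors], dtype=float)
    p = np.array([r.shape_penalty for r, _ in survivors], dtype=float)
    if normalization == "minmax":
        b = _normalize_feature(b, is_penalty=False)
        c = _normalize_feature(c, is_penalty=False)
        s_ = _normalize_feature(s_, is_penalty=False)
        p = _normalize_feature(p, is_penalty=True)
    else:
        # raw mode: non-evaluable (NaN) statistics contribute 0
        c = np.where(np.isfinite(c), c, 0.0)
        s_ = np.where(np.isfinite(s_), s_, 0.0)
    scored = []
    for i, (region, result) in enumerate(survivors):
        scored.append(
            ScoredCandidate(
                region=region,
                screen_result=result,
                total=total_score(b[i], c[i], s_[i], p[i], weights),
                normalized_features=(float(b[i]), float(c[i]), float(s_[i]), float(p[i])),
            )
        )
    return scored


def select_best(scored: list[ScoredCandidate]) -> ScoredCandidate | None:
    """Highest total score wins; ties broken by higher shadow-region
    score, then shallower centroid, then smaller lateral position.
    An empty list yields None (no candidate)."""
    if not scored:
        return None

    def sr_key(sc: ScoredCandidate) -> float:
        sr = sc.screen_result.shadow_region
        return sr if np.isfinite(sr) else -np.inf

    return max(
        scored,
        key=lambda sc: (
            sc.total,
            sr_key(sc),
            -sc.region.centroid_y,
            -sc.region.centroid_x,
        ),
    )


def estimate_shadow_onset(profile: ShadowProfilePair) -> int:
    """Absolute image row where the shadow begins.

    The onset is the first row after the steepest decrease of the
    center profile.  If the profile never decreases, the shadow is
    assumed to begin immediately below the candidate (``y_start``).
    """
    if profile.y_drop is None:
        logger.debug("profile has no drop; onset set to y_start")
        return profile.y_start
    d = profile.pc[profile.y_drop + 1] - profile.pc[profile.y_drop]
    if d >= 0:
        logger.debug("steepest difference is non-negative; onset set to y_start")
        return profile.y_start
    return profile.y_start + profile.y_drop + 1


def extract_shadow_roi(
    winner: CandidateRegion,
    onset_row: int,
    depth: int,
    image_height: int,
) -> RoiBox | None:
    """Posterior shadow box: winner's column span, from the onset row,
    up to ``depth`` rows, clipped to the image.  Returns None when no
    rows remain below the onset."""
    n_rows = min(depth, image_height - onset_row)
    if n_rows < 1:
        logger.debug("no rows remaining below onset %d; shadow ROI absent", onset_row)
        return None
    return RoiBox(onset_row, winner.bbox.col0, n_rows, winner.bbox.n_cols)


def detect(frame: UltrasoundFrame, roi: RoiBox, config: RunConfig) -> DetectionResult:
    """Run the full detection pipeline on one frame within ``roi``.

    The result reports coordinates in full-frame space (ROI offset
    added back).  Deterministic for fixed inputs and config.
    """
    sub = crop_roi(frame, roi)
    image = median_denoise(normalize_minmax(sub, config.scale_max), config.median_kernel)
    candidates = generate_candidates(image, config.candidate_params())
    survivors = screen(
        image,
        candidates,
        config.screen_params(),
        enable_lc=config.enable_lc,
        enable_sr=config.enable_sr,
    )
    scored = score_candidates(survivors, config.score_weights(), config.score_normalization)
    best = select_best(scored)
    if best is None:
        return DetectionResult(status="no_candidate")

    ranked = sorted(scored, key=lambda sc: -sc.total)
    alternates = tuple((sc.region.label, float(sc.total)) for sc in ranked)

    onset_roi: int | None = None
    shadow_box: RoiBox | None = None
    if best.screen_result.profile is not None:
        onset_roi = estimate_shadow_onset(best.screen_result.profile)
        shadow_box = extract_shadow_roi(
            best.region, onset_roi, config.depth, image.height
        )

    nb, nc, ns, np_ = best.normalized_features
    return DetectionResult(
        status="detected",
        winner=best.region.translated(roi.row0, roi.col0),
        total_score=float(best.total),
        component_scores={
            "brightness": float(best.region.brightness),
            "local_contrast": float(best.screen_result.local_contrast),
            "shadow_region": float(best.screen_result.shadow_region),
            "shape_penalty": float(best.region.shape_penalty),
            "brightness_norm": nb,
            "local_contrast_norm": nc,
            "shadow_region_norm": ns,
            "shape_penalty_norm": np_,
        },
        shadow_onset_row=None if onset_roi is None else onset_roi + roi.row0,
        shadow_roi=None if shadow_box is None else shadow_box.translated(roi.row0, roi.col0),
        ranked_alternates=alternates,
    )
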