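"""Quantitative evaluation of stone localization.

Experts annotate each stone by two endpoints of its visually
estimated long axis.  The endpoints define a reference line
a*x + b*y + c = 0; the localization error of a predicted stone
centroid O is its perpendicular distance to that line,

    d = |a*xo + b*yo + c| / sqrt(a^2 + b^2),

reported in pixels and in millimetres (pixel spacing, default
0.35 mm/px).  A prediction counts as *correct* when it falls inside a
capsule around the annotated segment: perpendicular distance at most
``radial_factor * |AB|`` and longitudinal projection within the
segment extended by ``axial_margin * |AB|`` beyond each end.  The
capsule is a declared surrogate for the expert-drawn "suspected stone
region": it uses only the two collected endpoints and scales with
stone size.

Group summaries report mean +/- sample SD with t-based 95% CIs, and
two-observer agreement is quantified with the intraclass correlation
coefficient ICC(2,1) (two-way random effects, absolute agreement,
single rater), interpreted as good at >= 0.75 and excellent at
>= 0.90.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .exceptions import ValidationError
from .frame_io import RoiBox, UltrasoundFrame
from .scoring import DetectionResult, detect

Point = tuple[float, float]


@dataclass(frozen=True)
class AxisAnnotation:
    """Expert-marked endpoints of the stone's long axis (frame coords)."""

    endpoint_a: Point
    endpoint_b: Point
    observer_id: str = ""

    def __post_init__(self) -> None:
        if self.axis_length == 0:
            raise ValidationError("annotation endpoints are coincident")

    @property
    def line(self) -> tuple[float, float, float]:
        return line_from_endpoints(self.endpoint_a, self.endpoint_b)

    @property
    def center(self) -> Point:
        (xa, ya), (xb, yb) = self.endpoint_a, self.endpoint_b
        return ((xa + xb) / 2.0, (ya + yb) / 2.0)

    @property
    def axis_length(self) -> float:
        (xa, ya), (xb, yb) = self.endpoint_a, self.endpoint_b
        return math.hypot(xb - xa, yb - ya)


@dataclass(frozen=True)
class GroupSummary:
    """Distance and accuracy summary for one confidence stratum."""

    group_label: str
    n: int
    mean_d: float
    sd_d: float
    ci95: tuple[float, float] | None
    accuracy: float
    n_correct: int
    n_total: int


@dataclass(frozen=True)
class IccResult:
    value: float
    band: str  # "poor_or_moderate" | "good" | "excellent"
    form: str = "ICC(2,1)"


def line_from_endpoints(a: Point, b: Point) -> tuple[float, float, float]:
    """General-form coefficients of the line through two points.

    a_coef = yb - ya, b_coef = xa - xb, c = -(a_coef*xa + b_coef*ya);
    both endpoints satisfy the equation exactly.
    """
    (xa, ya), (xb, yb) = a, b
    if xa == xb and ya == yb:
        raise ValidationError("endpoints are coincident; no unique line")
    a_coef = yb - ya
    b_coef = xa - xb
    c_coef = -(a_coef * xa + b_coef * ya)
    return a_coef, b_coef, c_coef


def centroid_distance(o: Point, line: tuple[float, float, float]) -> float:
    """Perpendicular distance from point ``o`` to ``a*x + b*y + c = 0``."""
    a, b, c = line
    norm = math.hypot(a, b)
    if norm == 0:
        raise ValidationError("degenerate line: a = b = 0")
    return abs(a * o[0] + b * o[1] + c) / norm


def px_to_mm(d_px: float, spacing: float = 0.35) -> float:
    """Convert a pixel distance to millimetres."""
    if not spacing > 0:
        raise ValidationError(f"pixel spacing must be > 0, got {spacing}")
    return d_px * spacing


def is_correct(
    pred: Point,
    annotation: AxisAnnotation,
    axial_margin: float = 0.25,
    radial_factor: float = 0.5,
) -> bool:
    """Capsule acceptance rule (boundary inclusive).

    The prediction is correct iff its orthogonal projection onto the
    annotated segment lies within the segment extended by
    ``axial_margin * |AB|`` beyond each end, and its perpendicular
    distance to the axis line is at most ``radial_factor * |AB|``.
    """
    (xa, ya), (xb, yb) = annotation.endpoint_a, annotation.endpoint_b
    ab = np.array([xb - xa, yb - ya])
    ap = np.array([pred[0] - xa, pred[1] - ya])
    length_sq = float(ab @ ab)
    t = float(ap @ ab) / length_sq
    if not (-axial_margin <= t <= 1.0 + axial_margin):
        return False
    d = centroid_distance(pred, annotation.line)
    return d <= radial_factor * annotation.axis_length


def accuracy(flags: list[bool]) -> float:
    """Fraction of correct detections, N_correct / N_total."""
    if not flags:
        raise ValidationError("accuracy of an empty list is undefined")
    return sum(bool(f) for f in flags) / len(flags)


def annotation_params(annotation: AxisAnnotation) -> tuple[Point, float]:
    """Representative parameters of an annotation: midpoint and |AB|."""
    return annotation.center, annotation.axis_length


def summarize_group(
    distances_mm: list[float], flags: list[bool], label: str = ""
) -> GroupSummary:
    """Mean +/- sample SD with a t-based 95% CI, plus capsule accuracy.

    The CI is mean +/- t_{0.975, n-1} * SD / sqrt(n); it is reported
    as absent for n = 1.
    """
    if len(distances_mm) == 0:
        raise ValidationError("cannot summarize an empty group")
    if len(distances_mm) != len(flags):
        raise ValidationError("distances and flags lengths differ")
    d = np.asarray(distances_mm, dtype=float)
    n = len(d)
    mean = float(d.mean())
    if n >= 2:
        sd = float(d.std(ddof=1))
        t_crit = float(stats.t.ppf(0.975, n - 1))
        half = t_crit * sd / math.sqrt(n)
        ci: tuple[float, float] | None = (mean - half, mean + half)
    else:
        sd = float("nan")
        ci = None
    return GroupSummary(
        group_label=label,
        n=n,
        mean_d=mean,
        sd_d=sd,
        ci95=ci,
        accuracy=accuracy(flags),
        n_correct=sum(bool(f) for f in flags),
        n_total=n,
    )


def icc_agreement(obs1: list[float], obs2: list[float]) -> IccResult:
    """Two-observer ICC(2,1): two-way random, absolute agreement, single rater."""
    if len(obs1) != len(obs2):
        raise ValidationError("observer series have different lengths")
    n = len(obs1)
    if n < 3:
        raise ValidationError("ICC requires at least 3 subjects")
    import pingouin as pg

    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["obs1", "obs2"], n),
            "rating": np.concatenate([np.asarray(obs1, float), np.asarray(obs2, float)]),
        }
    )
    table = pg.intraclass_corr(
        data=df, targets="subject", raters="rater", ratings="rating"
    )
    # label differs across pingouin versions: "ICC2" vs "ICC(A,1)"
    sel = table["Type"].isin(["ICC2", "ICC(A,1)"])
    value = float(table.loc[sel, "ICC"].iloc[0])
    if value >= 0.90:
        band = "excellent"
    elif value >= 0.75:
        band = "good"
    else:
        band = "poor_or_moderate"
    return IccResult(value=value, band=band)


# ---------------------------------------------------------------------------
# Ablation runner
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """One composite-score configuration for the ablation table.

    Dropping a feature zeroes its weight and disables its screen
    (the penalty has no screen).
    """

    name: str
    use_contrast: bool
    use_shadow: bool
    use_penalty: bool

    def apply(self, config: RunConfig) -> RunConfig:
        import dataclasses

        return dataclasses.replace(
            config,
            w_contrast=config.w_contrast if self.use_contrast else 0.0,
            w_shadow=config.w_shadow if self.use_shadow else 0.0,
            w_penalty=config.w_penalty if self.use_penalty else 0.0,
            enable_lc=self.use_contrast,
            enable_sr=self.use_shadow,
        )


DEFAULT_VARIANTS: tuple[Variant, ...] = (
    Variant("B", use_contrast=False, use_shadow=False, use_penalty=False),
    Variant("B+C", use_contrast=True, use_shadow=False, use_penalty=False),
    Variant("B+C+S", use_contrast=True, use_shadow=True, use_penalty=False),
    Variant("B+C+S+P", use_contrast=True, use_shadow=True, use_penalty=True),
)


@dataclass(frozen=True)
class DatasetItem:
    """One evaluation case: frame, ROI, expert axis, confidence stratum."""

    frame: UltrasoundFrame
    roi: RoiBox
    annotation: AxisAnnotation
    group_label: str
    image_id: str = ""


@dataclass(frozen=True)
class AblationResult:
    """Accuracy per (variant, group) and distance summaries for the
    full variant (computed over detected cases; ``n_detected`` of
    ``n`` cases contributed distances)."""

    accuracy_table: pd.DataFrame  # index: variant name; columns: group labels
    distance_summaries: dict[str, GroupSummary]
    n_detected: dict[str, int]


def evaluate_case(
    result: DetectionResult, item: DatasetItem, config: RunConfig
) -> tuple[bool, float | None]:
    """Correctness flag and distance (mm) for one detection result.

    A ``no_candidate`` result is incorrect and contributes no
    distance.
    """
    if not result.detected or result.winner is None:
        return False, None
    pred = (result.winner.centroid_x, result.winner.centroid_y)
    ok = is_correct(
        pred,
        item.annotation,
        axial_margin=config.axial_margin,
        radial_factor=config.radial_factor,
    )
    d_px = centroid_distance(pred, item.annotation.line)
    return ok, px_to_mm(d_px, item.frame.pixel_spacing_mm)


def ablation_run(
    dataset: list[DatasetItem],
    config: RunConfig,
    variants: tuple[Variant, ...] = DEFAULT_VARIANTS,
) -> AblationResult:
    """Run every score variant over the dataset, stratified by group.

    Accuracy is reported per (group, variant); centroid-distance
    summaries are reported per group for the *last* variant in the
    list (by default the full model).
    """
    if not dataset:
        raise ValidationError("ablation dataset is empty")
    if not variants:
        raise ValidationError("variant list is empty")
    groups = sorted({item.group_label for item in dataset})
    acc = pd.DataFrame(index=[v.name for v in variants], columns=groups, dtype=float)
    distance_summaries: dict[str, GroupSummary] = {}
    n_detected: dict[str, int] = {}
    for vi, variant in enumerate(variants):
        vcfg = variant.apply(config)
        flags: dict[str, list[bool]] = {g: [] for g in groups}
        dists: dict[str, list[float]] = {g: [] for g in groups}
        det_flags: dict[str, list[bool]] = {g: [] for g in groups}
        for item in dataset:
            result = detect(item.frame, item.roi, vcfg)
            ok, d_mm = evaluate_case(result, item, vcfg)
            flags[item.group_label].append(ok)
            if d_mm is not None:
                dists[item.group_label].append(d_mm)
                det_flags[item.group_label].append(ok)
        for g in groups:
            acc.loc[variant.name, g] = accuracy(flags[g])
        if vi == len(variants) - 1:
            for g in groups:
                n_detected[g] = len(dists[g])
                if dists[g]:
                    distance_summaries[g] = summarize_group(dists[g], det_flags[g], g)
    return AblationResult(
        accuracy_table=acc,
        distance_summaries=distance_summaries,
        n_detected=n_detected,
    )
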