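"""Synthetic B-mode phantoms with exact ground truth.

A phantom emulates the features the detector consumes rather than
full acoustic physics: a speckled background (Rayleigh envelope noise
smoothed by a small Gaussian, rescaled to a target mean), a
hyperechoic elliptical stone (multiplicative gain with a 1 px soft
edge), a graded hypoechoic column beneath it (the posterior shadow),
and optional shadow-free bright line confounders mimicking vessel
walls or fascial interfaces.

Shadow grades map to the three diagnostic-confidence strata:

======== ============ ======= ======== ===========
grade    attenuation  length  feather  group label
======== ============ ======= ======== ===========
weak     0.20         10 px   3 px     50to60
moderate 0.45         20 px   2 px     60to80
strong   0.70         40 px   1 px     ge80
======== ============ ======= ======== ===========

The weak grade additionally interrupts the column with two random
2-3 row gaps ("faint, discontinuous" shadowing).  All truth fields
(stone mask, centroid, axis endpoints, shadow mask) are derived
analytically from the spec parameters, never measured from the
rendered image.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .evaluation import AxisAnnotation, DatasetItem
from .exceptions import ValidationError
from .frame_io import RoiBox, UltrasoundFrame

GRADE_ATTENUATION = {"weak": 0.20, "moderate": 0.45, "strong": 0.70}
GRADE_LENGTH = {"weak": 10, "moderate": 20, "strong": 40}
GRADE_FEATHER = {"weak": 3, "moderate": 2, "strong": 1}
GRADE_LABEL = {"weak": "50to60", "moderate": "60to80", "strong": "ge80"}

#: Stone hyperechoic gain per grade used by the dataset generator:
#: weakly shadowing stones are typically smaller/less calcified and
#: echo somewhat more faintly, so difficulty co-varies with shadow
#: grade; the dominant grade driver remains the shadow itself.
GRADE_STONE_GAIN = {"weak": 2.4, "moderate": 2.8, "strong": 3.2}


@dataclass(frozen=True)
class Confounder:
    """A thin bright line segment with no posterior attenuation."""

    start: tuple[float, float]  # (x, y)
    end: tuple[float, float]
    gain: float = 3.0
    thickness: int = 2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic frame (raw intensity units).

    ``background_mean`` is the target mean of the speckled background;
    the stone multiplies the background by ``stone_gain`` inside the
    ellipse (semi-axes in pixels, orientation in radians from the
    lateral axis).  ``shadow_grade`` is one of weak/moderate/strong or
    None for a shadow-free frame.
    """

    height: int = 160
    width: int = 160
    background_mean: float = 300.0
    speckle_scale: float = 1.0
    smoothing_sigma: float = 1.2
    stone_center: tuple[float, float] = (80.0, 60.0)  # (x, y)
    stone_axes: tuple[float, float] = (6.0, 4.0)  # (semi-major, semi-minor)
    stone_orientation: float = 0.0
    stone_gain: float = 3.0
    shadow_grade: str | None = "strong"
    confounders: tuple[Confounder, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("phantom dimensions must be >= 1")
        if not self.stone_gain > 1:
            raise ValidationError("stone_gain must be > 1")
        if self.stone_axes[0] < self.stone_axes[1] or self.stone_axes[1] <= 0:
            raise ValidationError("stone_axes must satisfy semi-major >= semi-minor > 0")
        if self.shadow_grade is not None and self.shadow_grade not in GRADE_ATTENUATION:
            raise ValidationError(f"unknown shadow grade {self.shadow_grade!r}")


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom."""

    stone_mask: np.ndarray
    stone_centroid: tuple[float, float]  # (x, y)
    axis_endpoints: tuple[tuple[float, float], tuple[float, float]]
    shadow_mask: np.ndarray
    group_label: str | None
    seed: int


def speckle_background(spec: PhantomSpec) -> UltrasoundFrame:
    """Smoothed Rayleigh envelope noise rescaled to ``background_mean``.

    The rescale uses the theoretical Rayleigh mean
    ``scale * sqrt(pi/2)`` (Gaussian smoothing preserves the mean), so
    the empirical frame mean matches ``background_mean`` up to
    sampling noise.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    envelope = rng.rayleigh(spec.speckle_scale, size=(spec.height, spec.width))
    smooth = gaussian_filter(envelope, spec.smoothing_sigma, mode="nearest")
    rayleigh_mean = spec.speckle_scale * math.sqrt(math.pi / 2.0)
    pixels = smooth * (spec.background_mean / rayleigh_mean)
    return UltrasoundFrame(pixels, source_id=f"phantom-{spec.seed}")


def _ellipse_field(spec: PhantomSpec) -> np.ndarray:
    """Normalized elliptical radius d(y, x): d <= 1 inside the stone."""
    cx, cy = spec.stone_center
    a, b = spec.stone_axes
    theta = spec.stone_orientation
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    dx = xx - cx
    dy = yy - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def add_stone(frame: UltrasoundFrame, spec: PhantomSpec) -> tuple[UltrasoundFrame, PhantomTruth]:
    """Multiply the elliptical stone region by ``stone_gain`` (1 px soft edge).

    Truth (mask, centroid, major-axis endpoints) is recorded
    analytically from the ellipse parameters.
    """
    cx, cy = spec.stone_center
    a, b = spec.stone_axes
    theta = spec.stone_orientation
    wx = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    wy = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    if cx - wx < 0 or cx + wx > spec.width - 1 or cy - wy < 0 or cy + wy > spec.height - 1:
        raise ValidationError("stone ellipse extends outside the frame")
    d = _ellipse_field(spec)
    # soft edge: full gain inside, linear fade over ~1 px outside the boundary
    t = np.clip((d - 1.0) * spec.stone_axes[1], 0.0, 1.0)
    factor = 1.0 + (spec.stone_gain - 1.0) * (1.0 - t)
    pixels = frame.pixels * factor
    endpoints = (
        (cx - a * math.cos(theta), cy - a * math.sin(theta)),
        (cx + a * math.cos(theta), cy + a * math.sin(theta)),
    )
    truth = PhantomTruth(
        stone_mask=d <= 1.0,
        stone_centroid=(cx, cy),
        axis_endpoints=endpoints,
        shadow_mask=np.zeros_like(d, dtype=bool),
        group_label=None if spec.shadow_grade is None else GRADE_LABEL[spec.shadow_grade],
        seed=spec.seed,
    )
    return dataclasses.replace(frame, pixels=pixels), truth


def add_shadow(
    frame: UltrasoundFrame, spec: PhantomSpec, truth: PhantomTruth
) -> tuple[UltrasoundFrame, PhantomTruth]:
    """Attenuate a column of the stone's lateral extent beneath it.

    The column spans the grade's length, multiplied by
    ``1 - attenuation`` with the grade's lateral feathering; the weak
    grade is interrupted by two random 2-3 row gaps (zero attenuation,
    still part of the shadow mask).  A frame without a shadow grade is
    returned unchanged.
    """
    if spec.shadow_grade is None:
        return frame, truth
    att = GRADE_ATTENUATION[spec.shadow_grade]
    length = GRADE_LENGTH[spec.shadow_grade]
    feather = GRADE_FEATHER[spec.shadow_grade]

    cx, cy = spec.stone_center
    a, b = spec.stone_axes
    theta = spec.stone_orientation
    wx = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    wy = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    col0 = max(0, round(cx - wx))
    col1 = min(frame.width - 1, round(cx + wx))
    row0 = min(frame.height, int(math.ceil(cy + wy)) + 1)
    row1 = min(frame.height, row0 + length)
    if row0 >= row1 or col0 > col1:
        return frame, truth

    # per-column attenuation: full in the interior, linear ramp to 0
    # across `feather` columns at each lateral edge
    cols = np.arange(col0, col1 + 1)
    edge_dist = np.minimum(cols - col0, col1 - cols)
    ramp = np.clip((edge_dist + 1) / (feather + 1), 0.0, 1.0)
    att_cols = att * ramp

    # per-row multiplier, with gaps for the weak grade
    row_on = np.ones(row1 - row0)
    if spec.shadow_grade == "weak" and row1 - row0 >= 4:
        gap_rng = np.random.default_rng([spec.seed, 7919])
        starts = gap_rng.choice(row1 - row0 - 2, size=2, replace=False)
        for s in starts:
            row_on[s : s + int(gap_rng.integers(2, 4))] = 0.0

    pixels = frame.pixels.copy()
    factor = 1.0 - np.outer(row_on, att_cols)
    pixels[row0:row1, col0 : col1 + 1] *= factor

    shadow_mask = truth.shadow_mask.copy()
    interior = edge_dist >= feather  # columns at full attenuation
    shadow_mask[row0:row1, cols[interior]] = True
    truth = dataclasses.replace(truth, shadow_mask=shadow_mask)
    return dataclasses.replace(frame, pixels=pixels), truth


def add_confounders(frame: UltrasoundFrame, spec: PhantomSpec) -> UltrasoundFrame:
    """Draw each confounder as a thin bright segment (no shadow below)."""
    if not spec.confounders:
        return frame
    from skimage.draw import line as draw_line

    pixels = frame.pixels.copy()
    for conf in spec.confounders:
        (x0, y0), (x1, y1) = conf.start, conf.end
        rr, cc = draw_line(round(y0), round(x0), round(y1), round(x1))
        mask = np.zeros(pixels.shape, dtype=bool)
        keep = (rr >= 0) & (rr < frame.height) & (cc >= 0) & (cc < frame.width)
        mask[rr[keep], cc[keep]] = True
        for extra in range(1, conf.thickness):
            shifted = np.zeros_like(mask)
            shifted[extra:, :] = mask[:-extra, :] if extra else mask
            mask |= shifted
        pixels[mask] *= conf.gain
    return dataclasses.replace(frame, pixels=pixels)


def render_phantom(
    spec: PhantomSpec, quantize: bool = True
) -> tuple[UltrasoundFrame, PhantomTruth]:
    """Compose background + stone + shadow + confounders.

    With ``quantize`` the pixel values are rounded to the uint16 grid,
    so a frame written as 16-bit TIFF reads back pixel-exact.
    """
    frame = speckle_background(spec)
    frame, truth = add_stone(frame, spec)
    frame, truth = add_shadow(frame, spec, truth)
    frame = add_confounders(frame, spec)
    if quantize:
        pixels = np.clip(np.round(frame.pixels), 0, 65535)
        frame = dataclasses.replace(frame, pixels=pixels)
    return frame, truth


def _roi_for(spec: PhantomSpec) -> RoiBox:
    """Clinician-style ROI: stone plus its downstream shadow zone."""
    cx, cy = spec.stone_center
    row0 = max(0, int(cy) - 30)
    col0 = max(0, int(cx) - 55)
    col1 = min(spec.width, int(cx) + 55)
    return RoiBox(row0, col0, spec.height - row0, col1 - col0)


def sample_spec(
    grade: str | None,
    seed: int,
    with_confounder: bool = False,
    base_spec: PhantomSpec | None = None,
) -> PhantomSpec:
    """Draw one randomized phantom spec for a grade (None = stone-free).

    Stone position, size, orientation and gain vary around the grade's
    nominal values; the optional confounder is a bright horizontal
    line placed laterally beside the stone, brighter than the stone
    and without posterior attenuation.
    """
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng([seed, 11])
    if grade is None:
        return dataclasses.replace(base, shadow_grade=None, stone_gain=3.0, seed=seed)
    cx = float(rng.uniform(60.0, 100.0))
    cy = float(rng.uniform(45.0, 70.0))
    a = float(rng.uniform(5.0, 7.0))
    b = float(rng.uniform(3.5, min(5.0, a)))
    theta = float(rng.uniform(-0.35, 0.35))
    gain = GRADE_STONE_GAIN[grade] * float(rng.uniform(0.95, 1.1))
    confounders: tuple[Confounder, ...] = ()
    if with_confounder:
        side = -1.0 if cx > base.width / 2 else 1.0
        x_near = cx + side * 16.0
        x_far = cx + side * 41.0
        y_line = cy + float(rng.uniform(-12.0, 12.0))
        confounders = (
            Confounder(
                start=(min(x_near, x_far), y_line),
                end=(max(x_near, x_far), y_line),
                gain=gain * 1.15,
                thickness=3,
            ),
        )
    return dataclasses.replace(
        base,
        stone_center=(cx, cy),
        stone_axes=(a, b),
        stone_orientation=theta,
        stone_gain=gain,
        shadow_grade=grade,
        confounders=confounders,
        seed=seed,
    )


def make_samples(
    grade: str,
    n: int,
    seed: int,
    with_confounder: bool = False,
    base_spec: PhantomSpec | None = None,
) -> tuple[list[DatasetItem], list[PhantomTruth]]:
    """Generate ``n`` in-memory evaluation cases of one grade."""
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    items: list[DatasetItem] = []
    truths: list[PhantomTruth] = []
    for i, child in enumerate(child_seeds):
        spec = sample_spec(grade, int(child), with_confounder, base_spec)
        frame, truth = render_phantom(spec)
        annotation = AxisAnnotation(
            endpoint_a=truth.axis_endpoints[0],
            endpoint_b=truth.axis_endpoints[1],
            observer_id="truth",
        )
        items.append(
            DatasetItem(
                frame=frame,
                roi=_roi_for(spec),
                annotation=annotation,
                group_label=GRADE_LABEL[grade],
                image_id=f"{grade}_{i:04d}",
            )
        )
        truths.append(truth)
    return items, truths


def stone_free_frames(n: int, seed: int, base_spec: PhantomSpec | None = None) -> list[tuple[UltrasoundFrame, RoiBox]]:
    """Pure-speckle frames (no stone, no shadow) with a central ROI."""
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    out = []
    for child in child_seeds:
        spec = dataclasses.replace(base, seed=int(child))
        frame = speckle_background(spec)
        pixels = np.clip(np.round(frame.pixels), 0, 65535)
        frame = dataclasses.replace(frame, pixels=pixels)
        roi = RoiBox(20, 35, spec.height - 20, 90)
        out.append((frame, roi))
    return out


def generate_dataset(
    n_per_grade: dict[str, int],
    out_dir: str | Path,
    seed: int = 0,
    with_confounders: bool = False,
    base_spec: PhantomSpec | None = None,
) -> dict[str, Path]:
    """Write a reproducible phantom dataset to disk.

    Emits 16-bit TIFF frames under ``frames/``, a ``manifest.csv``
    (image id, path, ROI box, group label), an ``annotations.csv`` in
    the evaluation format (axis endpoints from truth), and a
    ``truth.json`` with the analytic ground truth.  Byte-identical
    across reruns with the same arguments.
    """
    import tifffile

    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    annotation_rows = []
    truth_records = {}
    for gi, grade in enumerate(["strong", "moderate", "weak"]):
        n = n_per_grade.get(grade, 0)
        if n < 0:
            raise ValidationError("phantom counts must be >= 0")
        items, truths = make_samples(grade, n, seed + gi, with_confounders, base_spec)
        for item, truth in zip(items, truths):
            fname = f"{item.image_id}.tif"
            path = frames_dir / fname
            tifffile.imwrite(path, item.frame.pixels.astype(np.uint16))
            manifest_rows.append(
                {
                    "image_id": item.image_id,
                    "path": f"frames/{fname}",
                    "row0": item.roi.row0,
                    "col0": item.roi.col0,
                    "n_rows": item.roi.n_rows,
                    "n_cols": item.roi.n_cols,
                    "group_label": item.group_label,
                }
            )
            (xa, ya), (xb, yb) = (
                item.annotation.endpoint_a,
                item.annotation.endpoint_b,
            )
            annotation_rows.append(
                {
                    "image_id": item.image_id,
                    "observer_id": "truth",
                    "xa": xa,
                    "ya": ya,
                    "xb": xb,
                    "yb": yb,
                    "group_label": item.group_label,
                }
            )
            truth_records[item.image_id] = {
                "stone_centroid": list(truth.stone_centroid),
                "axis_endpoints": [list(p) for p in truth.axis_endpoints],
                "group_label": truth.group_label,
                "seed": truth.seed,
            }

    manifest_path = out_dir / "manifest.csv"
    annotations_path = out_dir / "annotations.csv"
    truth_path = out_dir / "truth.json"
    manifest_cols = ["image_id", "path", "row0", "col0", "n_rows", "n_cols", "group_label"]
    annotation_cols = ["image_id", "observer_id", "xa", "ya", "xb", "yb", "group_label"]
    pd.DataFrame(manifest_rows, columns=manifest_cols).to_csv(manifest_path, index=False)
    pd.DataFrame(annotation_rows, columns=annotation_cols).to_csv(annotations_path, index=False)
    truth_path.write_text(json.dumps(truth_records, sort_keys=True, indent=1), encoding="utf-8")
    return {
        "manifest": manifest_path,
        "annotations": annotations_path,
        "truth": truth_path,
        "frames_dir": frames_dir,
    }
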