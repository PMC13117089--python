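"""Run configuration: one flat, serializable record of every tunable.

``RunConfig`` collects the parameters of all pipeline stages with the
reference defaults, round-trips losslessly through YAML, and rejects
unknown keys by name.  A stable content hash identifies the
configuration in every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .candidates import CandidateParams
from .exceptions import ValidationError
from .screening import ScreenParams


@dataclass(frozen=True)
class ScoreWeights:
    """Composite-score weights (brightness, contrast, shadow, penalty)."""

    w_brightness: float = 0.35
    w_contrast: float = 0.25
    w_shadow: float = 0.25
    w_penalty: float = 0.15

    def __post_init__(self) -> None:
        if min(self.w_brightness, self.w_contrast, self.w_shadow, self.w_penalty) < 0:
            raise ValidationError("score weights must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    # intensity scale / geometry
    scale_max: float = 1000.0
    pixel_spacing_mm: float = 0.35
    median_kernel: int = 3
    # candidate generation
    se_radius: int = 5
    percentile_q: float = 99.0
    min_area: int = 20
    top_k: int = 5
    alpha: float = 0.4
    beta: float = 0.3
    gamma: float = 0.3
    elong_tol: float = 2.0
    brightness_mode: str = "product"
    # screening
    ring_margin: int = 5
    tau_lc: float = 300.0
    band_halfwidth: int = 2
    depth: int = 30
    lateral_offset: int = 10
    rho: float = 0.5
    tau_sr: float = 100.0
    pce_mode: str = "segment"
    enable_lc: bool = True
    enable_sr: bool = True
    # composite score
    w_brightness: float = 0.35
    w_contrast: float = 0.25
    w_shadow: float = 0.25
    w_penalty: float = 0.15
    score_normalization: str = "minmax"  # "minmax" or "raw"
    # acceptance rule (capsule around the annotated axis)
    axial_margin: float = 0.25
    radial_factor: float = 0.5
    # randomness (phantom generation only; detection is deterministic)
    seed: int = 0

    def candidate_params(self) -> CandidateParams:
        return CandidateParams(
            se_radius=self.se_radius,
            percentile_q=self.percentile_q,
            min_area=self.min_area,
            top_k=self.top_k,
            alpha=self.alpha,
            beta=self.beta,
            gamma=self.gamma,
            elong_tol=self.elong_tol,
            brightness_mode=self.brightness_mode,
        )

    def screen_params(self) -> ScreenParams:
        return ScreenParams(
            ring_margin=self.ring_margin,
            tau_lc=self.tau_lc,
            band_halfwidth=self.band_halfwidth,
            depth=self.depth,
            lateral_offset=self.lateral_offset,
            rho=self.rho,
            tau_sr=self.tau_sr,
            pce_mode=self.pce_mode,
        )

    def score_weights(self) -> ScoreWeights:
        return ScoreWeights(
            w_brightness=self.w_brightness,
            w_contrast=self.w_contrast,
            w_shadow=self.w_shadow,
            w_penalty=self.w_penalty,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]
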