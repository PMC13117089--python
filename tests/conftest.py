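import numpy as np
import pytest

from sonoshadow import PhantomSpec, RunConfig, UltrasoundFrame, render_phantom
from sonoshadow.candidates import CandidateRegion
from sonoshadow.frame_io import RoiBox


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def strong_phantom():
    """A single strong-shadow phantom with its analytic truth."""
    spec = PhantomSpec(seed=7, shadow_grade="strong")
    frame, truth = render_phantom(spec)
    return spec, frame, truth


def make_region(
    coords: np.ndarray,
    image: np.ndarray | None = None,
    label: int = 1,
    **overrides,
) -> CandidateRegion:
    """Hand-build a CandidateRegion from pixel coordinates for unit tests."""
    coords = np.asarray(coords, dtype=np.int64)
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    mu = float(image[coords[:, 0], coords[:, 1]].mean()) if image is not None else 0.0
    fields = dict(
        label=label,
        coords=coords,
        area=len(coords),
        mean_intensity=mu,
        centroid_x=float(coords[:, 1].mean()),
        centroid_y=float(coords[:, 0].mean()),
        bbox=RoiBox(int(r0), int(c0), int(r1 - r0 + 1), int(c1 - c0 + 1)),
        eccentricity=0.0,
        solidity=1.0,
        axis_major=1.0,
        axis_minor=1.0,
    )
    fields.update(overrides)
    return CandidateRegion(**fields)
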