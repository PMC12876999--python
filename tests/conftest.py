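import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mindseye.io import Fixation, Scanpath, ScreenGeometry

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


def make_scanpath(positions, durations=None, geometry=None, gap_ms=30.0, **ids) -> Scanpath:
    """Build a scanpath from (x, y) positions with back-to-back onsets."""
    geometry = geometry or ScreenGeometry()
    positions = np.asarray(positions, dtype=float)
    if durations is None:
        durations = np.full(len(positions), 200.0)
    onset = 0.0
    fixations = []
    for (x, y), d in zip(positions, durations):
        fixations.append(Fixation(onset_ms=onset, duration_ms=float(d), x_px=float(x), y_px=float(y)))
        onset += d + gap_ms
    defaults = dict(participant_id="p00", trial_id="t00", phase="encoding",
                    condition="FP", category="abstract")
    defaults.update(ids)
    return Scanpath(fixations=fixations, geometry=geometry, **defaults)


def random_scanpath(rng: np.random.Generator, n: int, geometry=None,
                    scale: float = 400.0, **ids) -> Scanpath:
    """Random on-screen scanpath used by the oracle-equivalence tests."""
    geometry = geometry or ScreenGeometry()
    # cluster around a few centres so recurrences actually occur
    centres = rng.uniform([100, 100], [geometry.width_px - 100, geometry.height_px - 100],
                          size=(max(2, n // 4), 2))
    idx = rng.integers(0, len(centres), size=n)
    pos = centres[idx] + rng.normal(0, scale / 4, size=(n, 2))
    pos = np.clip(pos, [0, 0], [geometry.width_px - 1, geometry.height_px - 1])
    durations = rng.uniform(120, 600, size=n)
    return make_scanpath(pos, durations, geometry, **ids)
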