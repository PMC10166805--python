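import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from roiconsensus import DetectorConfig, ROISet, generate_ground_truth, simulate_detector_pair


@pytest.fixture
def small_field() -> tuple[int, int]:
    return 256, 256


@pytest.fixture
def ground_truth_50(small_field):
    w, h = small_field
    return generate_ground_truth(50, w, h, min_separation=15, seed=123)


@pytest.fixture
def detector_pair(ground_truth_50):
    cfg_a = DetectorConfig(detection_prob=0.8, jitter_sigma=2.0, n_false_positives=10, seed=1)
    cfg_b = DetectorConfig(detection_prob=0.8, jitter_sigma=2.0, n_false_positives=10, seed=2)
    return simulate_detector_pair(ground_truth_50, cfg_a, cfg_b)


def random_roiset(rng: np.random.Generator, n: int, w: int = 100, h: int = 100) -> ROISet:
    coords = rng.uniform((0, 0), (w, h), size=(n, 2))
    return ROISet.from_arrays(range(n), coords[:, 0], coords[:, 1], w, h)
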