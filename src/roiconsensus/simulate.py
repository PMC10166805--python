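"""Synthetic detector simulator.

Stands in for a pair of cell-segmentation algorithms run on the same field
of view. A ground-truth cell field is drawn uniformly with a minimum
pairwise separation (cells do not overlap); each simulated detector then

* reports each true cell independently with probability ``detection_prob``
  (false negatives),
* perturbs each reported location by iid Gaussian noise of per-axis standard
  deviation ``jitter_sigma`` pixels, clipped to the field of view,
* adds ``n_false_positives`` spurious ROIs placed uniformly at distance
  greater than ``fp_min_distance`` from every true cell, so that a false
  positive can never be spatially matched to ground truth at the default
  15-px threshold.

Two detectors with different seeds have independent detection draws and
independent false-positive placements — the regime in which consensus
filtering removes false positives, because a spurious ROI is unlikely to
appear at the same location in both outputs.

All randomness flows from one integer seed per configuration through
``numpy.random.default_rng`` (PCG64), so every scene is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .roi import InvalidInputError, ROISet


class PlacementError(RuntimeError):
    """Raised when the requested geometry cannot be placed in the field."""


@dataclass(frozen=True)
class DetectorConfig:
    """Error model of one simulated cell-detection algorithm."""

    detection_prob: float = 0.8
    jitter_sigma: float = 2.0
    n_false_positives: int = 50
    seed: int = 0
    fp_min_distance: float = 15.0  # set 0 for the hard-FP-near-cells mode

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise InvalidInputError(f"detection_prob must be in [0, 1], got {self.detection_prob}")
        if self.jitter_sigma < 0:
            raise InvalidInputError(f"jitter_sigma must be >= 0, got {self.jitter_sigma}")
        if self.n_false_positives < 0:
            raise InvalidInputError(f"n_false_positives must be >= 0, got {self.n_false_positives}")
        if self.fp_min_distance < 0:
            raise InvalidInputError(f"fp_min_distance must be >= 0, got {self.fp_min_distance}")


@dataclass
class SimulatedScene:
    """A ground-truth field plus the outputs of the simulated detectors."""

    ground_truth: ROISet
    detector_outputs: list[ROISet] = field(default_factory=list)
    configs: list[DetectorConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        gt = self.ground_truth
        for out in self.detector_outputs:
            if (out.field_width, out.field_height) != (gt.field_width, gt.field_height):
                raise InvalidInputError("detector output field dims differ from ground truth")


def generate_ground_truth(
    n_cells: int,
    field_width: int,
    field_height: int,
    min_separation: float = 15.0,
    seed: int = 0,
    max_attempts_per_cell: int = 10_000,
) -> ROISet:
    """Place ``n_cells`` centroids uniformly with pairwise separation >= ``min_separation``.

    Rejection sampling with a bounded retry budget; an infeasible packing
    (too many cells for the field at the requested separation) raises
    :class:`PlacementError` rather than looping forever.
    """
    if n_cells < 1:
        raise InvalidInputError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(seed)
    placed = np.empty((0, 2))
    attempts = 0
    budget = max_attempts_per_cell * n_cells
    while len(placed) < n_cells:
        if attempts >= budget:
            raise PlacementError(
                f"could not place {n_cells} cells at separation {min_separation} "
                f"in {field_width}x{field_height} after {budget} attempts"
            )
        attempts += 1
        p = rng.uniform((0, 0), (field_width, field_height))
        if len(placed) == 0 or np.min(np.hypot(*(placed - p).T)) >= min_separation:
            placed = np.vstack([placed, p])
    return ROISet.from_arrays(
        range(n_cells), placed[:, 0], placed[:, 1], field_width, field_height, "ground_truth"
    )


def _place_false_positives(
    rng: np.random.Generator,
    n_fp: int,
    truth: np.ndarray,
    field_width: int,
    field_height: int,
    min_distance: float,
    max_attempts: int = 200_000,
) -> np.ndarray:
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_fp:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n_fp} false positives at distance > {min_distance} "
                f"from {len(truth)} true cells"
            )
        attempts += 1
        p = rng.uniform((0, 0), (field_width, field_height))
        if len(truth) == 0 or np.min(np.hypot(*(truth - p).T)) > min_distance:
            placed.append(p)
    return np.array(placed) if placed else np.empty((0, 2))


def simulate_detector(ground_truth: ROISet, cfg: DetectorConfig) -> ROISet:
    """Apply one detector's error model to a ground-truth field.

    Output ids are sequential (the detector has no knowledge of true cell
    identities); detected true cells precede false positives in the set.
    """
    rng = np.random.default_rng(cfg.seed)
    w, h = ground_truth.field_width, ground_truth.field_height
    truth = ground_truth.coords

    hit = rng.random(len(truth)) < cfg.detection_prob
    detected = truth[hit]
    if cfg.jitter_sigma > 0 and len(detected):
        detected = detected + rng.normal(0.0, cfg.jitter_sigma, size=detected.shape)
    # physical field of view: clip, do not wrap (bounds are exclusive)
    upper = (np.nextafter(w, 0), np.nextafter(h, 0))
    detected = np.clip(detected, 0.0, upper) if len(detected) else detected

    fps = _place_false_positives(rng, cfg.n_false_positives, truth, w, h, cfg.fp_min_distance)
    coords = np.vstack([detected, fps]) if len(detected) or len(fps) else np.empty((0, 2))
    return ROISet.from_arrays(
        range(len(coords)), coords[:, 0], coords[:, 1], w, h, f"detector_seed{cfg.seed}"
    )


def simulate_detector_pair(
    ground_truth: ROISet, cfg_a: DetectorConfig, cfg_b: DetectorConfig
) -> tuple[ROISet, ROISet]:
    """Run two independent simulated detectors on the same ground truth.

    Seeds must differ: identical seeds would produce perfectly correlated
    errors, defeating the premise that the two algorithms' errors are
    independent.
    """
    if cfg_a.seed == cfg_b.seed:
        raise InvalidInputError("detector configs must use different seeds")
    return simulate_detector(ground_truth, cfg_a), simulate_detector(ground_truth, cfg_b)


def simulate_scene(
    n_cells: int,
    field_width: int,
    field_height: int,
    configs: list[DetectorConfig],
    min_separation: float = 15.0,
    seed: int = 0,
) -> SimulatedScene:
    """Convenience wrapper: ground truth plus any number of detector outputs."""
    gt = generate_ground_truth(n_cells, field_width, field_height, min_separation, seed)
    outputs = [simulate_detector(gt, cfg) for cfg in configs]
    return SimulatedScene(gt, outputs, list(configs))
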