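"""Evaluation statistics for cell detection and parameter-sweep maps.

Against a reference (usually anatomically labelled ground truth), a detector
output is scored by spatially matching the two sets within a distance
threshold and reporting

* TPR        = 100 * n_matched / n_reference   (sensitivity),
* precision  = 100 * n_matched / n_detected    (overlap with the reference),

both on the 0-100 percent scale. Two further agreement measures compare two
detector outputs directly: the count ratio |A|/|B| (1.0 means equal counts)
and the matched percentage 100 * n_matched / min(|A|, |B|).

Parameter sweeps collect one scalar metric per parameter combination into a
dense 2-D grid for heat-map display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matching import match_rois
from .roi import InvalidInputError, ROISet


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator would be zero."""


@dataclass(frozen=True)
class EvalReport:
    """Detection statistics of one ROISet against a reference set."""

    n_detected: int
    n_reference: int
    n_matched: int
    tpr_percent: float
    precision_percent: float
    threshold: float

    def __post_init__(self) -> None:
        assert 0 <= self.tpr_percent <= 100
        assert 0 <= self.precision_percent <= 100
        assert self.n_matched <= min(self.n_detected, self.n_reference)


def evaluate_detection(detected: ROISet, reference: ROISet, threshold: float) -> EvalReport:
    """Match ``detected`` against ``reference`` and report TPR and precision."""
    if len(reference) == 0:
        raise UndefinedMetricError("TPR undefined for empty reference set")
    if len(detected) == 0:
        raise UndefinedMetricError("precision undefined for empty detected set")
    m = match_rois(detected, reference, threshold)
    n = m.n_matched
    return EvalReport(
        n_detected=len(detected),
        n_reference=len(reference),
        n_matched=n,
        tpr_percent=100.0 * n / len(reference),
        precision_percent=100.0 * n / len(detected),
        threshold=float(threshold),
    )


def true_positive_rate(detected: ROISet, ground_truth: ROISet, threshold: float) -> float:
    """Percentage of ground-truth cells matched by the detector output."""
    if len(ground_truth) == 0:
        raise UndefinedMetricError("TPR undefined for empty ground truth")
    m = match_rois(detected, ground_truth, threshold)
    return 100.0 * m.n_matched / len(ground_truth)


def precision_vs_reference(detected: ROISet, reference: ROISet, threshold: float) -> float:
    """Percentage of detected cells that spatially match the reference set.

    The same formula scores a single detector's overlap with ground truth
    and the consensus set's overlap with ground truth.
    """
    if len(detected) == 0:
        raise UndefinedMetricError("precision undefined for empty detected set")
    m = match_rois(detected, reference, threshold)
    return 100.0 * m.n_matched / len(detected)


def count_ratio(set_a: ROISet, set_b: ROISet) -> float:
    """|A| / |B|; a value of 1.0 flags equal detected-cell counts."""
    if len(set_b) == 0:
        raise UndefinedMetricError("count ratio undefined for empty denominator set")
    return len(set_a) / len(set_b)


def matched_percentage(set_a: ROISet, set_b: ROISet, threshold: float) -> float:
    """Percentage of cells spatially matched between two detector outputs.

    Denominator is min(|A|, |B|), giving a 0-100 bounded agreement measure.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise UndefinedMetricError("matched percentage undefined for empty set")
    m = match_rois(set_a, set_b, threshold)
    return 100.0 * m.n_matched / min(len(set_a), len(set_b))


@dataclass(frozen=True)
class PatchParams:
    """Patch-based segmentation parameters derived from expected cell size.

    gSig is the expected half-size of cells in pixels (approximate neuronal
    radius); the patch half-size rf and patch overlap stride follow as
    rf = 4*gSig and stride = 2*gSig. The per-patch expected component count
    K divides the field-wide estimate K_total over the patch tiling.
    """

    gSig: int
    rf: int
    stride: int
    K: int
    K_total: int
    npatches: int

    def __post_init__(self) -> None:
        assert self.rf == 4 * self.gSig
        assert self.stride == 2 * self.gSig
        assert self.K >= 1
        assert self.npatches >= 1


def derive_patch_params(
    gSig: int, K_total: int, field_width: int, field_height: int
) -> PatchParams:
    """Derive patch half-size, stride, and per-patch K from gSig and K_total.

    The patch tiling is approximated as ceil(extent / pitch) per axis with
    pitch = 2*rf - stride (patch diameter minus overlap); the per-patch
    component count K = round(K_total / npatches) floors at 1 because a
    patch always expects at least one component.
    """
    if gSig < 1:
        raise InvalidInputError(f"gSig must be >= 1, got {gSig}")
    if K_total < 1:
        raise InvalidInputError(f"K_total must be >= 1, got {K_total}")
    if field_width <= 0 or field_height <= 0:
        raise InvalidInputError("field dimensions must be positive")
    rf = 4 * gSig
    stride = 2 * gSig
    pitch = 2 * rf - stride
    npatches = math.ceil(field_width / pitch) * math.ceil(field_height / pitch)
    K = max(1, round(K_total / npatches))
    return PatchParams(gSig=gSig, rf=rf, stride=stride, K=K, K_total=K_total, npatches=npatches)


@dataclass
class SweepGrid:
    """A scalar metric evaluated over the Cartesian product of two parameter axes."""

    axis_a_name: str
    axis_a_values: list
    axis_b_name: str
    axis_b_values: list
    values: np.ndarray  # shape (|axis_a|, |axis_b|), rows = axis_a
    metric_name: str

    def __post_init__(self) -> None:
        expected = (len(self.axis_a_values), len(self.axis_b_values))
        if self.values.shape != expected:
            raise InvalidInputError(
                f"grid shape {self.values.shape} != |axis_a| x |axis_b| {expected}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        """Dense table indexed by axis_a values, columns axis_b values."""
        return pd.DataFrame(
            self.values, index=self.axis_a_values, columns=self.axis_b_values
        ).rename_axis(index=self.axis_a_name, columns=self.axis_b_name)


def build_sweep_grid(
    records: list[tuple],
    axis_a: tuple[str, list],
    axis_b: tuple[str, list],
    metric_name: str = "metric",
) -> SweepGrid:
    """Assemble (value_a, value_b, metric) records into a dense 2-D grid.

    Exactly one record per parameter combination is required; duplicate or
    missing combinations raise with the offending combinations listed.
    """
    name_a, values_a = axis_a
    name_b, values_b = axis_b
    index_a = {v: i for i, v in enumerate(values_a)}
    index_b = {v: i for i, v in enumerate(values_b)}
    grid = np.full((len(values_a), len(values_b)), np.nan)
    seen: set[tuple] = set()
    dupes: list[tuple] = []
    for va, vb, metric in records:
        if va not in index_a or vb not in index_b:
            raise InvalidInputError(f"record ({va}, {vb}) not on the declared axes")
        key = (va, vb)
        if key in seen:
            dupes.append(key)
            continue
        seen.add(key)
        grid[index_a[va], index_b[vb]] = metric
    missing = [(va, vb) for va in values_a for vb in values_b if (va, vb) not in seen]
    if dupes or missing:
        parts = []
        if dupes:
            parts.append(f"duplicate combinations: {dupes}")
        if missing:
            parts.append(f"missing combinations: {missing}")
        raise InvalidInputError("; ".join(parts))
    return SweepGrid(name_a, list(values_a), name_b, list(values_b), grid, metric_name)
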