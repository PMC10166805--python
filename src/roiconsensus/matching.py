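"""Consensus matching of two ROI sets.

Two cell-detection algorithms run on the same field of view produce two sets
of candidate cell centroids. Cells found by both — location-matched within a
pixel distance threshold — form the consensus set; the consensus coordinate
of a matched pair is the average of the two locations. The default threshold
of 15 px corresponds to roughly one cell diameter in typical two-photon data.

Matching is greedy nearest-first: all cross pairs within the threshold
(inclusive) are sorted ascending by (distance, id_a, id_b) and accepted when
both endpoints are still free. This is deterministic and maximal — after
matching, no unmatched cross pair lies within the threshold — but it is not
an optimal (Hungarian) assignment, which is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .roi import InvalidInputError, Point, ROI, ROISet

DEFAULT_THRESHOLD = 15.0  # pixels, roughly one cell diameter


@dataclass
class MatchResult:
    """One-to-one pairing of two ROISets under a distance threshold."""

    pairs: list[tuple[int, int, float]]  # (id_a, id_b, distance)
    unmatched_a: list[int]
    unmatched_b: list[int]
    threshold: float
    consensus: ROISet = field(default=None)  # type: ignore[assignment]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_rois(set_a: ROISet, set_b: ROISet, threshold: float = DEFAULT_THRESHOLD) -> MatchResult:
    """Greedily match ROIs of ``set_a`` to ROIs of ``set_b`` within ``threshold``.

    Parameters
    ----------
    set_a, set_b : ROISet
        The two detector outputs; must share field dimensions.
    threshold : float
        Maximum acceptable centroid separation in pixels (inclusive).

    Returns
    -------
    MatchResult
        One-to-one pairs sorted in acceptance (ascending distance) order,
        ids of unmatched ROIs on both sides, and the merged consensus
        ROISet (one ROI per pair at the midpoint of the matched centroids).
    """
    if threshold <= 0:
        raise InvalidInputError(f"threshold must be positive, got {threshold}")
    if (set_a.field_width, set_a.field_height) != (set_b.field_width, set_b.field_height):
        raise InvalidInputError(
            f"field dimensions differ: {set_a.field_width}x{set_a.field_height} "
            f"vs {set_b.field_width}x{set_b.field_height}"
        )

    ids_a, ids_b = set_a.ids, set_b.ids
    if len(set_a) and len(set_b):
        d = cdist(set_a.coords, set_b.coords)
        ia, ib = np.nonzero(d <= threshold)
        candidates = sorted(
            zip(d[ia, ib].tolist(), ids_a[ia].tolist(), ids_b[ib].tolist())
        )
    else:
        candidates = []

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for dist_ab, id_a, id_b in candidates:
        if id_a in used_a or id_b in used_b:
            continue
        used_a.add(id_a)
        used_b.add(id_b)
        pairs.append((id_a, id_b, dist_ab))

    result = MatchResult(
        pairs=pairs,
        unmatched_a=[i for i in ids_a.tolist() if i not in used_a],
        unmatched_b=[i for i in ids_b.tolist() if i not in used_b],
        threshold=float(threshold),
    )
    result.consensus = consensus_roiset(result, set_a, set_b)
    return result


def consensus_roiset(match: MatchResult, set_a: ROISet, set_b: ROISet) -> ROISet:
    """Merge matched pairs into consensus coordinates.

    Each pair contributes one ROI at the coordinate-wise midpoint of the two
    matched centroids. Ids are sequential in pair order; the source label is
    ``"consensus"``.
    """
    by_id_a = {r.id: r for r in set_a}
    by_id_b = {r.id: r for r in set_b}
    rois = []
    for k, (id_a, id_b, _) in enumerate(match.pairs):
        if id_a not in by_id_a or id_b not in by_id_b:
            raise InvalidInputError(f"dangling pair ids ({id_a}, {id_b})")
        pa, pb = by_id_a[id_a].centroid, by_id_b[id_b].centroid
        rois.append(ROI(k, Point((pa.x + pb.x) / 2.0, (pa.y + pb.y) / 2.0)))
    return ROISet(rois, set_a.field_width, set_a.field_height, source="consensus")
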