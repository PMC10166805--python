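"""Core ROI types: centroids on a field of view, distances, and coordinate I/O.

A detected cell (ROI) is represented by its centroid in pixel coordinates,
using the image convention x = column, y = row, 0-based, with sub-pixel float
precision. A field of view of width W and height H admits centroids in the
half-open box [0, W) x [0, H).

Coordinate tables are CSV files with header ``id,x,y`` (comma separator,
'.' decimal point); masks may be integer label images (TIFF) or HDF5 files
with per-ROI pixel lists under ``/rois/<id>/pixels``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class InvalidInputError(ValueError):
    """Raised when an operation receives input violating its contract."""


@dataclass(frozen=True)
class Point:
    """A sub-pixel location on the imaging field (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError(f"non-finite point coordinates: ({self.x}, {self.y})")


@dataclass(frozen=True)
class ROI:
    """One detected cell: a stable id, a centroid, and optional member pixels.

    When ``pixels`` is given, the centroid must be the coordinate-wise mean
    of the pixel list (checked to 1e-9); this mirrors how ground-truth cell
    locations are derived from anatomically labelled masks.
    """

    id: int
    centroid: Point
    pixels: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.id < 0:
            raise InvalidInputError(f"ROI id must be non-negative, got {self.id}")
        if self.pixels is not None:
            c = centroid(self.pixels)
            if abs(c.x - self.centroid.x) > 1e-9 or abs(c.y - self.centroid.y) > 1e-9:
                raise InvalidInputError(
                    f"ROI {self.id}: centroid {self.centroid} does not equal "
                    f"pixel mean {c}"
                )


@dataclass
class ROISet:
    """An ordered collection of ROIs on one field of view.

    Parameters
    ----------
    rois : list of ROI
        Detected cells; ids must be unique and centroids inside the field.
    field_width, field_height : int
        Field-of-view dimensions in pixels (bounds are exclusive).
    source : str
        Free-text label of where the set came from (detector name, "ground_truth",
        "consensus", ...).
    """

    rois: list[ROI] = field(default_factory=list)
    field_width: int = 512
    field_height: int = 512
    source: str = ""

    def __post_init__(self) -> None:
        if self.field_width <= 0 or self.field_height <= 0:
            raise InvalidInputError(
                f"field dimensions must be positive, got "
                f"{self.field_width}x{self.field_height}"
            )
        ids = [r.id for r in self.rois]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate ROI ids: {dupes}")
        bad = [
            r.id
            for r in self.rois
            if not (0 <= r.centroid.x < self.field_width and 0 <= r.centroid.y < self.field_height)
        ]
        if bad:
            raise InvalidInputError(
                f"centroids outside field [0,{self.field_width})x[0,{self.field_height}) "
                f"for ids: {bad}"
            )

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def ids(self) -> np.ndarray:
        return np.array([r.id for r in self.rois], dtype=np.int64)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) float array of centroids, columns (x, y)."""
        if not self.rois:
            return np.empty((0, 2), dtype=np.float64)
        return np.array([[r.centroid.x, r.centroid.y] for r in self.rois], dtype=np.float64)

    def get(self, roi_id: int) -> ROI:
        for r in self.rois:
            if r.id == roi_id:
                return r
        raise KeyError(f"no ROI with id {roi_id}")

    @classmethod
    def from_arrays(
        cls,
        ids: Iterable[int],
        xs: Iterable[float],
        ys: Iterable[float],
        field_width: int,
        field_height: int,
        source: str = "",
    ) -> "ROISet":
        rois = [Point(float(x), float(y)) for x, y in zip(xs, ys)]
        return cls(
            rois=[ROI(int(i), p) for i, p in zip(ids, rois)],
            field_width=field_width,
            field_height=field_height,
            source=source,
        )


def centroid(pixels: Sequence[tuple[int, int]]) -> Point:
    """Coordinate-wise arithmetic mean of a pixel list.

    This is the rule used to reduce an anatomical ROI mask to a single cell
    location: the average of the ROI pixel locations.
    """
    if len(pixels) == 0:
        raise InvalidInputError("centroid of empty pixel list is undefined")
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError(f"pixels must be (x, y) pairs, got shape {arr.shape}")
    mx, my = arr.mean(axis=0)
    return Point(float(mx), float(my))


def distance(p: Point, q: Point) -> float:
    """Euclidean distance between two points, in pixels."""
    return math.hypot(p.x - q.x, p.y - q.y)


def _load_csv(path: Path, field_width: int, field_height: int, source: str) -> ROISet:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    ids = df["id"].to_numpy()
    if len(ids) != len(np.unique(ids)):
        uniq, counts = np.unique(ids, return_counts=True)
        raise InvalidInputError(f"{path}: duplicate ids {uniq[counts > 1].tolist()}")
    xs, ys = df["x"].to_numpy(float), df["y"].to_numpy(float)
    bad = ids[(xs < 0) | (xs >= field_width) | (ys < 0) | (ys >= field_height)]
    if bad.size:
        raise InvalidInputError(
            f"{path}: coordinates outside [0,{field_width})x[0,{field_height}) "
            f"for ids {bad.tolist()}"
        )
    return ROISet.from_arrays(ids, xs, ys, field_width, field_height, source)


def _load_label_image(path: Path, field_width: int, field_height: int, source: str) -> ROISet:
    import tifffile

    labels = np.asarray(tifffile.imread(path))
    if labels.ndim != 2:
        raise InvalidInputError(f"{path}: label image must be 2-D, got shape {labels.shape}")
    rois = []
    for lab in np.unique(labels):
        if lab == 0:  # background
            continue
        rr, cc = np.nonzero(labels == lab)
        pixels = tuple((int(c), int(r)) for r, c in zip(rr, cc))  # x = column
        rois.append(ROI(int(lab), centroid(pixels), pixels))
    return ROISet(rois, field_width, field_height, source)


def _load_hdf5_masks(path: Path, field_width: int, field_height: int, source: str) -> ROISet:
    import h5py

    rois = []
    with h5py.File(path, "r") as f:
        if "rois" not in f:
            raise InvalidInputError(f"{path}: no /rois group")
        for key in sorted(f["rois"], key=lambda k: int(k)):
            pix = np.asarray(f["rois"][key]["pixels"])
            pixels = tuple((int(x), int(y)) for x, y in pix)
            rois.append(ROI(int(key), centroid(pixels), pixels))
    return ROISet(rois, field_width, field_height, source)


def load_roiset(
    path: str | Path,
    field_width: int,
    field_height: int,
    source: str = "",
) -> ROISet:
    """Load an ROISet from a coordinate table (CSV) or a mask container.

    Dialect is chosen by file suffix: ``.csv`` = coordinate table with header
    ``id,x,y``; ``.tif``/``.tiff`` = integer label image (0 = background);
    ``.h5``/``.hdf5`` = per-ROI pixel lists under ``/rois/<id>/pixels``.
    Mask dialects compute centroids with :func:`centroid`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _load_csv(path, field_width, field_height, source)
    if suffix in (".tif", ".tiff"):
        return _load_label_image(path, field_width, field_height, source)
    if suffix in (".h5", ".hdf5"):
        return _load_hdf5_masks(path, field_width, field_height, source)
    raise InvalidInputError(f"unrecognised ROI container suffix: {path.suffix}")


def save_roiset(roiset: ROISet, path: str | Path) -> None:
    """Write a coordinate table (CSV, header ``id,x,y``).

    Floats are written with ``repr`` (shortest round-trip form), so
    load -> save -> load reproduces coordinates bit-exactly.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("id,x,y\n")
        for r in roiset:
            fh.write(f"{r.id},{r.centroid.x!r},{r.centroid.y!r}\n")
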