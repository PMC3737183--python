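"""Noise-tolerance maxima detection and trichome spacing cells.

The detector reimplements the "find maxima with noise tolerance" operation
familiar from ImageJ's Process > Find Maxima: a local-maximum plateau of
value v is kept only if it is *prominent* — every 8-connected path from the
plateau to any strictly higher pixel must descend to at least ``v - tol``.
Equal-valued plateaus that can reach each other without descending below
that floor count as a single spot.  Trichome bases are slightly darker than
the wing blade, so detection runs on the photometric inverse of the image
(``invert_first=True``, the default).

Exact semantics (all deterministic):

* A *candidate* is a maximal 8-connected set of equal-valued pixels none of
  which has a strictly greater 8-neighbor.
* A candidate of value v is accepted iff every 8-connected path from it to a
  pixel of value > v contains a pixel with value <= v - tol.
* Among equal-valued candidates mutually reachable through pixels of value
  > v - tol, only one point is emitted (smallest rounded centroid, row-major).
* A global-maximum plateau touching the image border is suppressed — a flat
  field contains no identifiable spot (so a constant image yields no points).
* Each accepted plateau emits its pixel centroid rounded to the nearest
  pixel, halves rounding toward the smaller row/col; points are returned
  sorted by (row, col).

The spacing-cell partition ("segmented particles") floods the inverted image
from the accepted maxima: one watershed cell per trichome, boundary pixels
labeled 0, cell area inversely proportional to local trichome density.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._flood import ACCEPTED, PENDING, resolve_maxima, watershed_flood
from .errors import EmptyResultError, InputError
from .image import Micrograph

__all__ = [
    "TrichomePoints",
    "SpacingCells",
    "find_maxima",
    "count_maxima",
    "trichome_spacing_cells",
    "save_points",
    "load_points",
]

DEFAULT_NOISE_TOLERANCE = 10.0

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class TrichomePoints:
    """Detected trichome base coordinates plus the tolerance that produced them.

    ``points`` is an (N, 2) int array of (row, col) pairs, sorted
    lexicographically, with no duplicates.
    """

    points: np.ndarray
    noise_tolerance: float
    source_dims: tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)
        self.points = pts

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass
class SpacingCells:
    """Watershed partition with one cell per detected trichome.

    ``label_map`` has one positive integer label per cell and 0 on boundary
    lines; ``cell_areas[k]`` is the pixel area of cell ``k`` (index 0 unused).
    """

    label_map: np.ndarray
    cell_areas: np.ndarray
    seeds: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.cell_areas.shape[0]) - 1

    def areas(self) -> dict[int, int]:
        return {k: int(self.cell_areas[k]) for k in range(1, self.cell_areas.shape[0])}


def _round_half_down(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, exact halves toward the smaller value."""
    return np.ceil(x - 0.5).astype(np.int64)


def _candidate_plateaus(arr: np.ndarray):
    """Label local-maximum plateaus; return per-plateau geometry.

    Returns (labels-1 map flat int64, value, centroid_r, centroid_c exact,
    rounded centroids, border flag) arrays indexed by candidate id.
    """
    a = arr.astype(np.int16)
    padded = np.pad(a, 1, mode="constant", constant_values=-1)
    has_greater = np.zeros(a.shape, dtype=bool)
    h, w = a.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            has_greater |= padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w] > a
    summit = ~has_greater
    labels, n = ndimage.label(summit, structure=_EIGHT)
    if n == 0:
        empty = np.zeros(0)
        return (
            np.full(arr.size, -1, np.int64),
            empty,
            empty,
            empty,
            empty.astype(np.int64),
            empty.astype(np.int64),
            empty.astype(bool),
        )
    flat_labels = labels.ravel()
    counts = np.bincount(flat_labels, minlength=n + 1)[1:].astype(np.float64)
    rows, cols = np.nonzero(labels)
    lab_idx = labels[rows, cols] - 1
    sum_r = np.bincount(lab_idx, weights=rows, minlength=n)
    sum_c = np.bincount(lab_idx, weights=cols, minlength=n)
    value = np.zeros(n, dtype=np.float64)
    value[lab_idx] = arr[rows, cols]
    cr = sum_r / counts
    cc = sum_c / counts
    rr = _round_half_down(cr)
    rc = _round_half_down(cc)
    border = np.zeros(n, dtype=bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        ids = np.unique(edge)
        ids = ids[ids > 0]
        border[ids - 1] = True
    return flat_labels.astype(np.int64) - 1, value, cr, cc, rr, rc, border


def _accepted_points(arr: np.ndarray, tol: float) -> np.ndarray:
    """Accepted maxima of a 2D uint8 array as a sorted (N, 2) int array."""
    h, w = arr.shape
    plateau_of, value, cr, cc, rr, rc, border = _candidate_plateaus(arr)
    n_cand = value.shape[0]
    if n_cand == 0:
        return np.zeros((0, 2), dtype=np.int64)
    # deterministic candidate ranking for group tie-breaks:
    # rounded centroid first, then exact centroid, then label id
    order = np.lexsort((np.arange(n_cand), cc, cr, rc, rr))
    rank = np.empty(n_cand, dtype=np.int64)
    rank[order] = np.arange(n_cand)

    flat = arr.ravel().astype(np.int64)
    pixel_order = np.argsort(-flat, kind="stable")
    status = np.zeros(n_cand, dtype=np.int64)
    pend_next = np.full(n_cand, -1, dtype=np.int64)
    resolve_maxima(
        flat,
        pixel_order,
        h,
        w,
        float(tol),
        plateau_of,
        value,
        rank,
        status,
        pend_next,
    )
    keep = (status == ACCEPTED) | ((status == PENDING) & ~border)
    pts = np.stack([rr[keep], rc[keep]], axis=1)
    if pts.shape[0] == 0:
        return pts
    pts = np.unique(pts, axis=0)  # sorts by (row, col) and drops duplicates
    return pts


def find_maxima(
    img: Micrograph,
    noise_tolerance: float = DEFAULT_NOISE_TOLERANCE,
    invert_first: bool = True,
) -> TrichomePoints:
    """Detect prominent spots; with ``invert_first`` dark spots on pale ground.

    Trichome detection always inverts first because the base of each
    trichome is darker than the surrounding blade.
    """
    if noise_tolerance < 0:
        raise InputError("noise tolerance must be >= 0")
    work = (255 - img.pixels) if invert_first else img.pixels
    pts = _accepted_points(work, float(noise_tolerance))
    return TrichomePoints(pts, float(noise_tolerance), img.shape)


def count_maxima(img: Micrograph, roi, noise_tolerance: float = DEFAULT_NOISE_TOLERANCE) -> int:
    """Number of detected trichomes inside an ROI.

    Detection runs on the *full* image and the points are then filtered by
    the ROI, so tolerance comparisons near the ROI border behave exactly as
    they do in a whole-image analysis.
    """
    roi.validate_within(img.shape)
    pts = find_maxima(img, noise_tolerance, invert_first=True)
    return int(np.count_nonzero(roi.contains(pts.points)))


def trichome_spacing_cells(
    img: Micrograph,
    noise_tolerance: float = DEFAULT_NOISE_TOLERANCE,
    points: TrichomePoints | None = None,
) -> SpacingCells:
    """Partition the image into one watershed cell per detected trichome.

    Seeds are the accepted maxima of the inverted image; flooding proceeds in
    decreasing inverted intensity; pixels claimed simultaneously by two
    basins become boundary (label 0).  Pass precomputed ``points`` to reuse a
    detection.
    """
    if points is None:
        points = find_maxima(img, noise_tolerance, invert_first=True)
    if len(points) == 0:
        raise EmptyResultError(
            "no trichomes detected; lower the noise tolerance and retry"
        )
    h, w = img.shape
    labels = np.zeros(h * w, dtype=np.int64)
    seeds = points.points
    labels[seeds[:, 0] * w + seeds[:, 1]] = np.arange(1, len(points) + 1)
    inverted = (255 - img.pixels).ravel().astype(np.int64)
    watershed_flood(inverted, labels, h, w)
    label_map = labels.reshape(h, w)
    label_map[label_map < 0] = 0
    areas = np.bincount(label_map.ravel(), minlength=len(points) + 1)
    areas[0] = 0
    return SpacingCells(label_map=label_map, cell_areas=areas, seeds=seeds.copy())


def save_points(points: TrichomePoints, path: str | os.PathLike) -> None:
    """Write detections as CSV (header ``row,col``) or JSON by extension."""
    path = os.fspath(path)
    if path.lower().endswith(".json"):
        payload = {
            "noise_tolerance": points.noise_tolerance,
            "source_dims": list(points.source_dims),
            "points": [[int(r), int(c)] for r, c in points.points],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col"])
            writer.writerows([[int(r), int(c)] for r, c in points.points])


def load_points(path: str | os.PathLike) -> TrichomePoints:
    path = os.fspath(path)
    if path.lower().endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        return TrichomePoints(
            np.asarray(payload["points"], dtype=np.int64).reshape(-1, 2),
            float(payload.get("noise_tolerance", DEFAULT_NOISE_TOLERANCE)),
            tuple(payload.get("source_dims", (0, 0))),
        )
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip() for h in header] != ["row", "col"]:
            raise InputError(f"expected 'row,col' header in {path}")
        pts = np.asarray([[int(r), int(c)] for r, c in reader], dtype=np.int64)
    return TrichomePoints(pts.reshape(-1, 2), DEFAULT_NOISE_TOLERANCE, (0, 0))
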