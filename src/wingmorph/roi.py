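"""Square and polygon ROIs, area measurement and trichome density.

The two classic ways of measuring local cell density on a wing micrograph:
click a point and count trichomes in a fixed square (presets 75 px and
150 px), or outline a whole compartment as a polygon and count inside it.
Density is trichomes per px^2 of subtended area, the only dimensionally
coherent reading of "density per pixel".

Conventions: a square of side s is centered on the click, an even side
extending one extra pixel down/right; polygon vertices are continuous
``(col, row)`` points at pixel centers, the area is the shoelace formula,
and point-in-polygon uses the even-odd rule with boundary points counted as
inside.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, InputError
from .image import Micrograph
from .maxima import DEFAULT_NOISE_TOLERANCE, find_maxima

__all__ = [
    "PixelCoord",
    "Roi",
    "DensityResult",
    "square_roi",
    "polygon_roi",
    "polygon_area",
    "measure_density",
    "count_in_square",
    "count_in_polygon",
    "density_ratio",
    "load_roi",
    "save_roi",
    "append_result_log",
]

SQUARE_PRESETS = (75, 150)

_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class PixelCoord:
    """0-based (row, col) pixel index, origin at the top-left."""

    row: int
    col: int


def polygon_area(vertices) -> float:
    """Shoelace area (px^2) of a simple polygon, orientation independent."""
    verts = _as_vertex_array(vertices)
    _check_simple(verts)
    x = verts[:, 0]
    y = verts[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def _as_vertex_array(vertices) -> np.ndarray:
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise InputError("a polygon needs at least 3 (col, row) vertices")
    if not np.all(np.isfinite(verts)):
        raise InputError("polygon vertices must be finite")
    return verts


def _check_simple(verts: np.ndarray) -> None:
    from shapely.geometry import Polygon

    poly = Polygon(verts)
    if (not poly.is_valid) or poly.area <= 0:
        raise InputError("polygon must be simple (non-self-intersecting) with positive area")


def _points_in_polygon(points_rc: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd containment of (row, col) points; boundary counts as inside."""
    if points_rc.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    px = points_rc[:, 1].astype(np.float64)  # col -> x
    py = points_rc[:, 0].astype(np.float64)  # row -> y
    n = verts.shape[0]
    inside = np.zeros(px.shape[0], dtype=bool)
    on_edge = np.zeros(px.shape[0], dtype=bool)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # boundary test: point on the closed segment
        dx, dy = x2 - x1, y2 - y1
        cross = (px - x1) * dy - (py - y1) * dx
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            on_edge |= (np.abs(px - x1) < _EDGE_EPS) & (np.abs(py - y1) < _EDGE_EPS)
            continue
        t = ((px - x1) * dx + (py - y1) * dy) / seg2
        on_edge |= (
            (np.abs(cross) < _EDGE_EPS * np.sqrt(seg2) * 1e3)
            & (t >= -_EDGE_EPS)
            & (t <= 1 + _EDGE_EPS)
        )
        # even-odd ray crossing (horizontal ray toward +x)
        cond = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
        inside ^= cond & (px < xin)
    return inside | on_edge


@dataclass
class Roi:
    """A square or polygon region in image coordinates.

    Squares carry ``center`` and ``side``; polygons carry ``vertices`` as an
    (N, 2) array of continuous (col, row) points.
    """

    kind: str
    center: PixelCoord | None = None
    side: int | None = None
    vertices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "square":
            if self.center is None or self.side is None or self.side < 1:
                raise InputError("square ROI needs a center and a side >= 1")
        elif self.kind == "polygon":
            self.vertices = _as_vertex_array(self.vertices)
            _check_simple(self.vertices)
        else:
            raise InputError(f"unknown ROI kind {self.kind!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def area_px2(self) -> float:
        if self.kind == "square":
            return float(self.side) ** 2
        return polygon_area(self.vertices)

    def square_bounds(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) inclusive bounds of a square ROI."""
        off = (self.side - 1) // 2
        r0 = self.center.row - off
        c0 = self.center.col - off
        return r0, r0 + self.side - 1, c0, c0 + self.side - 1

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.kind == "square":
            r0, r1, c0, c1 = self.square_bounds()
            if r0 < 0 or c0 < 0 or r1 >= h or c1 >= w:
                off = (self.side - 1) // 2
                sug_r = int(np.clip(self.center.row, off, h - 1 - (self.side - 1 - off)))
                sug_c = int(np.clip(self.center.col, off, w - 1 - (self.side - 1 - off)))
                raise InputError(
                    f"square ROI (center=({self.center.row},{self.center.col}), "
                    f"side={self.side}) exits the {h}x{w} image; nearest valid "
                    f"center is ({sug_r},{sug_c})"
                )
        else:
            v = self.vertices
            if (
                v[:, 0].min() < 0
                or v[:, 1].min() < 0
                or v[:, 0].max() > w - 1
                or v[:, 1].max() > h - 1
            ):
                raise InputError(f"polygon ROI exits the {h}x{w} image bounds")

    def contains(self, points_rc: np.ndarray) -> np.ndarray:
        """Boolean mask of (row, col) points inside the ROI (boundary inclusive)."""
        points_rc = np.asarray(points_rc).reshape(-1, 2)
        if self.kind == "square":
            r0, r1, c0, c1 = self.square_bounds()
            return (
                (points_rc[:, 0] >= r0)
                & (points_rc[:, 0] <= r1)
                & (points_rc[:, 1] >= c0)
                & (points_rc[:, 1] <= c1)
            )
        return _points_in_polygon(points_rc.astype(np.float64), self.vertices)


@dataclass
class DensityResult:
    """Trichome count, area and density for one ROI measurement."""

    roi: Roi
    trichome_count: int
    area_px2: float
    density: float
    noise_tolerance: float

    def __post_init__(self) -> None:
        if self.area_px2 <= 0:
            raise InputError("ROI area must be positive")
        if self.trichome_count < 0:
            raise InputError("trichome count must be >= 0")


def square_roi(center: PixelCoord | tuple[int, int], side: int, img_dims: tuple[int, int]) -> Roi:
    """Square of the given side centered on the click point, bounds-checked."""
    if side < 1:
        raise InputError("square side must be >= 1")
    if not isinstance(center, PixelCoord):
        center = PixelCoord(int(center[0]), int(center[1]))
    roi = Roi(kind="square", center=center, side=int(side))
    roi.validate_within(img_dims)
    return roi


def polygon_roi(vertices, img_dims: tuple[int, int] | None = None) -> Roi:
    """Polygon ROI from (col, row) vertices, optionally bounds-checked."""
    roi = Roi(kind="polygon", vertices=vertices)
    if img_dims is not None:
        roi.validate_within(img_dims)
    return roi


def measure_density(
    img: Micrograph, roi: Roi, noise_tolerance: float = DEFAULT_NOISE_TOLERANCE
) -> DensityResult:
    """Count full-image detections inside the ROI and derive the density.

    ``density * area_px2 == trichome_count`` holds exactly.
    """
    roi.validate_within(img.shape)
    pts = find_maxima(img, noise_tolerance, invert_first=True)
    count = int(np.count_nonzero(roi.contains(pts.points)))
    area = roi.area_px2
    return DensityResult(
        roi=roi,
        trichome_count=count,
        area_px2=area,
        density=count / area,
        noise_tolerance=float(noise_tolerance),
    )


def count_in_square(
    img: Micrograph,
    center: PixelCoord | tuple[int, int],
    side: int = 75,
    noise_tolerance: float = DEFAULT_NOISE_TOLERANCE,
) -> DensityResult:
    return measure_density(img, square_roi(center, side, img.shape), noise_tolerance)


def count_in_polygon(
    img: Micrograph, vertices, noise_tolerance: float = DEFAULT_NOISE_TOLERANCE
) -> DensityResult:
    return measure_density(img, polygon_roi(vertices, img.shape), noise_tolerance)


def density_ratio(a: DensityResult, b: DensityResult) -> float:
    """a.density / b.density, e.g. posterior/anterior compartment ratio."""
    if b.density <= 0:
        raise ComputationError("denominator density is zero")
    return a.density / b.density


# -- ROI / result file formats -------------------------------------------


def save_roi(roi: Roi, path: str | os.PathLike) -> None:
    if roi.kind == "square":
        payload = {
            "kind": "square",
            "center": [roi.center.row, roi.center.col],
            "side": roi.side,
        }
    else:
        payload = {"kind": "polygon", "vertices": roi.vertices.tolist()}
    with open(os.fspath(path), "w") as fh:
        json.dump(payload, fh, indent=1)


def load_roi(path: str | os.PathLike) -> Roi:
    with open(os.fspath(path)) as fh:
        payload = json.load(fh)
    kind = payload.get("kind")
    if kind == "square":
        r, c = payload["center"]
        return Roi(kind="square", center=PixelCoord(int(r), int(c)), side=int(payload["side"]))
    if kind == "polygon":
        return Roi(kind="polygon", vertices=payload["vertices"])
    raise InputError(f"unknown ROI kind in {path}: {kind!r}")


_LOG_COLUMNS = ["image", "roi_id", "area_px2", "count", "density", "noise_tolerance"]


def append_result_log(
    path: str | os.PathLike, image: str, roi_id: str, result: DensityResult
) -> None:
    """Append one measurement to a CSV results log (header written once)."""
    path = os.fspath(path)
    new = not os.path.exists(path)
    with open(path, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(_LOG_COLUMNS)
        writer.writerow(
            [
                image,
                roi_id,
                repr(result.area_px2),
                result.trichome_count,
                repr(result.density),
                result.noise_tolerance,
            ]
        )
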