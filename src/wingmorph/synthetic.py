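"""Synthetic wing micrographs with full ground truth.

The generator emulates a transmitted-light photomicrograph of an insect
wing: a pale featureless background (the empty slide), a slightly darker
blade bounded by a margin, dark elongated veins partitioning the blade into
seven intervein regions, and a quasi-regular lattice of trichomes whose
bases are *slightly* darker than the blade.  It also reproduces, at stated
fractions, the two classes of trichomes that defeat prominence-based
detection on real wings: dorsal/ventral pairs that coincide and share a
base, and undersized faint trichomes whose prominence straddles the default
noise tolerance.  Gaussian pixel noise and dirt specks are added last.

Every draw comes from one seeded ``numpy.random.Generator``, so a (params,
seed) pair maps to a bit-identical image and truth record.

What the synthetic wings do *not* emulate: optical vignetting and defocus
gradients, dust *on the optics* (only on the slide), wing folds/bubbles from
mounting, and the anatomical shapes of real vein corrugations — so a
detector that performs well here is validated for the geometry and contrast
regime, not for every artifact of a real slide.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import GeneratorError, InputError
from .image import Micrograph
from .maxima import TrichomePoints

__all__ = [
    "WingParams",
    "WingGroundTruth",
    "DetectionMetrics",
    "generate_wing",
    "evaluate_detection",
    "class_map_working",
    "scribbles_from_truth",
    "select_audit_squares",
    "region_polygon",
]

WORKING_SHAPE = (380, 512)  # rows x cols, i.e. 512 x 380 (width x height)

_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class WingParams:
    """Generator parameters; the defaults are the package's study conditions.

    ``shape`` matches the 2080 x 1544 capture resolution of the wing
    micrographs this pipeline targets.  ``trichome_rate`` (trichomes/px^2)
    gives ~65 trichomes in a 75 px square, the density regime in which the
    detector is meant to operate; ``rate_ratio`` scales the posterior
    compartment's rate relative to the anterior (1.0 = uniform wing).
    ``coincident_fraction`` and ``small_faint_fraction`` set the two
    detection-failure classes; ``noise_sigma`` is additive Gaussian pixel
    noise on the 8-bit scale; ``dirt_count`` dark specks land anywhere on
    the slide.  Intensity levels put the inverted-image prominence of a
    normal trichome at ~28-42 and of a small-faint one at ~8-14, so the
    default noise tolerance of 10 cleanly accepts the former and straddles
    the latter.
    """

    shape: tuple[int, int] = (1544, 2080)
    trichome_rate: float = 0.0115
    rate_ratio: float = 1.0
    coincident_fraction: float = 0.02
    small_faint_fraction: float = 0.03
    noise_sigma: float = 4.0
    dirt_count: int = 12
    background_level: float = 240.0
    intervein_level: float = 225.0
    vein_level: float = 120.0
    trichome_contrast: tuple[float, float] = (28.0, 42.0)
    faint_contrast: tuple[float, float] = (8.0, 14.0)
    trichome_diameter: float = 5.0
    vein_width: float = 12.0
    margin_width: float = 14.0
    placement_margin: float = 9.0
    jitter: float = 0.15
    blur_sigma: float = 2.0

    def clean(self) -> "WingParams":
        """Copy with both failure classes, noise and dirt switched off."""
        return replace(
            self,
            coincident_fraction=0.0,
            small_faint_fraction=0.0,
            noise_sigma=0.0,
            dirt_count=0,
        )

    def validate(self) -> None:
        h, w = self.shape
        if h < 256 or w < 256:
            raise InputError("wing dimensions must be at least 256x256")
        if self.trichome_rate <= 0 or self.rate_ratio <= 0:
            raise InputError("trichome rates must be positive")
        for name in ("coincident_fraction", "small_faint_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1]")
        # densest lattice any region can request, including the capped
        # erosion compensation applied during placement
        dense_rate = self.trichome_rate * max(1.0, self.rate_ratio) * 1.25
        spacing = _lattice_spacing(dense_rate)
        min_dist = spacing * (1.0 - 2.0 * np.sqrt(2.0) * self.jitter)
        if min_dist < self.trichome_diameter:
            raise GeneratorError(
                f"requested rate {dense_rate:.4g}/px^2 packs trichome bases "
                f"(diameter {self.trichome_diameter} px) closer than they are wide"
            )


@dataclass
class WingGroundTruth:
    """Everything the generator knows about a synthetic wing."""

    coords: np.ndarray  # (N, 2) float (row, col) true base centers
    diameter: np.ndarray
    contrast: np.ndarray
    coincident: np.ndarray  # bool, True for both members of a shared-base pair
    small_faint: np.ndarray  # bool
    region_of: np.ndarray  # int, region id (1..k) of each trichome
    vein_mask: np.ndarray
    intervein_mask: np.ndarray
    background_mask: np.ndarray
    region_labels: np.ndarray  # int map, 1..k by decreasing area, 0 elsewhere
    region_rates: dict[int, float]  # requested rate per region (trichomes/px^2)
    region_compartment: dict[int, str]  # "anterior" | "posterior"
    params: WingParams
    seed: int

    @property
    def n_regions(self) -> int:
        return int(self.region_labels.max())

    @property
    def n_trichomes(self) -> int:
        return int(self.coords.shape[0])


# ----------------------------------------------------------------- geometry


def _lattice_spacing(rate: float) -> float:
    """Triangular-lattice spacing that realizes ``rate`` points per px^2."""
    return float(np.sqrt(2.0 / (np.sqrt(3.0) * rate)))


def _bezier(p0, p1, p2, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _wing_geometry(shape):
    """Analytic blade ellipse and vein centerlines in (row, col) coords."""
    h, w = shape
    center = np.array([0.52 * h, 0.50 * w])
    ar, ac = 0.40 * h, 0.46 * w
    hinge = np.array([0.52 * h, center[1] - 0.93 * ac])
    angles = np.deg2rad([-62.0, -32.0, -5.0, 22.0, 50.0])
    curves = []
    for phi in angles:
        end = center + np.array([ar * np.sin(phi), ac * np.cos(phi)])
        ctrl = 0.5 * (hinge + end)
        ctrl = ctrl + 0.18 * (center - ctrl)  # gentle bow toward the blade center
        n = int(max(600, 2 * np.hypot(*(end - hinge))))
        curves.append(_bezier(hinge, ctrl, end, n))
    # cross veins: short connectors between neighboring longitudinal veins
    cross = []
    for (i, j, t) in ((2, 3, 0.52), (3, 4, 0.64)):
        a = curves[i][int(t * (len(curves[i]) - 1))]
        b = curves[j][int(t * (len(curves[j]) - 1))]
        n = int(max(60, 2 * np.hypot(*(b - a))))
        cross.append(np.linspace(a, b, n))
    return center, (ar, ac), curves + cross


def _wing_masks(params: WingParams):
    """Rasterize blade/margin/vein geometry into disjoint class masks."""
    h, w = params.shape
    center, (ar, ac), polylines = _wing_geometry(params.shape)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    e = ((rows - center[0]) / ar) ** 2 + ((cols - center[1]) / ac) ** 2
    blade = e <= 1.0

    centerline = np.zeros((h, w), dtype=bool)
    for line in polylines:
        rr = np.clip(np.round(line[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(line[:, 1]).astype(int), 0, w - 1)
        centerline[rr, cc] = True
    dist_vein = ndimage.distance_transform_edt(~centerline)
    vein_band = dist_vein <= params.vein_width / 2.0

    dist_edge = ndimage.distance_transform_edt(blade)
    margin = blade & (dist_edge <= params.margin_width)

    vein_mask = blade & (vein_band | margin)
    intervein = blade & ~vein_mask
    background = ~blade

    labels, n = ndimage.label(intervein, structure=_FOUR)
    areas = np.bincount(labels.ravel())[1:]
    # absorb rasterization slivers into the vein class
    tiny = np.nonzero(areas < 0.01 * areas.max())[0] + 1
    if tiny.size:
        sliver = np.isin(labels, tiny)
        vein_mask |= sliver
        intervein &= ~sliver
        labels, n = ndimage.label(intervein, structure=_FOUR)
        areas = np.bincount(labels.ravel())[1:]
    # relabel 1..k by decreasing area (ties by old label id, deterministic)
    order = np.argsort(-areas, kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[labels]
    return vein_mask, intervein, background, labels


# ----------------------------------------------------------- trichome placement


def _place_trichomes(truth_masks, params: WingParams, rng):
    """Jittered triangular lattice per region at that region's rate.

    The lattice rate is boosted by area/eroded-area so that the *realized*
    per-region count matches rate x full region area even though bases keep
    ``placement_margin`` px clear of veins and margin.
    """
    vein_mask, intervein, background, labels = truth_masks
    h, w = params.shape
    dt_iv = ndimage.distance_transform_edt(intervein)
    center_row = 0.52 * h

    n_regions = int(labels.max())
    coords = []
    region_of = []
    region_rates: dict[int, float] = {}
    region_compartment: dict[int, str] = {}
    objs = ndimage.find_objects(labels)
    for rid in range(1, n_regions + 1):
        sl = objs[rid - 1]
        region = labels[sl] == rid
        rr, cc = np.nonzero(region)
        centroid_row = rr.mean() + sl[0].start
        compartment = "posterior" if centroid_row > center_row else "anterior"
        rate = params.trichome_rate * (
            params.rate_ratio if compartment == "posterior" else 1.0
        )
        region_rates[rid] = rate
        region_compartment[rid] = compartment

        area = rr.size
        placeable = region & (dt_iv[sl] > params.placement_margin)
        eroded_area = int(placeable.sum())
        if eroded_area == 0:
            continue
        # boost the lattice rate so the realized count matches rate x full
        # region area despite the placement margin; the cap keeps slim
        # regions from collapsing the lattice below the hard-core spacing
        eff_rate = rate * min(area / eroded_area, 1.25)
        s = _lattice_spacing(eff_rate)
        dy = s * np.sqrt(3.0) / 2.0
        r0, c0 = sl[0].start, sl[1].start
        hh, ww = placeable.shape
        phase_r = rng.uniform(0, dy)
        phase_c = rng.uniform(0, s)
        n_rows = int(np.ceil(hh / dy)) + 2
        n_cols = int(np.ceil(ww / s)) + 2
        for i in range(n_rows):
            y = phase_r + i * dy - dy
            xs = phase_c + (np.arange(n_cols) - 1) * s + (s / 2.0 if i % 2 else 0.0)
            ys = np.full(n_cols, y)
            jx = rng.uniform(-params.jitter * s, params.jitter * s, n_cols)
            jy = rng.uniform(-params.jitter * s, params.jitter * s, n_cols)
            py = ys + jy
            px = xs + jx
            ok = (py >= 0) & (py <= hh - 1) & (px >= 0) & (px <= ww - 1)
            py, px = py[ok], px[ok]
            iy = np.round(py).astype(int)
            ix = np.round(px).astype(int)
            keep = placeable[iy, ix]
            for y_, x_ in zip(py[keep], px[keep]):
                coords.append((y_ + r0, x_ + c0))
                region_of.append(rid)

    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    region_of = np.asarray(region_of, dtype=np.int32)
    n = coords.shape[0]

    diameter = rng.uniform(
        params.trichome_diameter * 0.9, params.trichome_diameter * 1.1, n
    )
    contrast = rng.uniform(*params.trichome_contrast, n)
    small = np.zeros(n, dtype=bool)
    coincident = np.zeros(n, dtype=bool)

    if n and params.small_faint_fraction > 0:
        k = int(round(params.small_faint_fraction * n))
        idx = rng.choice(n, size=min(k, n), replace=False)
        small[idx] = True
        diameter[idx] = params.trichome_diameter / 2.0
        contrast[idx] = rng.uniform(*params.faint_contrast, idx.size)

    if n and params.coincident_fraction > 0:
        eligible = np.nonzero(~small)[0]
        k = int(round(params.coincident_fraction * n))
        idx = rng.choice(eligible, size=min(k, eligible.size), replace=False)
        coincident[idx] = True
        extra_coords, extra_rid = [], []
        extra_d, extra_c = [], []
        for i in idx:
            theta = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.35, 0.7) * diameter[i]
            extra_coords.append(coords[i] + dist * np.array([np.sin(theta), np.cos(theta)]))
            extra_rid.append(region_of[i])
            extra_d.append(diameter[i])
            extra_c.append(contrast[i] * rng.uniform(0.9, 1.0))
        coords = np.vstack([coords, np.asarray(extra_coords).reshape(-1, 2)])
        region_of = np.concatenate([region_of, extra_rid]).astype(np.int32)
        diameter = np.concatenate([diameter, extra_d])
        contrast = np.concatenate([contrast, extra_c])
        small = np.concatenate([small, np.zeros(len(idx), dtype=bool)])
        coincident = np.concatenate([coincident, np.ones(len(idx), dtype=bool)])

    return coords, diameter, contrast, coincident, small, region_of, region_rates, region_compartment


# ------------------------------------------------------------------- render


def _stamp_blob(canvas, row, col, sigma, amplitude):
    """Add ``amplitude * exp(-d^2 / 2 sigma^2)`` centered at a subpixel point."""
    h, w = canvas.shape
    rad = int(np.ceil(3 * sigma))
    r0 = max(0, int(np.floor(row)) - rad)
    r1 = min(h, int(np.floor(row)) + rad + 2)
    c0 = max(0, int(np.floor(col)) - rad)
    c1 = min(w, int(np.floor(col)) + rad + 2)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    canvas[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def generate_wing(
    params: WingParams | None = None, seed: int = 0, **overrides
) -> tuple[Micrograph, WingGroundTruth]:
    """Render a synthetic wing and its ground truth; deterministic given seed."""
    params = replace(params or WingParams(), **overrides)
    params.validate()
    rng = np.random.default_rng(seed)

    masks = _wing_masks(params)
    vein_mask, intervein, background, labels = masks
    (
        coords,
        diameter,
        contrast,
        coincident,
        small,
        region_of,
        region_rates,
        region_compartment,
    ) = _place_trichomes(masks, params, rng)

    canvas = np.full(params.shape, params.background_level, dtype=np.float64)
    canvas[intervein | vein_mask] = params.intervein_level
    canvas[vein_mask] = params.vein_level
    canvas = ndimage.gaussian_filter(canvas, params.blur_sigma)

    shaft_theta = rng.uniform(0, 2 * np.pi, coords.shape[0])
    for i in range(coords.shape[0]):
        r, c = coords[i]
        sigma = diameter[i] / 3.0
        _stamp_blob(canvas, r, c, sigma, -contrast[i])
        # short brighter shaft leaning away from the base
        dr, dc = np.sin(shaft_theta[i]), np.cos(shaft_theta[i])
        for step in range(3):
            d = diameter[i] * (0.8 + 0.5 * step)
            _stamp_blob(canvas, r + dr * d, c + dc * d, 0.9, 5.0 * (1 - 0.25 * step))

    for _ in range(params.dirt_count):
        r = rng.uniform(0, params.shape[0] - 1)
        c = rng.uniform(0, params.shape[1] - 1)
        _stamp_blob(canvas, r, c, rng.uniform(1.0, 3.0), -rng.uniform(30.0, 80.0))

    if params.noise_sigma > 0:
        canvas += rng.normal(0.0, params.noise_sigma, params.shape)

    pixels = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    img = Micrograph(pixels, source="synthetic", scale_note=f"seed={seed}")
    truth = WingGroundTruth(
        coords=coords,
        diameter=diameter,
        contrast=contrast,
        coincident=coincident,
        small_faint=small,
        region_of=region_of,
        vein_mask=vein_mask,
        intervein_mask=intervein,
        background_mask=background,
        region_labels=labels,
        region_rates=region_rates,
        region_compartment=region_compartment,
        params=params,
        seed=seed,
    )
    return img, truth


# --------------------------------------------------------------- evaluation


@dataclass
class DetectionMetrics:
    """Greedy nearest-neighbor matching of detections against ground truth."""

    n_truth: int
    n_pred: int
    matched: int
    missed: int
    spurious: int
    recall: float
    precision: float
    truth_matched: np.ndarray
    pred_matched: np.ndarray


def evaluate_detection(
    pred: TrichomePoints | np.ndarray,
    truth: WingGroundTruth | np.ndarray,
    radius: float = 4.0,
) -> DetectionMetrics:
    """Match predictions to true trichome bases within ``radius`` px.

    Candidate pairs are matched greedily in increasing distance order; each
    truth and each prediction is used at most once.  ``recall`` is
    matched/|truth| and ``precision`` matched/|pred|.
    """
    if radius <= 0:
        raise InputError("matching radius must be positive")
    pred_pts = pred.points if isinstance(pred, TrichomePoints) else np.asarray(pred)
    truth_pts = truth.coords if isinstance(truth, WingGroundTruth) else np.asarray(truth)
    pred_pts = pred_pts.reshape(-1, 2).astype(np.float64)
    truth_pts = truth_pts.reshape(-1, 2).astype(np.float64)
    nt, npr = truth_pts.shape[0], pred_pts.shape[0]
    truth_used = np.zeros(nt, dtype=bool)
    pred_used = np.zeros(npr, dtype=bool)
    if nt and npr:
        from scipy.spatial import cKDTree

        tree = cKDTree(truth_pts)
        pairs = tree.query_ball_point(pred_pts, r=radius)
        cand = [
            (float(np.hypot(*(truth_pts[ti] - pred_pts[pi]))), ti, pi)
            for pi, tis in enumerate(pairs)
            for ti in tis
        ]
        cand.sort()
        for d, ti, pi in cand:
            if not truth_used[ti] and not pred_used[pi]:
                truth_used[ti] = True
                pred_used[pi] = True
    matched = int(truth_used.sum())
    return DetectionMetrics(
        n_truth=nt,
        n_pred=npr,
        matched=matched,
        missed=nt - matched,
        spurious=npr - matched,
        recall=matched / nt if nt else 1.0,
        precision=matched / npr if npr else 1.0,
        truth_matched=truth_used,
        pred_matched=pred_used,
    )


# ---------------------------------------------------- working-scale helpers


def class_map_working(truth: WingGroundTruth, shape=WORKING_SHAPE) -> np.ndarray:
    """Ground-truth class map (0=vein, 1=intervein, 2=background) at 512x380.

    Masks are downsampled by area coverage; the vein class wins whenever its
    coverage exceeds 0.3 so that thin veins stay connected and keep
    partitioning the blade at the working resolution.
    """
    from skimage.transform import resize as _sk_resize

    def frac(mask):
        return _sk_resize(
            mask.astype(np.float64), shape, order=1, anti_aliasing=True,
            preserve_range=True, mode="edge",
        )

    vf = frac(truth.vein_mask)
    ivf = frac(truth.intervein_mask)
    bf = frac(truth.background_mask)
    out = np.where(ivf >= bf, 1, 2).astype(np.uint8)
    out[vf >= 0.3] = 0
    return out


def scribbles_from_truth(
    truth: WingGroundTruth,
    n_per_class: int = 200,
    seed: int = 42,
    shape=WORKING_SHAPE,
) -> np.ndarray:
    """Sparse training scribbles sampled from the true class map.

    Returns a working-resolution label mask: 0 unlabeled, 1 vein,
    2 intervein, 3 background.  Samples avoid class boundaries, the way a
    human annotator scribbles inside obviously pure areas.
    """
    cmap = class_map_working(truth, shape)
    rng = np.random.default_rng(seed)
    out = np.zeros(shape, dtype=np.uint8)
    for cls in range(3):
        mask = cmap == cls
        interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), iterations=1)
        rr, cc = np.nonzero(interior if interior.sum() >= n_per_class else mask)
        if rr.size < n_per_class:
            raise GeneratorError(f"class {cls} has too few pure pixels to scribble")
        idx = rng.choice(rr.size, size=n_per_class, replace=False)
        out[rr[idx], cc[idx]] = cls + 1
    return out


def select_audit_squares(
    truth: WingGroundTruth, n: int = 5, side: int = 75
) -> list[tuple[int, int]]:
    """Deterministic centers of ``n`` audit squares inside distinct regions.

    Takes the ``n`` largest intervein regions and centers a square at each
    region's deepest interior point (Chebyshev distance transform argmax);
    squares in distinct vein-bounded regions cannot overlap.
    """
    labels = truth.region_labels
    half = (side - 1) // 2
    centers: list[tuple[int, int]] = []
    for rid in range(1, truth.n_regions + 1):
        if len(centers) >= n:
            break
        mask = labels == rid
        dt = ndimage.distance_transform_cdt(mask, metric="chessboard")
        if dt.max() <= half + 1:
            continue
        flat = int(np.argmax(dt))
        centers.append((flat // labels.shape[1], flat % labels.shape[1]))
    if len(centers) < n:
        raise GeneratorError(
            f"only {len(centers)} regions can hold a {side} px square"
        )
    return centers


def region_polygon(truth: WingGroundTruth, region_id: int, max_vertices: int = 128) -> np.ndarray:
    """Polygon (col, row) tracing a true intervein region's outline."""
    from shapely.geometry import Polygon
    from skimage.measure import find_contours

    mask = truth.region_labels == region_id
    if not mask.any():
        raise InputError(f"no region with id {region_id}")
    contours = find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col) points
    step = max(1, len(contour) // max_vertices)
    verts_rc = contour[::step]
    verts = np.stack([verts_rc[:, 1], verts_rc[:, 0]], axis=1)  # (col, row)
    h, w = truth.region_labels.shape
    verts[:, 0] = np.clip(verts[:, 0], 0, w - 1)
    verts[:, 1] = np.clip(verts[:, 1], 0, h - 1)
    if not Polygon(verts).is_valid:
        verts = np.asarray(Polygon(verts).convex_hull.exterior.coords[:-1])
    return verts


# ------------------------------------------------------------------ file IO


def save_truth(truth: WingGroundTruth, outdir: str | os.PathLike) -> None:
    """Write truth CSV, indexed-PNG masks and the parameter record."""
    import csv

    from PIL import Image

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "truth.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "diameter", "contrast", "coincident", "small_faint", "region"])
        for i in range(truth.n_trichomes):
            writer.writerow(
                [
                    f"{truth.coords[i, 0]:.2f}",
                    f"{truth.coords[i, 1]:.2f}",
                    f"{truth.diameter[i]:.2f}",
                    f"{truth.contrast[i]:.2f}",
                    int(truth.coincident[i]),
                    int(truth.small_faint[i]),
                    int(truth.region_of[i]),
                ]
            )
    class_map = np.full(truth.region_labels.shape, 2, dtype=np.uint8)
    class_map[truth.intervein_mask] = 1
    class_map[truth.vein_mask] = 0
    im = Image.fromarray(class_map, mode="P")
    im.putpalette([60, 60, 60, 120, 200, 120, 230, 230, 230] + [0] * 759)
    im.save(os.path.join(outdir, "class_map.png"))
    Image.fromarray(truth.region_labels.astype(np.uint8), mode="P").save(
        os.path.join(outdir, "region_labels.png")
    )
    record = asdict(truth.params)
    record["seed"] = truth.seed
    record["n_trichomes"] = truth.n_trichomes
    record["n_regions"] = truth.n_regions
    record["region_rates"] = {str(k): v for k, v in truth.region_rates.items()}
    record["region_compartment"] = truth.region_compartment
    with open(os.path.join(outdir, "params.json"), "w") as fh:
        json.dump(record, fh, indent=1)
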