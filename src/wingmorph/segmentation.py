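"""Trainable pixel classification of veins vs intervein vs background.

High-throughput wing morphometry needs the vein skeleton found
automatically: the image is shrunk to a fixed 512 x 380 working resolution,
every pixel gets a 15-dimensional texture/intensity feature vector, and a
random forest trained on sparse user scribbles (or generator ground truth)
assigns one of three classes — vein+margin, intervein blade, or empty
slide.  Particle analysis of the intervein class then yields labeled
regions whose areas and trichome densities are measured back at the source
resolution.

Three classes rather than two because the empty slide and the blade are
both pale: border-touching background must stay distinguishable from
intervein tissue or every segmentation would leak through the margin.

The forest is fit with scikit-learn, but prediction always runs through the
package's own serialized tree tables (per-tree argmax + majority vote, ties
to the first class in ``CLASS_LABELS``), so a model loaded from its JSON
file reproduces in-session predictions bit for bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._flood import forest_predict
from .errors import InputError, SegmentationError, TrainingError
from .image import Micrograph, resize
from .maxima import DEFAULT_NOISE_TOLERANCE, find_maxima

__all__ = [
    "CLASS_LABELS",
    "WORKING_SHAPE",
    "PixelClassifierModel",
    "InterveinRegion",
    "compute_features",
    "train_classifier",
    "segment_wing",
    "extract_intervein_regions",
    "intervein_density",
    "save_model",
    "load_model",
    "write_region_table",
]

CLASS_LABELS = ("vein", "intervein", "background")
WORKING_SHAPE = (380, 512)  # rows x cols == 512 x 380 in width x height
MIN_REGION_AREA = 200  # px at working resolution
MIN_LABELS_PER_CLASS = 50
MODEL_FORMAT_VERSION = 1

_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# (feature name, scale sigma); order is the feature-vector order
FEATURE_SPEC: tuple[tuple[str, float], ...] = (
    ("intensity", 0.0),
    *[("gaussian", s) for s in (1.0, 2.0, 4.0, 8.0, 16.0)],
    *[("gradient_magnitude", s) for s in (1.0, 2.0, 4.0)],
    ("difference_of_gaussians", (1.0, 4.0)),
    ("difference_of_gaussians", (2.0, 8.0)),
    *[
        (name, s)
        for s in (2.0, 4.0)
        for name in ("hessian_eig_large", "hessian_eig_small")
    ],
)


def compute_features(img: Micrograph) -> np.ndarray:
    """Per-pixel feature stack at the working resolution.

    Returns a float64 array of shape (380, 512, 15): raw intensity,
    Gaussian smooths (sigma 1,2,4,8,16), gradient magnitudes (sigma 1,2,4),
    differences of Gaussians (1,4) and (2,8), and the larger/smaller Hessian
    eigenvalues at sigma 2 and 4 (ridge detectors — veins are dark elongated
    ridges).
    """
    if img.shape != WORKING_SHAPE:
        raise InputError(
            f"features are computed at the {WORKING_SHAPE[1]}x{WORKING_SHAPE[0]} "
            f"working resolution, got {img.width}x{img.height}"
        )
    from skimage.feature import hessian_matrix, hessian_matrix_eigvals

    x = img.pixels.astype(np.float64)
    feats: list[np.ndarray] = [x]
    smooth = {s: ndimage.gaussian_filter(x, s) for s in (1.0, 2.0, 4.0, 8.0, 16.0)}
    feats.extend(smooth[s] for s in (1.0, 2.0, 4.0, 8.0, 16.0))
    feats.extend(
        ndimage.gaussian_gradient_magnitude(x, s) for s in (1.0, 2.0, 4.0)
    )
    feats.append(smooth[1.0] - smooth[4.0])
    feats.append(smooth[2.0] - smooth[8.0])
    for s in (2.0, 4.0):
        H = hessian_matrix(
            x, sigma=s, order="rc", mode="reflect", use_gaussian_derivatives=True
        )
        large, small = hessian_matrix_eigvals(H)
        feats.append(large)
        feats.append(small)
    assert len(feats) == len(FEATURE_SPEC)
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifierModel:
    """A trained 3-class pixel classifier as portable tree tables.

    Tree arrays are concatenated node tables (children stored tree-relative,
    -1 marks a leaf) with ``tree_offsets`` delimiting each tree; this is the
    whole decision function, so the model round-trips through JSON.
    """

    feature_spec: tuple = FEATURE_SPEC
    class_labels: tuple[str, ...] = CLASS_LABELS
    n_trees: int = 100
    train_seed: int = 0
    train_accuracy: float = 0.0
    children_left: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    children_right: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    feature: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    threshold: np.ndarray = field(default_factory=lambda: np.zeros(0, np.float64))
    leaf_class: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    tree_offsets: np.ndarray = field(default_factory=lambda: np.zeros(1, np.int64))

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Class indices (into ``class_labels``) for an (..., 15) feature array."""
        lead = features.shape[:-1]
        X = np.ascontiguousarray(features.reshape(-1, features.shape[-1]))
        out = forest_predict(
            X,
            self.children_left,
            self.children_right,
            self.feature,
            self.threshold,
            self.leaf_class,
            self.tree_offsets,
            len(self.class_labels),
        )
        return out.reshape(lead)


def _tables_from_sklearn(forest) -> dict[str, np.ndarray]:
    cl, cr, ft, th, lc, offsets = [], [], [], [], [], [0]
    for est in forest.estimators_:
        t = est.tree_
        cl.append(t.children_left)
        cr.append(t.children_right)
        ft.append(np.where(t.children_left == -1, 0, t.feature))
        th.append(t.threshold)
        votes = t.value[:, 0, :]
        lc.append(np.argmax(votes, axis=1))
        offsets.append(offsets[-1] + t.node_count)
    return {
        "children_left": np.concatenate(cl).astype(np.int64),
        "children_right": np.concatenate(cr).astype(np.int64),
        "feature": np.concatenate(ft).astype(np.int64),
        "threshold": np.concatenate(th).astype(np.float64),
        "leaf_class": np.concatenate(lc).astype(np.int64),
        "tree_offsets": np.asarray(offsets, dtype=np.int64),
    }


def train_classifier(
    img: Micrograph,
    labels: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
) -> PixelClassifierModel:
    """Fit the forest on scribble-labeled pixels of a working-resolution image.

    ``labels`` is a (380, 512) mask: 0 unlabeled, 1 vein, 2 intervein,
    3 background; each class needs at least 50 labeled pixels.  Each of the
    ``n_trees`` trees is grown on a bootstrap sample with sqrt(n_features)
    candidate features per split; the whole fit is deterministic given
    ``seed``.  Raises if the fitted forest reproduces fewer than 95% of its
    own training labels — a model that cannot even memorize its scribbles
    will not segment anything.
    """
    labels = np.asarray(labels)
    if labels.shape != WORKING_SHAPE:
        raise InputError(f"label mask must have shape {WORKING_SHAPE}")
    for cls_idx, name in enumerate(CLASS_LABELS):
        n = int(np.count_nonzero(labels == cls_idx + 1))
        if n < MIN_LABELS_PER_CLASS:
            raise TrainingError(
                f"class '{name}' has {n} labeled pixels; at least "
                f"{MIN_LABELS_PER_CLASS} are required"
            )
    from sklearn.ensemble import RandomForestClassifier

    feats = compute_features(img)
    rr, cc = np.nonzero(labels)
    X = feats[rr, cc, :]
    y = labels[rr, cc] - 1
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    model = PixelClassifierModel(
        n_trees=n_trees, train_seed=seed, **_tables_from_sklearn(forest)
    )
    acc = float(np.mean(model.predict(X) == y))
    model.train_accuracy = acc
    if acc < 0.95:
        raise TrainingError(
            f"training-pixel accuracy {acc:.3f} is below the 0.95 sanity floor; "
            "check the scribbles for mislabeled pixels"
        )
    return model


@dataclass
class SegmentationResult:
    """Class map at working resolution plus a source-resolution outline render."""

    class_map: np.ndarray  # (380, 512) uint8, indices into CLASS_LABELS
    outline: np.ndarray  # (H, W, 3) uint8 RGB, boundaries drawn on the source image


def segment_wing(img: Micrograph, model: PixelClassifierModel) -> SegmentationResult:
    """Classify every pixel of a micrograph at the working resolution.

    The image is resized to 512 x 380, classified by majority vote of the
    forest, despeckled once with a 3 x 3 modal filter, and the class
    boundaries are rendered onto the source-resolution image (nearest
    neighbor upscale of the class map).
    """
    if tuple(model.feature_spec) != tuple(FEATURE_SPEC):
        raise InputError("model was trained with an incompatible feature stack")
    work = resize(img, WORKING_SHAPE[1], WORKING_SHAPE[0])
    feats = compute_features(work)
    class_map = model.predict(feats).astype(np.uint8)
    from skimage.filters.rank import modal
    from skimage.morphology import footprint_rectangle

    class_map = modal(class_map, footprint_rectangle((3, 3)))
    outline = _render_outline(img, class_map)
    return SegmentationResult(class_map=class_map, outline=outline)


def _render_outline(img: Micrograph, class_map: np.ndarray) -> np.ndarray:
    from skimage.segmentation import find_boundaries

    up = _upscale_nearest(class_map, img.shape)
    edges = find_boundaries(up, mode="thick")
    rgb = np.stack([img.pixels] * 3, axis=-1).astype(np.uint8)
    rgb[edges] = (255, 0, 255)
    return rgb


def _upscale_nearest(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rows = np.minimum(
        (np.arange(shape[0]) * arr.shape[0] / shape[0]).astype(int), arr.shape[0] - 1
    )
    cols = np.minimum(
        (np.arange(shape[1]) * arr.shape[1] / shape[1]).astype(int), arr.shape[1] - 1
    )
    return arr[np.ix_(rows, cols)]


@dataclass
class InterveinRegion:
    """One vein-bounded blade region found by particle analysis."""

    region_id: int
    mask: np.ndarray  # working resolution, hole-filled
    mask_fullres: np.ndarray  # nearest-neighbor upscale to source resolution
    area_px2: float  # pixel count at source resolution
    trichome_count: int | None = None
    density: float | None = None


def extract_intervein_regions(
    class_map: np.ndarray,
    source_shape: tuple[int, int],
    min_area: int = MIN_REGION_AREA,
) -> list[InterveinRegion]:
    """Particle analysis of the intervein class.

    4-connected intervein components are filtered by per-component
    predicates — hole-filled mask, filled area >= ``min_area`` (at working
    resolution), and no contact with the image border (border-touching
    intervein is background leaking through the margin).  Because each
    predicate is evaluated on the component itself, the outcome does not
    depend on any filter ordering.  Survivors are labeled 1..k by decreasing
    area and their masks upscaled to ``source_shape``, where ``area_px2`` is
    measured.
    """
    class_map = np.asarray(class_map)
    if class_map.shape != WORKING_SHAPE:
        raise InputError(f"class map must have shape {WORKING_SHAPE}")
    intervein = class_map == CLASS_LABELS.index("intervein")
    labels, n = ndimage.label(intervein, structure=_FOUR)
    h, w = class_map.shape
    border_ids = set()
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border_ids.update(np.unique(edge).tolist())
    survivors = []
    for rid in range(1, n + 1):
        if rid in border_ids:
            continue
        filled = ndimage.binary_fill_holes(labels == rid)
        area = int(filled.sum())
        if area < min_area:
            continue
        survivors.append((area, rid, filled))
    if not survivors:
        raise SegmentationError(
            "no intervein region survived particle analysis; retrain the "
            "classifier or check that the wing fills the frame"
        )
    survivors.sort(key=lambda t: (-t[0], t[1]))
    regions = []
    for out_id, (area, _rid, filled) in enumerate(survivors, start=1):
        full = _upscale_nearest(filled.astype(np.uint8), source_shape).astype(bool)
        regions.append(
            InterveinRegion(
                region_id=out_id,
                mask=filled,
                mask_fullres=full,
                area_px2=float(full.sum()),
            )
        )
    return regions


def intervein_density(
    img: Micrograph,
    region: InterveinRegion,
    noise_tolerance: float = DEFAULT_NOISE_TOLERANCE,
) -> InterveinRegion:
    """Fill in a region's trichome count and density from the source image."""
    if region.mask_fullres is None or not region.mask_fullres.any():
        raise InputError("region has an empty full-resolution mask")
    if region.mask_fullres.shape != img.shape:
        raise InputError("region mask does not match the micrograph dimensions")
    pts = find_maxima(img, noise_tolerance, invert_first=True)
    inside = region.mask_fullres[pts.points[:, 0], pts.points[:, 1]]
    count = int(np.count_nonzero(inside))
    return replace(
        region, trichome_count=count, density=count / region.area_px2
    )


# ------------------------------------------------------------------ file IO


def save_model(model: PixelClassifierModel, path: str | os.PathLike) -> None:
    """Serialize the classifier to a single versioned JSON file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_spec": [[name, s] for name, s in model.feature_spec],
        "class_labels": list(model.class_labels),
        "n_trees": model.n_trees,
        "train_seed": model.train_seed,
        "train_accuracy": model.train_accuracy,
        "children_left": model.children_left.tolist(),
        "children_right": model.children_right.tolist(),
        "feature": model.feature.tolist(),
        "threshold": model.threshold.tolist(),
        "leaf_class": model.leaf_class.tolist(),
        "tree_offsets": model.tree_offsets.tolist(),
    }
    with open(os.fspath(path), "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | os.PathLike) -> PixelClassifierModel:
    with open(os.fspath(path)) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise InputError(f"unsupported model format in {path}")
    spec = tuple(
        (name, tuple(s) if isinstance(s, list) else s)
        for name, s in payload["feature_spec"]
    )
    return PixelClassifierModel(
        feature_spec=spec,
        class_labels=tuple(payload["class_labels"]),
        n_trees=int(payload["n_trees"]),
        train_seed=int(payload["train_seed"]),
        train_accuracy=float(payload["train_accuracy"]),
        children_left=np.asarray(payload["children_left"], np.int64),
        children_right=np.asarray(payload["children_right"], np.int64),
        feature=np.asarray(payload["feature"], np.int64),
        threshold=np.asarray(payload["threshold"], np.float64),
        leaf_class=np.asarray(payload["leaf_class"], np.int64),
        tree_offsets=np.asarray(payload["tree_offsets"], np.int64),
    )


def write_region_table(regions: list[InterveinRegion], path: str | os.PathLike) -> None:
    """ROI table as CSV: region_id, area_px2, count, density."""
    import csv

    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region_id", "area_px2", "count", "density"])
        for r in regions:
            writer.writerow(
                [
                    r.region_id,
                    int(r.area_px2),
                    "" if r.trichome_count is None else r.trichome_count,
                    "" if r.density is None else repr(r.density),
                ]
            )
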