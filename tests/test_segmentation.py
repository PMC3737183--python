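"""Pixel classifier features, training, segmentation and particle analysis."""

import numpy as np
import pytest
from scipy import ndimage

from wingmorph.errors import InputError, SegmentationError, TrainingError
from wingmorph.image import Micrograph, resize
from wingmorph.segmentation import (
    FEATURE_SPEC,
    WORKING_SHAPE,
    compute_features,
    extract_intervein_regions,
    intervein_density,
    load_model,
    save_model,
    segment_wing,
    train_classifier,
)
from wingmorph.synthetic import class_map_working


def _iou(a, b):
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


# ---------------------------------------------------------------- features


def test_feature_stack_has_fifteen_features():
    assert len(FEATURE_SPEC) == 15
    img = Micrograph(np.full(WORKING_SHAPE, 128, np.uint8))
    assert compute_features(img).shape == WORKING_SHAPE + (15,)


def test_constant_image_has_zero_derivative_features():
    feats = compute_features(Micrograph(np.full(WORKING_SHAPE, 200, np.uint8)))
    names = [name for name, _ in FEATURE_SPEC]
    for i, name in enumerate(names):
        if name in ("gradient_magnitude", "difference_of_gaussians",
                    "hessian_eig_large", "hessian_eig_small"):
            assert np.allclose(feats[..., i], 0.0), name
        else:
            assert np.allclose(feats[..., i], 200.0), name


def test_impulse_gaussian_response_peaks_at_impulse():
    arr = np.zeros(WORKING_SHAPE, np.uint8)
    arr[190, 256] = 255
    feats = compute_features(Micrograph(arr))
    g1 = feats[..., 1]  # gaussian sigma=1
    assert np.unravel_index(np.argmax(g1), g1.shape) == (190, 256)


def test_wrong_resolution_rejected():
    with pytest.raises(InputError):
        compute_features(Micrograph(np.zeros((100, 100), np.uint8)))


# ---------------------------------------------------------------- training


def test_training_requires_fifty_pixels_per_class(trained_model):
    img, truth, labels, model = trained_model
    work = resize(img, 512, 380)
    sparse = labels.copy()
    vein_px = np.argwhere(sparse == 1)
    sparse[tuple(vein_px[30:].T)] = 0  # leave only 30 vein labels
    with pytest.raises(TrainingError, match="vein"):
        train_classifier(work, sparse, n_trees=10, seed=0)
    two_class = labels.copy()
    two_class[two_class == 3] = 0
    with pytest.raises(TrainingError, match="background"):
        train_classifier(work, two_class, n_trees=10, seed=0)


def test_training_is_seed_deterministic_and_accurate(trained_model):
    img, truth, labels, model = trained_model
    assert model.train_accuracy >= 0.95
    work = resize(img, 512, 380)
    again = train_classifier(work, labels, n_trees=100, seed=42)
    probe = compute_features(work)
    assert np.array_equal(model.predict(probe), again.predict(probe))


def test_model_json_round_trip(tmp_path, trained_model):
    img, truth, labels, model = trained_model
    path = tmp_path / "model.json"
    save_model(model, path)
    loaded = load_model(path)
    work = resize(img, 512, 380)
    probe = compute_features(work)
    assert np.array_equal(model.predict(probe), loaded.predict(probe))
    assert loaded.feature_spec == tuple(FEATURE_SPEC)


# ------------------------------------------------------------ segmentation


def test_segmenting_training_wing_iou(trained_model):
    img, truth, labels, model = trained_model
    seg = segment_wing(img, model)
    gt = class_map_working(truth)
    assert _iou(seg.class_map == 1, gt == 1) >= 0.90


def test_segmenting_heldout_wing_iou(trained_model, heldout_wing):
    img, truth = heldout_wing
    _, _, _, model = trained_model
    seg = segment_wing(img, model)
    gt = class_map_working(truth)
    assert _iou(seg.class_map == 1, gt == 1) >= 0.80
    assert seg.outline.shape == img.shape + (3,)


def test_blank_field_is_classified_background(trained_model):
    _, _, _, model = trained_model
    rng = np.random.default_rng(0)
    blank = np.clip(
        240 + rng.normal(0, 1.0, (1544, 2080)), 0, 255
    ).astype(np.uint8)
    seg = segment_wing(Micrograph(blank), model)
    assert np.mean(seg.class_map == 2) >= 0.95


# -------------------------------------------------------- particle analysis


def test_ground_truth_class_map_yields_generator_regions(heldout_wing):
    img, truth = heldout_wing
    regions = extract_intervein_regions(class_map_working(truth), img.shape)
    assert len(regions) == truth.n_regions
    # labels 1..k by strictly non-increasing area, masks pairwise disjoint
    areas = [r.area_px2 for r in regions]
    assert areas == sorted(areas, reverse=True)
    union = np.zeros(WORKING_SHAPE, bool)
    for r in regions:
        assert not (union & r.mask).any()
        union |= r.mask


def test_all_intervein_map_touches_border_and_fails():
    cmap = np.ones(WORKING_SHAPE, np.uint8)
    with pytest.raises(SegmentationError):
        extract_intervein_regions(cmap, (1544, 2080))


def test_min_area_filter_discards_specks():
    cmap = np.zeros(WORKING_SHAPE, np.uint8)  # all vein
    cmap[100:110, 100:110] = 1  # 100 px blob < 200 px minimum
    with pytest.raises(SegmentationError):
        extract_intervein_regions(cmap, (1544, 2080))
    cmap[200:220, 200:220] = 1  # 400 px blob survives
    regions = extract_intervein_regions(cmap, (1544, 2080))
    assert len(regions) == 1


def test_region_filters_match_brute_force_on_random_maps():
    """Per-component predicates vs an independently coded pixel filter."""
    rng = np.random.default_rng(3)
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for _ in range(20):
        blob = rng.random(WORKING_SHAPE) < 0.18
        blob = ndimage.binary_dilation(blob, iterations=2)
        cmap = blob.astype(np.uint8)  # 1 = intervein
        labels, n = ndimage.label(cmap == 1, structure=four)
        expected = set()
        for rid in range(1, n + 1):
            comp = labels == rid
            filled = ndimage.binary_fill_holes(comp)
            touches = (
                comp[0, :].any() or comp[-1, :].any()
                or comp[:, 0].any() or comp[:, -1].any()
            )
            if filled.sum() >= 200 and not touches:
                expected.add(frozenset(map(tuple, np.argwhere(filled))))
        try:
            regions = extract_intervein_regions(cmap, WORKING_SHAPE)
            got = {frozenset(map(tuple, np.argwhere(r.mask))) for r in regions}
        except SegmentationError:
            got = set()
        assert got == expected


# -------------------------------------------------------- region densities


def test_clean_region_density_matches_ground_truth(clean_small_wing):
    img, truth, pts = clean_small_wing
    regions = extract_intervein_regions(
        class_map_working(truth), img.shape
    )
    total = 0
    for region in regions:
        done = intervein_density(img, region, 10)
        n_true = int(
            truth.region_labels[
                np.round(truth.coords[:, 0]).astype(int),
                np.round(truth.coords[:, 1]).astype(int),
            ].astype(bool).sum()
        )
        inside = region.mask_fullres[
            np.round(truth.coords[:, 0]).astype(int),
            np.round(truth.coords[:, 1]).astype(int),
        ]
        assert done.trichome_count == int(inside.sum())
        assert done.density == done.trichome_count / done.area_px2
        total += done.trichome_count
    # regions exclude veins/margins: region counts cannot exceed the whole image
    assert total <= len(pts)


def test_empty_region_mask_rejected(clean_small_wing):
    img, truth, _ = clean_small_wing
    regions = extract_intervein_regions(class_map_working(truth), img.shape)
    import dataclasses

    hollow = dataclasses.replace(
        regions[0], mask_fullres=np.zeros(img.shape, bool)
    )
    with pytest.raises(InputError):
        intervein_density(img, hollow, 10)
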