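"""Synthetic wing generator: determinism, ground-truth contracts, failure classes."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import small_params
from wingmorph.errors import GeneratorError, InputError
from wingmorph.image import Micrograph
from wingmorph.maxima import find_maxima
from wingmorph.synthetic import (
    WingParams,
    evaluate_detection,
    generate_wing,
    region_polygon,
    scribbles_from_truth,
    select_audit_squares,
)


def test_same_seed_is_bit_identical():
    a_img, a_truth = generate_wing(small_params(), seed=7)
    b_img, b_truth = generate_wing(small_params(), seed=7)
    assert np.array_equal(a_img.pixels, b_img.pixels)
    assert np.array_equal(a_truth.coords, b_truth.coords)
    c_img, _ = generate_wing(small_params(), seed=8)
    assert not np.array_equal(a_img.pixels, c_img.pixels)


def test_masks_are_disjoint_and_tile_the_image(clean_small_wing):
    _, truth, _ = clean_small_wing
    total = (
        truth.vein_mask.astype(int)
        + truth.intervein_mask.astype(int)
        + truth.background_mask.astype(int)
    )
    assert np.all(total == 1)
    assert 6 <= truth.n_regions <= 8


def test_every_trichome_base_lies_in_intervein(clean_small_wing):
    _, truth, _ = clean_small_wing
    rr = np.round(truth.coords[:, 0]).astype(int)
    cc = np.round(truth.coords[:, 1]).astype(int)
    assert truth.intervein_mask[rr, cc].all()
    assert np.all(truth.region_of == truth.region_labels[rr, cc])


def test_trichomes_respect_hard_core_spacing(clean_small_wing):
    _, truth, _ = clean_small_wing
    tree = cKDTree(truth.coords)
    assert len(tree.query_pairs(truth.params.trichome_diameter)) == 0


def test_realized_counts_follow_requested_rates(default_wing):
    """Per-compartment counts within the Poisson band of rate x area."""
    _, truth = default_wing
    for compartment in ("anterior", "posterior"):
        rids = [r for r, c in truth.region_compartment.items() if c == compartment]
        if not rids:
            continue
        area = np.isin(truth.region_labels, rids).sum()
        rate = truth.region_rates[rids[0]]
        expected = rate * area
        realized = np.isin(truth.region_of, rids).sum()
        assert abs(realized - expected) <= 4 * np.sqrt(expected), compartment


def test_clean_mode_recovers_every_trichome():
    for seed in (1, 2):
        img, truth = generate_wing(small_params().clean(), seed=seed)
        pts = find_maxima(img, 10)
        m = evaluate_detection(pts, truth, 2.0)
        assert m.recall == 1.0, seed


def test_rate_ratio_is_recovered_in_realized_counts():
    img, truth = generate_wing(
        WingParams(shape=(772, 1040), rate_ratio=0.5), seed=11
    )
    post = [r for r, c in truth.region_compartment.items() if c == "posterior"]
    ant = [r for r, c in truth.region_compartment.items() if c == "anterior"]
    n_post = np.isin(truth.region_of, post).sum()
    n_ant = np.isin(truth.region_of, ant).sum()
    a_post = np.isin(truth.region_labels, post).sum()
    a_ant = np.isin(truth.region_labels, ant).sum()
    assert n_post + n_ant >= 2000
    ratio = (n_post / a_post) / (n_ant / a_ant)
    assert ratio == pytest.approx(0.5, abs=0.05)


def test_coincident_pair_yields_at_most_one_detection():
    """Two bases closer than their diameter merge into a single spot."""
    arr = np.full((40, 40), 225.0)
    yy, xx = np.mgrid[0:40, 0:40].astype(float)
    for r, c in ((20.0, 20.0), (21.5, 21.8)):  # sub-diameter offset
        arr -= 35 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * (5 / 3) ** 2))
    img = Micrograph(np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8))
    assert len(find_maxima(img, 10)) == 1


def test_recall_degrades_monotonically_with_failure_fractions(degradation_grid):
    fractions, grid = degradation_grid
    assert grid[0, 0] > 0.99  # no failure classes -> near-perfect recall
    for i in range(3):
        assert grid[i, 0] >= grid[i, 1] >= grid[i, 2]  # small-faint axis
        assert grid[0, i] >= grid[1, i] >= grid[2, i]  # coincident axis


def test_infeasible_packing_rejected():
    with pytest.raises(GeneratorError):
        generate_wing(small_params(trichome_rate=0.05), seed=0)


def test_too_small_dims_rejected():
    with pytest.raises(InputError):
        generate_wing(WingParams(shape=(100, 100)), seed=0)


# ----------------------------------------------------------- evaluation op


def test_evaluate_exact_match_and_one_missing():
    truth = np.array([[10.0, 10.0], [20.0, 30.0], [35.0, 5.0]])
    m = evaluate_detection(truth.copy(), truth, 4.0)
    assert (m.recall, m.precision) == (1.0, 1.0)
    m = evaluate_detection(truth[:-1].copy(), truth, 4.0)
    assert m.missed == 1 and m.spurious == 0


def test_evaluate_respects_matching_radius():
    rng = np.random.default_rng(19)
    # well-separated truths so a 3.5 px displacement cannot cross-match
    gy, gx = np.mgrid[0:6, 0:6]
    truth = np.stack([40.0 + 60 * gy.ravel(), 40.0 + 60 * gx.ravel()], axis=1)
    truth += rng.uniform(-2, 2, truth.shape)
    angle = rng.uniform(0, 2 * np.pi, len(truth))
    offsets = np.stack([np.sin(angle), np.cos(angle)], axis=1)
    within = truth + 3.5 * offsets
    beyond = truth + 25.0 * offsets
    assert evaluate_detection(within, truth, 4.0).recall == 1.0
    assert evaluate_detection(beyond, truth, 4.0).recall == 0.0


def test_greedy_matching_uses_each_point_once():
    truth = np.array([[10.0, 10.0], [10.0, 12.0]])
    pred = np.array([[10.0, 11.0]])  # one detection between two truths
    m = evaluate_detection(pred, truth, 4.0)
    assert m.matched == 1 and m.missed == 1 and m.spurious == 0


# ----------------------------------------------------------- audit helpers


def test_audit_squares_sit_inside_distinct_regions(default_wing):
    _, truth = default_wing
    centers = select_audit_squares(truth, n=5, side=75)
    assert len(centers) == 5
    regions = set()
    for r, c in centers:
        rid = truth.region_labels[r, c]
        assert rid > 0
        regions.add(rid)
        block = truth.region_labels[r - 37 : r + 38, c - 37 : c + 38]
        assert block.shape == (75, 75) and np.all(block == rid)
    assert len(regions) == 5


def test_region_polygon_outlines_its_region(clean_small_wing):
    _, truth, _ = clean_small_wing
    verts = region_polygon(truth, region_id=2)
    from wingmorph.roi import polygon_roi

    roi = polygon_roi(verts, truth.region_labels.shape)
    in_region = truth.region_of == 2
    contained = roi.contains(truth.coords[in_region])
    assert contained.all()


def test_scribbles_balanced_and_on_pure_classes(clean_small_wing):
    _, truth, _ = clean_small_wing
    from wingmorph.synthetic import class_map_working

    labels = scribbles_from_truth(truth, n_per_class=120, seed=1)
    cmap = class_map_working(truth)
    for cls in (1, 2, 3):
        sel = labels == cls
        assert sel.sum() == 120
        assert np.all(cmap[sel] == cls - 1)
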