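"""Square/polygon ROIs, shoelace areas, counting and density ratios."""

import numpy as np
import pytest

from wingmorph.errors import ComputationError, InputError
from wingmorph.image import Micrograph, resize
from wingmorph.roi import (
    PixelCoord,
    Roi,
    count_in_polygon,
    count_in_square,
    density_ratio,
    load_roi,
    measure_density,
    polygon_area,
    polygon_roi,
    save_roi,
    square_roi,
)
from wingmorph.synthetic import region_polygon


def _spot_image(h, w, spots):
    arr = np.full((h, w), 230, np.uint8)
    for r, c in spots:
        arr[r, c] = 100
    return Micrograph(arr)


# ------------------------------------------------------------- square ROIs


def test_square_preset_geometry():
    roi = square_roi(PixelCoord(100, 100), 75, (2080, 1544))
    assert roi.square_bounds() == (63, 137, 63, 137)
    assert roi.area_px2 == 5625
    assert square_roi((200, 200), 150, (2080, 1544)).area_px2 == 22500


def test_square_out_of_bounds_suggests_center():
    with pytest.raises(InputError, match=r"nearest valid center is \(37,37\)"):
        square_roi(PixelCoord(0, 0), 75, (2080, 1544))


def test_single_pixel_square():
    roi = square_roi((50, 50), 1, (100, 100))
    assert roi.square_bounds() == (50, 50, 50, 50)
    assert roi.area_px2 == 1


def test_even_square_extends_down_right():
    roi = square_roi((10, 10), 4, (100, 100))
    assert roi.square_bounds() == (9, 12, 9, 12)


# ---------------------------------------------------------------- polygons


def test_polygon_area_examples():
    assert polygon_area([(0, 0), (10, 0), (10, 10), (0, 10)]) == 100
    assert polygon_area([(0, 0), (4, 0), (0, 3)]) == 6
    # orientation independence
    assert polygon_area([(0, 10), (10, 10), (10, 0), (0, 0)]) == 100


def test_polygon_area_rejects_degenerate_and_self_intersecting():
    with pytest.raises(InputError):
        polygon_area([(0, 0), (1, 1)])
    with pytest.raises(InputError):
        polygon_area([(0, 0), (10, 10), (10, 0), (0, 10)])  # bow-tie


def test_shoelace_matches_shapely_on_random_star_polygons():
    """Dual route: hand-written shoelace vs shapely's exact area."""
    from shapely.geometry import Polygon

    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(3, 12))
        # angles strewn once around the circle -> star-shaped, hence simple
        angles = 2 * np.pi * (np.arange(n) + rng.uniform(0, 1, n)) / n
        radii = rng.uniform(2, 30, n)
        verts = np.stack(
            [50 + radii * np.cos(angles), 50 + radii * np.sin(angles)], axis=1
        )
        assert polygon_area(verts) == pytest.approx(Polygon(verts).area, rel=1e-12)


def test_shoelace_matches_monte_carlo_area():
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = int(rng.integers(4, 9))
        angles = 2 * np.pi * (np.arange(n) + rng.uniform(0, 1, n)) / n
        radii = rng.uniform(5, 40, n)
        verts = np.stack(
            [50 + radii * np.cos(angles), 50 + radii * np.sin(angles)], axis=1
        )
        area = polygon_area(verts)
        samples = rng.uniform(0, 100, size=(200_000, 2))
        roi = polygon_roi(np.asarray(verts))
        hits = roi.contains(samples[:, ::-1])  # (col,row) -> (row,col)
        mc = hits.mean() * 100 * 100
        assert mc == pytest.approx(area, rel=0.015)


# ------------------------------------------------------- counting / density


def test_empty_polygon_counts_zero():
    img = _spot_image(40, 40, [])
    res = count_in_polygon(img, [(5, 5), (30, 5), (30, 30), (5, 30)])
    assert res.trichome_count == 0
    assert res.density == 0


def test_density_times_area_equals_count_exactly():
    img = _spot_image(60, 60, [(10, 10), (20, 30), (40, 40), (41, 12)])
    res = count_in_polygon(img, [(2.5, 2.5), (55.5, 2.5), (55.5, 55.5), (2.5, 55.5)])
    assert res.trichome_count == 4
    assert res.density * res.area_px2 == res.trichome_count


def test_polygon_count_is_additive_over_a_partition():
    spots = [(10, 10), (12, 40), (30, 20), (44, 44), (25, 50), (50, 8)]
    img = _spot_image(60, 60, spots)
    # parent square split along the non-integer column 28.5: no detection can
    # sit on the shared edge
    parent = [(2.0, 2.0), (55.0, 2.0), (55.0, 55.0), (2.0, 55.0)]
    left = [(2.0, 2.0), (28.5, 2.0), (28.5, 55.0), (2.0, 55.0)]
    right = [(28.5, 2.0), (55.0, 2.0), (55.0, 55.0), (28.5, 55.0)]
    total = count_in_polygon(img, parent).trichome_count
    parts = (
        count_in_polygon(img, left).trichome_count
        + count_in_polygon(img, right).trichome_count
    )
    assert total == len(spots)
    assert parts == total


def test_polygon_outside_image_rejected():
    img = _spot_image(30, 30, [])
    with pytest.raises(InputError):
        count_in_polygon(img, [(5, 5), (40, 5), (40, 25), (5, 25)])


def test_boundary_points_count_as_inside():
    roi = polygon_roi([(10.0, 10.0), (20.0, 10.0), (20.0, 20.0), (10.0, 20.0)])
    pts = np.array([[10, 15], [15, 20], [10, 10], [15, 15], [9, 15], [21, 15]])
    assert roi.contains(pts).tolist() == [True, True, True, True, False, False]


def test_density_ratio_identity_and_zero_denominator():
    img = _spot_image(60, 60, [(10, 10), (40, 40)])
    poly = [(2.0, 2.0), (55.0, 2.0), (55.0, 55.0), (2.0, 55.0)]
    a = count_in_polygon(img, poly)
    assert density_ratio(a, a) == 1.0
    empty = count_in_polygon(_spot_image(60, 60, []), poly)
    with pytest.raises(ComputationError):
        density_ratio(a, empty)


def test_repeat_measurements_are_identical(clean_small_wing):
    img, truth, _ = clean_small_wing
    # a deterministic interior point that can hold a 51 px square
    from wingmorph.synthetic import select_audit_squares

    center = select_audit_squares(truth, n=1, side=51)[0]
    results = [count_in_square(img, center, 51, 10) for _ in range(3)]
    assert len({r.trichome_count for r in results}) == 1
    assert len({r.density for r in results}) == 1


def test_clean_wing_polygon_count_matches_ground_truth(clean_small_wing):
    img, truth, pts = clean_small_wing
    verts = region_polygon(truth, region_id=1)
    res = count_in_polygon(img, verts, 10)
    in_region = truth.region_of == 1
    assert res.trichome_count == int(in_region.sum())


def test_doubling_resolution_quarters_density(clean_small_wing):
    img, truth, _ = clean_small_wing
    verts = region_polygon(truth, region_id=1)
    res1 = count_in_polygon(img, verts, 10)
    big = resize(img, img.width * 2, img.height * 2)
    # pixel-center mapping of a 2x bilinear upscale: x -> 2x + 0.5
    res2 = count_in_polygon(big, 2.0 * verts + 0.5, 10)
    assert res2.trichome_count == res1.trichome_count
    assert res2.area_px2 == pytest.approx(4 * res1.area_px2)
    assert res2.density == pytest.approx(res1.density / 4)


def test_roi_json_round_trip(tmp_path):
    sq = Roi(kind="square", center=PixelCoord(10, 12), side=75)
    save_roi(sq, tmp_path / "sq.json")
    again = load_roi(tmp_path / "sq.json")
    assert again.center == PixelCoord(10, 12) and again.side == 75
    poly = polygon_roi([(0.0, 0.0), (4.0, 0.0), (0.0, 3.0)])
    save_roi(poly, tmp_path / "poly.json")
    again = load_roi(tmp_path / "poly.json")
    assert np.allclose(again.vertices, poly.vertices)
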