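"""Detect trichomes on a synthetic wing and measure square/polygon densities.

Generates a clean synthetic wing (no noise, no failure classes), detects
every trichome base by noise-tolerance maxima finding on the inverted
image, then measures trichome density in a 75 px square and in a polygon
tracing one whole intervein region — the two ways a fly geneticist samples
cell density on a wing.
"""

from wingmorph import (
    WingParams,
    count_in_polygon,
    count_in_square,
    find_maxima,
    generate_wing,
    region_polygon,
    select_audit_squares,
)

img, truth = generate_wing(WingParams(shape=(772, 1040)).clean(), seed=1)
print(f"synthetic wing: {img.width}x{img.height}, "
      f"{truth.n_trichomes} true trichomes in {truth.n_regions} intervein regions")

points = find_maxima(img, noise_tolerance=10)
print(f"detected {len(points)} spots at noise tolerance 10")

center = select_audit_squares(truth, n=1, side=75)[0]
sq = count_in_square(img, center, side=75, noise_tolerance=10)
print(f"75 px square at {center}: {sq.trichome_count} trichomes / "
      f"{sq.area_px2:.0f} px^2 = {sq.density:.5f} per px^2")

verts = region_polygon(truth, region_id=1)
poly = count_in_polygon(img, verts, noise_tolerance=10)
true_n = int((truth.region_of == 1).sum())
print(f"largest intervein region: {poly.trichome_count} trichomes counted "
      f"({true_n} placed by the generator), area {poly.area_px2:.0f} px^2, "
      f"density {poly.density:.5f} per px^2")

# density * area always reproduces the raw count exactly
assert poly.density * poly.area_px2 == poly.trichome_count
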