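"""Recover a known posterior/anterior density ratio.

Misexpressing a cell-cycle brake in the posterior compartment lowers its
cell (trichome) density relative to the anterior internal control.  Here
the generator plays the transgene: the posterior compartment is rendered at
half the anterior trichome rate, and the polygon-density pipeline should
measure a posterior/anterior ratio near 0.5.
"""

from wingmorph import (
    WingParams,
    density_ratio,
    generate_wing,
    measure_density,
    polygon_roi,
    region_polygon,
)

img, truth = generate_wing(WingParams(rate_ratio=0.5).clean(), seed=11)

results = {}
for compartment in ("anterior", "posterior"):
    rid = next(
        r for r in range(1, truth.n_regions + 1)
        if truth.region_compartment[r] == compartment
    )  # regions are sorted by area, so this is the compartment's largest
    roi = polygon_roi(region_polygon(truth, rid), img.shape)
    res = measure_density(img, roi, noise_tolerance=10)
    results[compartment] = res
    print(f"{compartment}: region {rid}, {res.trichome_count} trichomes, "
          f"area {res.area_px2:.0f} px^2, density {res.density:.5f} per px^2")

ratio = density_ratio(results["posterior"], results["anterior"])
print(f"posterior/anterior density ratio: {ratio:.3f} (generated at 0.5)")
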