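"""Render the two heat-map products for one synthetic wing.

The spacing heat map colors each watershed cell (one per trichome) by its
area — sparse, low-density patches render hot; the area heat map colors
each segmented intervein region by its size.  Both are written as PNG with
a calibrated legend, plus a CSV of the values behind the colors.
"""

import os

import numpy as np

from wingmorph import (
    HeatmapSpec,
    class_map_working,
    extract_intervein_regions,
    find_maxima,
    generate_wing,
    render_area_heatmap,
    render_spacing_heatmap,
    save_micrograph,
    trichome_spacing_cells,
)
from wingmorph.heatmap import normalize_values, write_value_table

outdir = "example_output"
os.makedirs(outdir, exist_ok=True)

img, truth = generate_wing(seed=1)
points = find_maxima(img, noise_tolerance=10)
cells = trichome_spacing_cells(img, 10, points=points)
print(f"{cells.n_cells} spacing cells; "
      f"median cell area {np.median(cells.cell_areas[1:]):.0f} px^2")

spacing_spec = HeatmapSpec("trichome_spacing", value_min=0, value_max=300)
save_micrograph(render_spacing_heatmap(cells, spacing_spec),
                os.path.join(outdir, "spacing_heatmap.png"))

# area heat map from the ground-truth class map (or a trained model's output)
regions = extract_intervein_regions(class_map_working(truth), img.shape)
area_spec = HeatmapSpec("intervein_area")  # auto-scaled range
save_micrograph(render_area_heatmap(regions, area_spec, img.shape),
                os.path.join(outdir, "area_heatmap.png"))

values = np.array([r.area_px2 for r in regions])
norm = np.clip(normalize_values(values, area_spec), 0, 1)
write_value_table(os.path.join(outdir, "area_values.csv"),
                  [r.region_id for r in regions], values, norm)
print(f"region areas {values.min():.0f}..{values.max():.0f} px^2 "
      f"-> heat maps written to {outdir}/")
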