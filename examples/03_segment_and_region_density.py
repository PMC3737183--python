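"""Train the vein classifier, segment a held-out wing, measure every region.

The classifier learns vein / intervein / background from 200 scribbled
pixels per class on one wing, then segments a wing it has never seen.
Particle analysis of the intervein class yields the region table the
intervein-density measurements run on.
"""

from wingmorph import (
    class_map_working,
    extract_intervein_regions,
    generate_wing,
    intervein_density,
    resize,
    scribbles_from_truth,
    segment_wing,
    train_classifier,
)
import numpy as np

train_img, train_truth = generate_wing(seed=42)
work = resize(train_img, 512, 380)
scribbles = scribbles_from_truth(train_truth, n_per_class=200, seed=42)
model = train_classifier(work, scribbles, n_trees=100, seed=42)
print(f"classifier trained; training-pixel accuracy {model.train_accuracy:.3f}")

img, truth = generate_wing(seed=5)  # held-out wing
seg = segment_wing(img, model)
gt = class_map_working(truth)
iou = ((seg.class_map == 1) & (gt == 1)).sum() / ((seg.class_map == 1) | (gt == 1)).sum()
print(f"held-out wing: intervein IoU vs ground truth = {iou:.3f}")

regions = extract_intervein_regions(seg.class_map, img.shape)
print(f"{len(regions)} intervein regions (generator drew {truth.n_regions}):")
for region in regions:
    done = intervein_density(img, region, noise_tolerance=10)
    print(f"  region {done.region_id}: area {done.area_px2:9.0f} px^2, "
          f"count {done.trichome_count:5d}, density {done.density:.5f} per px^2")
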