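"""Audit the detector against ground truth under realistic failure modes.

Renders a wing with the two classes that defeat prominence detection on
real micrographs — dorsal/ventral trichome pairs sharing a base (2%) and
undersized faint trichomes (3%) — plus pixel noise, then matches detections
to the ground truth within 4 px and reports recall, miss rate and
precision, the automatic version of a manual recount audit.
"""

from wingmorph import WingParams, evaluate_detection, find_maxima, generate_wing

img, truth = generate_wing(WingParams(dirt_count=0), seed=1)
points = find_maxima(img, noise_tolerance=10)
metrics = evaluate_detection(points, truth, radius=4.0)

print(f"{truth.n_trichomes} true trichomes, {len(points)} detections")
print(f"matched {metrics.matched}, missed {metrics.missed} "
      f"({100 * metrics.missed / metrics.n_truth:.1f}%), "
      f"spurious {metrics.spurious}")
print(f"recall {metrics.recall:.3f}")

missed_faint = int(truth.small_faint[~metrics.truth_matched].sum())
missed_pair = int(truth.coincident[~metrics.truth_matched].sum())
print(f"misses by class: {missed_pair} coincident-pair members, "
      f"{missed_faint} small-faint, "
      f"{metrics.missed - missed_faint - missed_pair} other")
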