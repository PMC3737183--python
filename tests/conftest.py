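"""Shared fixtures: synthetic wings at the study conditions.

Full-scale (2080 x 1544) wings are expensive, so they are session-scoped
and shared between the unit suite and the acceptance suite; small wings
(544 x 400, same trichome/vein scale as a lower-magnification capture) are
used where only structure matters.
"""

import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # for the oracle module

from wingmorph.image import resize
from wingmorph.maxima import find_maxima
from wingmorph.segmentation import train_classifier
from wingmorph.synthetic import (
    WingParams,
    generate_wing,
    scribbles_from_truth,
)

SMALL_SHAPE = (400, 544)


def small_params(**overrides) -> WingParams:
    return WingParams(shape=SMALL_SHAPE, **overrides)


@pytest.fixture(scope="session")
def default_wing():
    """Full-scale wing at the default study conditions, seed 1."""
    return generate_wing(seed=1)


@pytest.fixture(scope="session")
def audit_wings():
    """Three full-scale wings at the detection-audit conditions.

    Coincident 2%, small-faint 3%, noise sigma 4, no dirt; seeds 1-3.
    Yields (img, truth, detections) triples.
    """
    out = []
    for seed in (1, 2, 3):
        img, truth = generate_wing(WingParams(dirt_count=0), seed=seed)
        pts = find_maxima(img, 10)
        out.append((img, truth, pts))
    return out


@pytest.fixture(scope="session")
def clean_small_wing():
    """Small wing with failure classes, noise and dirt disabled (seed 3)."""
    img, truth = generate_wing(small_params().clean(), seed=3)
    return img, truth, find_maxima(img, 10)


@pytest.fixture(scope="session")
def trained_model():
    """Classifier trained on a full-scale wing (seed 42) via truth scribbles."""
    img, truth = generate_wing(seed=42)
    work = resize(img, 512, 380)
    labels = scribbles_from_truth(truth, n_per_class=200, seed=42)
    model = train_classifier(work, labels, n_trees=100, seed=42)
    return img, truth, labels, model


@pytest.fixture(scope="session")
def heldout_wing():
    """Full-scale wing (seed 5) never seen by the trained classifier."""
    return generate_wing(seed=5)


@pytest.fixture(scope="session")
def degradation_grid():
    """Mean recall over a 3x3 grid of failure-class fractions, 3 seeds each.

    Returns (fractions, recall_grid) where recall_grid[i, j] is the mean
    recall at coincident_fraction=fractions[i], small_faint_fraction=
    fractions[j] on small wings.
    """
    from wingmorph.synthetic import evaluate_detection

    fractions = (0.0, 0.06, 0.12)
    grid = np.zeros((3, 3))
    for i, fc in enumerate(fractions):
        for j, fs in enumerate(fractions):
            recalls = []
            for seed in (1, 2, 3):
                img, truth = generate_wing(
                    small_params(
                        coincident_fraction=fc,
                        small_faint_fraction=fs,
                        dirt_count=0,
                    ),
                    seed=seed,
                )
                pts = find_maxima(img, 10)
                recalls.append(evaluate_detection(pts, truth, 4.0).recall)
            grid[i, j] = np.mean(recalls)
    return fractions, grid
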