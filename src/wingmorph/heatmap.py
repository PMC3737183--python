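"""Heat-map rendering of intervein areas and trichome spacing cells.

Two visual summaries of a wing: color every intervein region by its area
(tissue-size map) or every watershed spacing cell by its area (the inverse
of local trichome density — sparse regions render "hotter").  Values are
normalized onto [value_min, value_max] and mapped through a fire-like ramp
(black -> blue -> red -> orange -> yellow -> white, monotone in lightness);
the range defaults to the per-image min/max and can be pinned for
cross-genotype comparisons.  Color assignment is a pure function of
(value, spec), so re-rendering is bit-identical.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .maxima import SpacingCells
from .segmentation import InterveinRegion

__all__ = [
    "HeatmapSpec",
    "fire_colormap",
    "normalize_values",
    "render_area_heatmap",
    "render_spacing_heatmap",
    "write_value_table",
]

# control points of the fire-like ramp (position in [0,1] -> RGB)
_FIRE_STOPS = np.array([0.0, 0.12, 0.28, 0.45, 0.62, 0.8, 1.0])
_FIRE_RGB = np.array(
    [
        [0, 0, 0],
        [0, 20, 140],
        [120, 10, 130],
        [220, 50, 20],
        [250, 130, 0],
        [255, 220, 40],
        [255, 255, 255],
    ],
    dtype=np.float64,
)

_LEGEND_WIDTH = 110
_BAR_WIDTH = 24


def fire_colormap(values: np.ndarray) -> np.ndarray:
    """Map values in [0, 1] (clamped) to RGB through the fire-like ramp."""
    v = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0)
    out = np.empty(v.shape + (3,), dtype=np.uint8)
    for ch in range(3):
        out[..., ch] = np.floor(
            np.interp(v, _FIRE_STOPS, _FIRE_RGB[:, ch]) + 0.5
        ).astype(np.uint8)
    return out


@dataclass
class HeatmapSpec:
    """Rendering parameters: mode, value range and colormap.

    ``value_min``/``value_max`` left as None auto-scale to the observed
    min/max of the rendered values (the zero-config default); pin them to
    compare wings on a shared scale.
    """

    mode: str  # "intervein_area" | "trichome_spacing"
    value_min: float | None = None
    value_max: float | None = None
    colormap: str = "fire"
    legend: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("intervein_area", "trichome_spacing"):
            raise InputError(f"unknown heatmap mode {self.mode!r}")
        if self.colormap != "fire":
            raise InputError(f"unknown colormap {self.colormap!r}")
        if (
            self.value_min is not None
            and self.value_max is not None
            and not (self.value_min < self.value_max)
        ):
            raise InputError("heatmap range requires value_min < value_max")

    def resolved_range(self, values: np.ndarray) -> tuple[float, float]:
        lo = float(np.min(values)) if self.value_min is None else self.value_min
        hi = float(np.max(values)) if self.value_max is None else self.value_max
        if lo >= hi:  # all observed values identical under auto-scale
            lo, hi = lo - 0.5, hi + 0.5
        return lo, hi


def normalize_values(values: np.ndarray, spec: HeatmapSpec) -> np.ndarray:
    """(v - value_min) / (value_max - value_min), before clamping."""
    lo, hi = spec.resolved_range(values)
    return (np.asarray(values, dtype=np.float64) - lo) / (hi - lo)


def render_area_heatmap(
    regions: list[InterveinRegion],
    spec: HeatmapSpec | None = None,
    dims: tuple[int, int] | None = None,
) -> np.ndarray:
    """RGB image with every intervein region colored by its area.

    ``dims`` defaults to the regions' full-resolution mask shape.
    Non-region pixels are black; an optional legend bar labeled with the
    exact value_min/value_max is rendered in a right margin.
    """
    spec = spec or HeatmapSpec(mode="intervein_area")
    if spec.mode != "intervein_area":
        raise InputError("spec.mode must be 'intervein_area'")
    if not regions:
        raise InputError("need at least one intervein region to render")
    dims = dims or regions[0].mask_fullres.shape
    values = np.array([r.area_px2 for r in regions], dtype=np.float64)
    norm = np.clip(normalize_values(values, spec), 0.0, 1.0)
    colors = fire_colormap(norm)
    canvas = np.zeros(dims + (3,), dtype=np.uint8)
    for r, color in zip(regions, colors):
        if r.mask_fullres.shape != dims:
            raise InputError("region mask does not match the requested dims")
        canvas[r.mask_fullres] = color
    if spec.legend:
        canvas = _attach_legend(canvas, *spec.resolved_range(values))
    return canvas


def render_spacing_heatmap(cells: SpacingCells, spec: HeatmapSpec | None = None) -> np.ndarray:
    """RGB image with every spacing cell colored by its area, boundaries black."""
    spec = spec or HeatmapSpec(mode="trichome_spacing")
    if spec.mode != "trichome_spacing":
        raise InputError("spec.mode must be 'trichome_spacing'")
    if cells.n_cells < 1:
        raise InputError("spacing-cell partition contains no cells")
    areas = cells.cell_areas.astype(np.float64)
    norm = np.zeros_like(areas)
    norm[1:] = np.clip(normalize_values(areas[1:], spec), 0.0, 1.0)
    lut = fire_colormap(norm)
    lut[0] = (0, 0, 0)  # boundary lines
    canvas = lut[cells.label_map]
    if spec.legend:
        canvas = _attach_legend(canvas, *spec.resolved_range(areas[1:]))
    return canvas


def format_legend_value(v: float) -> str:
    """Exact short label for a legend endpoint."""
    return f"{v:g}"


def _attach_legend(canvas: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Append a right margin holding the color bar and min/max labels."""
    from PIL import Image, ImageDraw

    h, w = canvas.shape[:2]
    out = np.zeros((h, w + _LEGEND_WIDTH, 3), dtype=np.uint8)
    out[:, :w] = canvas
    pad = max(8, h // 20)
    bar_h = h - 2 * pad
    ramp = fire_colormap(np.linspace(1.0, 0.0, bar_h))
    out[pad : pad + bar_h, w + 8 : w + 8 + _BAR_WIDTH] = ramp[:, None, :]
    im = Image.fromarray(out)
    draw = ImageDraw.Draw(im)
    x = w + 8 + _BAR_WIDTH + 4
    draw.text((x, pad - 4), format_legend_value(hi), fill=(255, 255, 255))
    draw.text((x, pad + bar_h - 8), format_legend_value(lo), fill=(255, 255, 255))
    return np.asarray(im)


def write_value_table(path: str | os.PathLike, labels, values, normalized) -> None:
    """CSV dump of the values behind a heat map."""
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "value", "normalized_value"])
        for lab, v, nv in zip(labels, values, normalized):
            writer.writerow([lab, repr(float(v)), repr(float(nv))])
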