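"""Fixed-grid kernel segmentation on the cropped tray.

The staged tray is a 10 x 10 grid of cells on a blue background.  Because
staging is rigid, segmentation needs no learned model: inside each fixed
270 x 270 px cell box, a pixel belongs to the tray iff r - b <= -40 (the
blue tray has far more blue than red; kernels are warm-colored), and every
other pixel is kernel.  Cells with fewer than 500 kernel pixels are treated
as empty — that cutoff separates dust and debris from true kernels.

Per non-empty cell the module records the pixel count, the mean, and the
10/25/50/75/90th percentiles of R, G, B and L*, a*, b*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .color_model import rgb_to_lab

__all__ = [
    "TRAY_RULE_THRESHOLD",
    "MIN_KERNEL_PIXELS",
    "CHANNELS",
    "PERCENTILES",
    "STAT_NAMES",
    "CellBox",
    "CellGrid",
    "KernelRecord",
    "load_grid",
    "default_grid",
    "tray_mask",
    "segment_cell",
    "segment_image",
    "records_to_frame",
]

#: A pixel is tray iff r - b <= this value (8-bit channels).
TRAY_RULE_THRESHOLD = -40

#: Minimum kernel-pixel count for a cell to hold a true kernel.
MIN_KERNEL_PIXELS = 500

CHANNELS = ("R", "G", "B", "L", "a", "b")
PERCENTILES = (10, 25, 50, 75, 90)

#: Canonical statistic names, e.g. "R_mean", "L_p50".
STAT_NAMES = tuple(
    f"{ch}_{stat}" for ch in CHANNELS for stat in ["mean"] + [f"p{q}" for q in PERCENTILES]
)


@dataclass(frozen=True)
class CellBox:
    """One grid cell: half-open box [x, x+side) x [y, y+side) on the crop."""

    row: int
    col: int
    x: int
    y: int
    side: int = 270


class GridValidationError(ValueError):
    pass


@dataclass
class CellGrid:
    """The 100 cell boxes of a tray, in row-major order."""

    boxes: list

    def __post_init__(self):
        self.validate()

    def __iter__(self):
        return iter(self.boxes)

    def __len__(self):
        return len(self.boxes)

    def validate(self, tray_side: Optional[int] = None) -> None:
        if len(self.boxes) != 100:
            raise GridValidationError(f"expected 100 cells, got {len(self.boxes)}")
        keys = {(b.row, b.col) for b in self.boxes}
        if len(keys) != 100:
            raise GridValidationError("duplicate (row, col) cell identities")
        for b in self.boxes:
            if b.x < 0 or b.y < 0 or b.side <= 0:
                raise GridValidationError(f"cell {(b.row, b.col)} out of bounds")
            if tray_side is not None and (b.x + b.side > tray_side or b.y + b.side > tray_side):
                raise GridValidationError(
                    f"cell {(b.row, b.col)} exceeds tray side {tray_side}"
                )
        # pairwise overlap (boxes are axis-aligned)
        bs = sorted(self.boxes, key=lambda b: (b.y, b.x))
        for i, p in enumerate(bs):
            for q in bs[i + 1 :]:
                if q.y >= p.y + p.side:
                    break
                if p.x < q.x + q.side and q.x < p.x + p.side:
                    raise GridValidationError(
                        f"cells {(p.row, p.col)} and {(q.row, q.col)} overlap"
                    )


def default_grid(tray_side: int = 2780, side: Optional[int] = None) -> CellGrid:
    """Parametric 10 x 10 grid centered in each pitch interval.

    With the default 2780 px tray the pitch is 278 px, the box side 270 px
    and the first box origin (4, 4).
    """
    pitch = tray_side // 10
    if side is None:
        side = pitch - 8
    origin = (pitch - side) // 2
    boxes = [
        CellBox(row=r, col=c, x=origin + c * pitch, y=origin + r * pitch, side=side)
        for r in range(10)
        for c in range(10)
    ]
    return CellGrid(boxes)


def load_grid(config) -> CellGrid:
    """Build a :class:`CellGrid` from a config dict or JSON file path.

    Two layouts are accepted: an explicit ``{"cells": [{row, col, x, y,
    side}, ...]}`` list of 100 boxes, or a parametric ``{"origin_x",
    "origin_y", "pitch_x", "pitch_y", "side"}`` 10 x 10 layout.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    if "cells" in config:
        boxes = [
            CellBox(int(c["row"]), int(c["col"]), int(c["x"]), int(c["y"]), int(c.get("side", 270)))
            for c in config["cells"]
        ]
    else:
        ox, oy = int(config["origin_x"]), int(config["origin_y"])
        px, py = int(config["pitch_x"]), int(config["pitch_y"])
        side = int(config["side"])
        boxes = [
            CellBox(row=r, col=c, x=ox + c * px, y=oy + r * py, side=side)
            for r in range(10)
            for c in range(10)
        ]
    return CellGrid(boxes)


def tray_mask(pixels: np.ndarray, threshold: int = TRAY_RULE_THRESHOLD) -> np.ndarray:
    """Boolean mask, true where a pixel is tray (r - b <= threshold).

    ``pixels`` is any (..., 3) 8-bit RGB array.  The kernel mask is the
    complement.
    """
    px = np.asarray(pixels)
    diff = px[..., 0].astype(np.int16) - px[..., 2].astype(np.int16)
    return diff <= threshold


@dataclass
class KernelRecord:
    """Measurements of one kernel half (one cell of one tray image)."""

    image_id: str
    row: int
    col: int
    n_pixels: int
    is_empty: bool
    stats: dict = field(default_factory=dict)
    blank_flag: Optional[bool] = None

    @property
    def cell(self):
        return (self.row, self.col)

    def validate(self) -> None:
        if self.is_empty:
            if self.stats:
                raise ValueError("empty record must not carry statistics")
            return
        for ch in CHANNELS:
            p = [self.stats[f"{ch}_p{q}"] for q in PERCENTILES]
            if any(p[i] > p[i + 1] for i in range(len(p) - 1)):
                raise ValueError(f"percentiles of {ch} are not monotone")


def _pixel_stats(rgb_pixels: np.ndarray, percentile_method: str) -> dict:
    """Means and percentiles of RGB and CIELAB over an (n, 3) pixel array."""
    r = rgb_pixels[:, 0].astype(float)
    g = rgb_pixels[:, 1].astype(float)
    b = rgb_pixels[:, 2].astype(float)
    L, aa, bb = rgb_to_lab(r, g, b)
    out = {}
    for name, vals in zip(CHANNELS, (r, g, b, L, aa, bb)):
        out[f"{name}_mean"] = float(vals.mean())
        pct = np.percentile(vals, PERCENTILES, method=percentile_method)
        for q, v in zip(PERCENTILES, pct):
            out[f"{name}_p{q}"] = float(v)
    return out


def segment_cell(
    cropped_image: np.ndarray,
    cell: CellBox,
    image_id: str = "",
    min_pixels: int = MIN_KERNEL_PIXELS,
    threshold: int = TRAY_RULE_THRESHOLD,
    percentile_method: str = "linear",
) -> KernelRecord:
    """Segment one cell and measure its kernel, if any.

    Kernel pixels are the complement of the tray rule inside the cell box;
    fewer than ``min_pixels`` of them marks the cell empty (debris filter)
    and no statistics are recorded.
    """
    h, w = cropped_image.shape[:2]
    if cell.x < 0 or cell.y < 0 or cell.x + cell.side > w or cell.y + cell.side > h:
        raise ValueError(f"cell {(cell.row, cell.col)} lies outside the image")
    box = cropped_image[cell.y : cell.y + cell.side, cell.x : cell.x + cell.side]
    kernel = ~tray_mask(box, threshold=threshold)
    n = int(kernel.sum())
    if n < min_pixels:
        return KernelRecord(image_id, cell.row, cell.col, n_pixels=n, is_empty=True)
    stats = _pixel_stats(box[kernel].reshape(-1, 3), percentile_method)
    return KernelRecord(image_id, cell.row, cell.col, n_pixels=n, is_empty=False, stats=stats)


def segment_image(
    cropped_image: np.ndarray,
    grid: CellGrid,
    image_id: str = "",
    **kwargs,
) -> list:
    """Segment all 100 cells; returns records in row-major cell order."""
    boxes = sorted(grid.boxes, key=lambda b: (b.row, b.col))
    return [segment_cell(cropped_image, b, image_id=image_id, **kwargs) for b in boxes]


def records_to_frame(records) -> pd.DataFrame:
    """Wide table: one row per cell, one column per statistic."""
    rows = []
    for rec in records:
        row = {
            "image_id": rec.image_id,
            "row": rec.row,
            "col": rec.col,
            "n_pixels": rec.n_pixels,
            "is_empty": rec.is_empty,
            "blank_flag": rec.blank_flag,
        }
        for name in STAT_NAMES:
            row[name] = rec.stats.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
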