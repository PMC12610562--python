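"""Synthetic tray-photograph generator with exact ground truth.

Emulates the staged capture system — a blue 100-cell tray photographed at
3300 x 3120 px against a black background, with a color swatch strip on the
left margin and white label stickers below columns 1, 3, 5, 7 and 9 — so
that every downstream stage (barrel correction, rotation, cropping, grid
segmentation, color statistics, blank detection, sample grouping) can be
tested against known truth.

Kernels are rendered as randomized perturbed-ellipse blobs of an exact
pixel area, filled with a target CIELAB color plus optional per-pixel
Gaussian RGB noise.  The generator is purely colorimetric on purpose: the
thresholding pipeline relies only on the warm kernel / blue tray contrast,
never on kernel texture, so photorealism would add nothing testable.

Blank kernels are drawn from a smaller, darker regime than normal kernels,
at a default prevalence of 2.4%, matching their incidence in multi-year
breeding-program trays.

Ground truth lives in cropped-tray coordinates (the canonical unrotated
2780 x 2780 frame): per-kernel masks whose pixel counts equal the requested
areas exactly, per-kernel color statistics measured from the rendered
raster, the true rotation and the true crop origin/side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import grid_segmentation as gs
from .color_model import lab_to_rgb
from .image_geometry import BarrelCoefficients, radial_remap, rotate_image

__all__ = [
    "TrayGeometry",
    "KernelSpec",
    "DebrisSpec",
    "TrayScene",
    "GroundTruth",
    "BLANK_PREVALENCE",
    "TRAY_FACE_RGB",
    "TRAY_WALL_RGB",
    "STICKER_COLUMNS",
    "random_scene",
    "render_tray",
    "apply_barrel",
    "write_scene",
    "read_scene",
    "write_outputs",
]

#: Default blank-kernel prevalence in breeding-program trays.
BLANK_PREVALENCE = 0.024

#: Tray face (lighter) and inner-cell-wall (darker) blues; both lie inside
#: the tray's printed channel ranges R 33-57, G 72-120, B 106-191.
TRAY_FACE_RGB = (57, 120, 191)
TRAY_WALL_RGB = (33, 72, 106)

#: 1-based sticker columns; each labels the sample in columns (c, c+1).
STICKER_COLUMNS = (1, 3, 5, 7, 9)

_TRAY_R_RANGE = (33, 57)
_TRAY_G_RANGE = (72, 120)
_TRAY_B_RANGE = (106, 191)

#: Fixed swatch patch colors (warm/neutral so the blue-tray rule never
#: fires on the swatch).  The real swatch is only checked for session
#: consistency, so any fixed patches serve.
_SWATCH_PATCHES = (
    (235, 235, 235),
    (200, 160, 120),
    (170, 110, 60),
    (120, 70, 40),
    (90, 90, 90),
    (210, 190, 80),
)


@dataclass(frozen=True)
class TrayGeometry:
    """Capture geometry: sensor size and tray square side, in pixels.

    The default matches the reference capture system (3300 x 3120 sensor,
    2780 px tray).  Smaller geometries scale everything proportionally and
    render much faster for tests.
    """

    image_w: int = 3300
    image_h: int = 3120
    tray_side: int = 2780

    @property
    def pitch(self) -> int:
        return self.tray_side // 10

    @property
    def cell_side(self) -> int:
        return self.pitch - 8

    @property
    def cell_origin(self) -> int:
        return (self.pitch - self.cell_side) // 2

    @property
    def tray_x0(self) -> int:
        return (self.image_w - self.tray_side) // 2

    @property
    def tray_y0(self) -> int:
        return (self.image_h - self.tray_side) // 2

    def grid(self) -> gs.CellGrid:
        return gs.default_grid(tray_side=self.tray_side, side=self.cell_side)


@dataclass
class KernelSpec:
    """One kernel half to render."""

    cell_index: int  # 0-99, row-major
    half_axes: tuple  # (ay, ax) blob half-axes in px (shape only)
    target_lab: tuple  # (L*, a*, b*), native CIELAB scale
    area_px: int
    color_noise_sd: float = 0.0
    is_blank: bool = False

    def __post_init__(self):
        if self.area_px <= 0:
            raise ValueError("area_px must be positive")
        if not (0 <= self.cell_index <= 99):
            raise ValueError("cell_index must be in 0-99")


@dataclass
class DebrisSpec:
    """A sub-threshold debris blob (area must stay below 500 px)."""

    cell_index: int
    area_px: int
    rgb: tuple = (150, 120, 90)

    def __post_init__(self):
        if not (0 < self.area_px < gs.MIN_KERNEL_PIXELS):
            raise ValueError("debris area must be in (0, 500)")


class SceneError(ValueError):
    pass


@dataclass
class TrayScene:
    """Complete description of one synthetic capture."""

    kernels: list = field(default_factory=list)
    debris: list = field(default_factory=list)
    rotation_deg: float = 0.0
    tray_face_rgb: tuple = TRAY_FACE_RGB
    tray_wall_rgb: tuple = TRAY_WALL_RGB
    sample_labels: tuple = tuple(f"SAMPLE-{c}" for c in STICKER_COLUMNS)
    seed: int = 0
    geometry: TrayGeometry = field(default_factory=TrayGeometry)
    allow_overlap: bool = False

    def __post_init__(self):
        for rng, val in zip(
            (_TRAY_R_RANGE, _TRAY_G_RANGE, _TRAY_B_RANGE), self.tray_face_rgb
        ):
            if not (rng[0] <= val <= rng[1]):
                raise SceneError(
                    f"tray face color {self.tray_face_rgb} outside printed ranges"
                )
        if len(self.sample_labels) != 5:
            raise SceneError("exactly one label per sticker position (5 labels)")


@dataclass
class GroundTruth:
    """Rendering truth, in cropped-tray (canonical, unrotated) coordinates."""

    masks: dict  # cell_index -> (ys, xs) int arrays
    kernel_table: pd.DataFrame  # per-kernel truth incl. measured stats
    rotation_deg: float
    crop_x0: int
    crop_y0: int
    crop_side: int
    labels: dict  # sticker column (1-based) -> label


def _blob_pixels(
    rng: np.random.Generator,
    cell: gs.CellBox,
    half_axes: tuple,
    area_px: int,
    margin: int = 2,
) -> tuple:
    """Pixel coordinates (ys, xs, tray frame) of a blob of exact area.

    A perturbed elliptical radial field is evaluated over the cell interior
    and exactly ``area_px`` pixels with the smallest field values are
    selected, giving an organic, star-shaped blob with exact bookkeeping.
    """
    side = cell.side
    interior = side - 2 * margin
    if area_px > interior * interior:
        raise SceneError(
            f"kernel of {area_px} px cannot fit cell ({cell.row}, {cell.col})"
        )
    ay, ax = half_axes
    cy = side / 2.0 + rng.uniform(-side * 0.04, side * 0.04)
    cx = side / 2.0 + rng.uniform(-side * 0.04, side * 0.04)
    yy, xx = np.mgrid[margin : side - margin, margin : side - margin]
    dy = (yy - cy) / max(ay, 1.0)
    dx = (xx - cx) / max(ax, 1.0)
    rad = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    pert = np.ones_like(rad)
    for k in (2, 3, 5):
        pert += rng.uniform(0.0, 0.06) * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    fieldv = rad / pert
    flat = np.argpartition(fieldv.ravel(), area_px - 1)[:area_px]
    ys, xs = np.unravel_index(flat, fieldv.shape)
    return ys + cell.y + margin, xs + cell.x + margin


def _render_tray_square(scene: TrayScene, rng: np.random.Generator):
    """Render the canonical tray square and collect exact masks."""
    geo = scene.geometry
    side = geo.tray_side
    tray = np.empty((side, side, 3), dtype=np.float64)
    tray[:] = scene.tray_face_rgb
    grid = geo.grid()
    boxes = {b.row * 10 + b.col: b for b in grid}
    wall = max(2, geo.cell_side // 27)
    for b in grid:
        tray[b.y : b.y + b.side, b.x : b.x + b.side] = scene.tray_wall_rgb
        tray[b.y + wall : b.y + b.side - wall, b.x + wall : b.x + b.side - wall] = (
            scene.tray_face_rgb
        )
    masks = {}
    for spec in scene.kernels:
        cell = boxes[spec.cell_index]
        ys, xs = _blob_pixels(rng, cell, spec.half_axes, spec.area_px)
        if not scene.allow_overlap:
            if (
                ys.min() < cell.y
                or xs.min() < cell.x
                or ys.max() >= cell.y + cell.side
                or xs.max() >= cell.x + cell.side
            ):
                raise SceneError(f"kernel exceeds cell {spec.cell_index}")
        base = np.array(lab_to_rgb(*spec.target_lab), dtype=np.float64)
        vals = np.tile(base, (ys.size, 1))
        if spec.color_noise_sd > 0:
            vals += rng.normal(0.0, spec.color_noise_sd, vals.shape)
        tray[ys, xs] = np.clip(vals, 0, 255)
        masks[spec.cell_index] = (ys.astype(np.int32), xs.astype(np.int32))
    for deb in scene.debris:
        cell = boxes[deb.cell_index]
        ys, xs = _blob_pixels(rng, cell, (cell.side * 0.2, cell.side * 0.2), deb.area_px)
        tray[ys, xs] = deb.rgb
    return np.round(tray).clip(0, 255).astype(np.uint8), masks


def _true_stats(tray: np.ndarray, masks: dict, kernels: list) -> pd.DataFrame:
    rows = []
    for spec in kernels:
        ys, xs = masks[spec.cell_index]
        stats = gs._pixel_stats(tray[ys, xs].reshape(-1, 3), "linear")
        rows.append(
            {
                "cell_index": spec.cell_index,
                "row": spec.cell_index // 10,
                "col": spec.cell_index % 10,
                "is_blank": spec.is_blank,
                "area_px": spec.area_px,
                "target_L": spec.target_lab[0],
                "target_a": spec.target_lab[1],
                "target_b": spec.target_lab[2],
                **stats,
            }
        )
    cols = ["cell_index", "row", "col", "is_blank", "area_px",
            "target_L", "target_a", "target_b", *gs.STAT_NAMES]
    return pd.DataFrame(rows, columns=cols)


def render_tray(scene: TrayScene) -> tuple:
    """Render a scene into an 8-bit RGB capture plus ground truth.

    The tray square is rendered pixel-exactly in its canonical frame, then
    pasted onto the black sensor canvas together with the label stickers and
    rotated by ``scene.rotation_deg`` (positive: top of the left edge moves
    right).  The swatch strip is drawn after rotation — it belongs to the
    capture box, not the tray.  Rendering is deterministic in
    ``scene.seed``.
    """
    geo = scene.geometry
    rng = np.random.default_rng(scene.seed)
    tray, masks = _render_tray_square(scene, rng)
    table = _true_stats(tray, masks, scene.kernels)

    canvas = np.zeros((geo.image_h, geo.image_w, 3), dtype=np.uint8)
    x0, y0 = geo.tray_x0, geo.tray_y0
    canvas[y0 : y0 + geo.tray_side, x0 : x0 + geo.tray_side] = tray

    # white label stickers under columns 1, 3, 5, 7, 9 (they sit on the
    # tray assembly, so they rotate with it)
    margin = geo.image_h - (y0 + geo.tray_side)
    sticker = max(8, min(margin - 2 * max(2, margin // 10), geo.pitch // 2))
    sy = y0 + geo.tray_side + max(2, margin // 10)
    for c in STICKER_COLUMNS:
        cx = x0 + (c - 1) * geo.pitch + geo.pitch // 2
        canvas[sy : sy + sticker, cx - sticker // 2 : cx + sticker // 2] = 255

    if scene.rotation_deg != 0.0:
        canvas = rotate_image(canvas, -scene.rotation_deg)

    # swatch strip on the fixed left margin of the capture box
    sw_w = max(4, int(geo.tray_x0 * 0.45))
    sw_x = max(2, int(geo.tray_x0 * 0.15))
    sw_top = int(geo.image_h * 0.24)
    sw_h = max(4, int(geo.image_h * 0.50 / len(_SWATCH_PATCHES)))
    for i, patch in enumerate(_SWATCH_PATCHES):
        yA = sw_top + i * sw_h
        canvas[yA : yA + sw_h - 2, sw_x : sw_x + sw_w] = patch

    truth = GroundTruth(
        masks=masks,
        kernel_table=table,
        rotation_deg=scene.rotation_deg,
        crop_x0=x0,
        crop_y0=y0,
        crop_side=geo.tray_side,
        labels=dict(zip(STICKER_COLUMNS, scene.sample_labels)),
    )
    return canvas, truth


def apply_barrel(image: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Forward barrel remap, used to distort synthetic fixtures.

    ``correct_barrel`` with the same coefficients is its (approximate)
    left inverse.
    """
    return radial_remap(image, BarrelCoefficients(a, b, c), inverse=False)


# ---------------------------------------------------------------------------
# Scene sampling


def random_scene(
    seed: int = 0,
    geometry: Optional[TrayGeometry] = None,
    blank_prob: float = BLANK_PREVALENCE,
    color_noise_sd: float = 0.0,
    rotation_deg: float = 0.0,
    fill_fraction: float = 1.0,
    n_debris: int = 0,
    labels: Optional[tuple] = None,
) -> TrayScene:
    """Sample a realistic full-tray scene.

    Ten nuts per sample, two halves per nut in adjacent columns; the two
    halves of a nut share a target color.  Normal kernels occupy roughly
    10-22% of their cell box and span the lighter pellicle range
    (L* 45-78); blank nuts (probability ``blank_prob``, applied per nut so
    both halves are blank) are drawn smaller (2-4.5% of the box) and darker
    (L* 25-40).  ``fill_fraction`` < 1 leaves a random subset of nuts out,
    producing empty cells.
    """
    geo = geometry or TrayGeometry()
    rng = np.random.default_rng(seed)
    cell = geo.cell_side
    kernels = []
    for sample in range(5):
        c0 = sample * 2
        for row in range(10):
            if rng.uniform() > fill_fraction:
                continue
            blank = rng.uniform() < blank_prob
            if blank:
                L = rng.uniform(25.0, 40.0)
                a = rng.uniform(6.0, 14.0)
                b = rng.uniform(12.0, 26.0)
                frac = rng.uniform(0.020, 0.045)
            else:
                L = rng.uniform(45.0, 78.0)
                a = rng.uniform(6.0, 16.0)
                b = rng.uniform(16.0, 34.0)
                frac = rng.uniform(0.10, 0.22)
            for col in (c0, c0 + 1):
                area = max(1, int(round(frac * cell * cell * rng.uniform(0.9, 1.1))))
                aspect = rng.uniform(0.7, 1.0)
                ax = cell * 0.40
                kernels.append(
                    KernelSpec(
                        cell_index=row * 10 + col,
                        half_axes=(ax * aspect, ax),
                        target_lab=(L + rng.uniform(-1.5, 1.5), a, b),
                        area_px=area,
                        color_noise_sd=color_noise_sd,
                        is_blank=blank,
                    )
                )
    filled = {k.cell_index for k in kernels}
    empty = [i for i in range(100) if i not in filled]
    debris = []
    for i in range(min(n_debris, len(empty))):
        debris.append(
            DebrisSpec(
                cell_index=empty[i],
                area_px=int(rng.integers(30, gs.MIN_KERNEL_PIXELS - 1)),
            )
        )
    if labels is None:
        labels = tuple(f"GEN{seed:04d}-C{c}" for c in STICKER_COLUMNS)
    return TrayScene(
        kernels=kernels,
        debris=debris,
        rotation_deg=rotation_deg,
        sample_labels=labels,
        seed=seed,
        geometry=geo,
    )


# ---------------------------------------------------------------------------
# Serialization


def write_scene(scene: TrayScene, path) -> None:
    """Serialize a scene as JSON."""
    d = asdict(scene)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def read_scene(path) -> TrayScene:
    with open(path) as fh:
        d = json.load(fh)
    d["geometry"] = TrayGeometry(**d["geometry"])
    d["kernels"] = [
        KernelSpec(**{**k, "half_axes": tuple(k["half_axes"]),
                      "target_lab": tuple(k["target_lab"])})
        for k in d["kernels"]
    ]
    d["debris"] = [DebrisSpec(**{**x, "rgb": tuple(x["rgb"])}) for x in d["debris"]]
    d["tray_face_rgb"] = tuple(d["tray_face_rgb"])
    d["tray_wall_rgb"] = tuple(d["tray_wall_rgb"])
    d["sample_labels"] = tuple(d["sample_labels"])
    return TrayScene(**d)


def write_outputs(
    image: np.ndarray,
    truth: GroundTruth,
    out_dir,
    image_id: str,
    image_format: str = "png",
) -> dict:
    """Write the rendered image, ground-truth tables and the label sidecar.

    Returns the paths written.  PNG is lossless (for exact tests); JPEG
    exercises compression tolerance.  The label-mask PNG encodes
    cell_index + 1 per kernel pixel (0 = background) in the canonical
    cropped-tray frame.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    img_path = os.path.join(out_dir, f"{image_id}.{image_format}")
    iio.imwrite(img_path, image)
    paths["image"] = img_path

    table_path = os.path.join(out_dir, f"{image_id}_truth.csv")
    truth.kernel_table.to_csv(table_path, index=False)
    paths["kernel_table"] = table_path

    mask = np.zeros((truth.crop_side, truth.crop_side), dtype=np.uint8)
    for ci, (ys, xs) in truth.masks.items():
        mask[ys, xs] = ci + 1
    mask_path = os.path.join(out_dir, f"{image_id}_labels.png")
    iio.imwrite(mask_path, mask)
    paths["label_mask"] = mask_path

    sidecar = os.path.join(out_dir, f"{image_id}_samples.csv")
    pd.DataFrame(
        {
            "image_id": image_id,
            "column": list(truth.labels.keys()),
            "label": list(truth.labels.values()),
        }
    ).to_csv(sidecar, index=False)
    paths["sidecar"] = sidecar
    return paths
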