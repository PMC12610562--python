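"""Normalization of raw tray captures into the canonical cropped tray.

A raw capture (nominally 3300 x 3120 px) carries three geometric nuisances:
barrel distortion from the wide-angle lens, a small rotation from tray
mispositioning, and arbitrary margins (black background, color swatch,
label stickers).  The pipeline removes them in order:

1. :func:`correct_barrel` — inverse radial remap with coefficients
   (a, b, c) = (0, -0.22, 0) for the reference capture system.
2. :func:`estimate_rotation` / :func:`rotate_image` — the tray's left edge
   is located in the top and bottom 20% bands of the image using the same
   r - b <= -40 blue-tray rule as segmentation; the x-offset between the
   two bands gives the rotation angle.
3. :func:`crop_tray` — row-wise then column-wise scans of mean r - b find
   the tray extent; the default capture geometry yields a 2780 x 2780 crop
   whose (0, 0) pixel is the tray's top-left corner.

Coordinates are 0-based; boxes are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as _tf

from .grid_segmentation import TRAY_RULE_THRESHOLD

__all__ = [
    "BarrelCoefficients",
    "DEFAULT_BARREL",
    "EdgeScanResult",
    "TrayCrop",
    "TrayNotFoundError",
    "radial_remap",
    "correct_barrel",
    "find_left_edge",
    "scan_edges",
    "estimate_rotation",
    "rotate_image",
    "crop_tray",
    "preprocess",
]

logger = logging.getLogger(__name__)


class TrayNotFoundError(ValueError):
    """No pixels satisfied the blue-tray rule where a tray was expected."""


@dataclass(frozen=True)
class BarrelCoefficients:
    """Radial polynomial coefficients of the barrel model.

    The source radius for an output pixel at normalized radius r is
    ``r * (a r^3 + b r^2 + c r + d)`` with ``d = 1 - (a + b + c)``; radii
    are normalized by half the smaller image dimension, about the image
    center.
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0

    @property
    def d(self) -> float:
        return 1.0 - (self.a + self.b + self.c)

    def poly(self, r: np.ndarray) -> np.ndarray:
        """Source radius as a function of output radius (forward model)."""
        return r * (self.a * r**3 + self.b * r**2 + self.c * r + self.d)


#: Coefficients of the reference capture system's lens.
DEFAULT_BARREL = BarrelCoefficients(0.0, -0.22, 0.0)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise TypeError("expected an 8-bit RGB image of shape (H, W, 3)")
    return image


def radial_remap(image: np.ndarray, coeffs: BarrelCoefficients, inverse: bool = False) -> np.ndarray:
    """Apply the barrel model's radial remap (or its functional inverse).

    ``inverse=False`` applies the forward model (used to distort synthetic
    fixtures); ``inverse=True`` undoes it (lens correction).  Bilinear
    resampling; out-of-source pixels are filled black.
    """
    image = _check_rgb(image)
    h, w = image.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    norm = min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - cy) / norm
    dx = (xx - cx) / norm
    r = np.hypot(dx, dy)
    if not inverse:
        s = coeffs.poly(r)
    else:
        # numerically invert the forward polynomial on its monotone prefix
        rmax = float(r.max()) * 1.25 + 1e-6
        t = np.linspace(0.0, rmax, 8193)
        sv = coeffs.poly(t)
        dsv = np.diff(sv)
        bad = np.nonzero(dsv <= 0)[0]
        cut = bad[0] + 1 if bad.size else t.size
        t, sv = t[:cut], sv[:cut]
        # radii beyond the invertible range map far outside the image (black)
        s = np.interp(r, sv, t, right=rmax * 10.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, s / np.where(r > 0, r, 1.0), 1.0)
    src_y = cy + dy * scale * norm
    src_x = cx + dx * scale * norm
    out = np.empty_like(image)
    for ch in range(3):
        out[..., ch] = ndimage.map_coordinates(
            image[..., ch].astype(np.float32),
            [src_y, src_x],
            order=1,
            mode="constant",
            cval=0.0,
        ).round().clip(0, 255).astype(np.uint8)
    return out


def correct_barrel(image: np.ndarray, coeffs: BarrelCoefficients = DEFAULT_BARREL) -> np.ndarray:
    """Undo barrel distortion (inverse of the forward radial model)."""
    return radial_remap(image, coeffs, inverse=True)


def _band_rows(height: int, band: str, fraction: float) -> slice:
    n = max(1, int(round(height * fraction)))
    if band == "top":
        return slice(0, n)
    if band == "bottom":
        return slice(height - n, height)
    raise ValueError("band must be 'top' or 'bottom'")


def find_left_edge(
    image: np.ndarray,
    band: str = "top",
    fraction: float = 0.20,
    threshold: int = TRAY_RULE_THRESHOLD,
) -> int:
    """Column where the blue tray's left edge begins within a band.

    The band's column-wise mean red and blue are thresholded with the tray
    rule; the smallest qualifying column index is returned.
    """
    image = _check_rgb(image)
    sub = image[_band_rows(image.shape[0], band, fraction)]
    col_diff = sub[..., 0].mean(axis=0) - sub[..., 2].mean(axis=0)
    on = col_diff <= threshold
    if not on.any():
        raise TrayNotFoundError(f"tray not found in {band} band")
    return int(np.argmax(on))


@dataclass(frozen=True)
class EdgeScanResult:
    """Left-edge positions in the two scan bands and the implied rotation."""

    top_edge_x: int
    bottom_edge_x: int
    band_centers_y: tuple

    @property
    def angle_deg(self) -> float:
        dy = self.band_centers_y[1] - self.band_centers_y[0]
        return float(np.degrees(np.arctan2(self.top_edge_x - self.bottom_edge_x, dy)))


def _tray_row_centroid(image: np.ndarray, rows: slice, threshold: int) -> float:
    """Centroid of tray-bearing rows inside a band.

    Rows whose own mean r - b satisfies the tray rule carry the tray; their
    centroid is the band's effective vertical center for the angle formula.
    Falls back to the geometric band center if no row qualifies.
    """
    sub = image[rows]
    row_diff = sub[..., 0].mean(axis=1) - sub[..., 2].mean(axis=1)
    on = np.nonzero(row_diff <= threshold)[0]
    start = rows.start or 0
    if on.size == 0:
        return start + (sub.shape[0] - 1) / 2.0
    return start + float(on.mean())


def scan_edges(
    image: np.ndarray, fraction: float = 0.20, threshold: int = TRAY_RULE_THRESHOLD
) -> EdgeScanResult:
    """Scan the top and bottom bands for the tray's left edge."""
    image = _check_rgb(image)
    h = image.shape[0]
    top = find_left_edge(image, "top", fraction, threshold)
    bottom = find_left_edge(image, "bottom", fraction, threshold)
    cy_top = _tray_row_centroid(image, _band_rows(h, "top", fraction), threshold)
    cy_bottom = _tray_row_centroid(image, _band_rows(h, "bottom", fraction), threshold)
    return EdgeScanResult(top, bottom, (cy_top, cy_bottom))


def estimate_rotation(image: np.ndarray, fraction: float = 0.20) -> float:
    """Tray rotation in degrees.

    Positive means the top of the left edge sits right of the bottom;
    passing the estimate to :func:`rotate_image` squares the tray up.
    """
    return scan_edges(image, fraction=fraction).angle_deg


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Corrective rotation about the image center (bilinear, black fill)."""
    image = _check_rgb(image)
    if angle_deg == 0.0:
        return image.copy()
    out = _tf.rotate(
        image.astype(np.float32), angle_deg, order=1, preserve_range=True, cval=0.0
    )
    return out.round().clip(0, 255).astype(np.uint8)


@dataclass
class TrayCrop:
    """Cropped tray image plus the crop geometry on the source image."""

    image: np.ndarray
    x0: int
    y0: int
    width: int
    height: int

    @property
    def side(self) -> int:
        return self.image.shape[0]


def crop_tray(
    image: np.ndarray,
    threshold: int = TRAY_RULE_THRESHOLD,
    expected_side: int = 2780,
    tolerance: float = 0.02,
) -> TrayCrop:
    """Crop the image to the blue tray's row/column extent.

    Row means (top to bottom) and column means (left to right) of r - b are
    thresholded with the tray rule; the crop spans the first through last
    qualifying row and column.  A measured extent deviating from
    ``expected_side`` by more than ``tolerance`` logs a warning but the
    crop is still returned.
    """
    image = _check_rgb(image)
    diff = image[..., 0].astype(np.float64) - image[..., 2].astype(np.float64)
    rows_on = np.nonzero(diff.mean(axis=1) <= threshold)[0]
    cols_on = np.nonzero(diff.mean(axis=0) <= threshold)[0]
    if rows_on.size == 0 or cols_on.size == 0:
        raise TrayNotFoundError("tray not found during crop scan")
    y0, y1 = int(rows_on[0]), int(rows_on[-1])
    x0, x1 = int(cols_on[0]), int(cols_on[-1])
    h, w = y1 - y0 + 1, x1 - x0 + 1
    for label, extent in (("height", h), ("width", w)):
        if expected_side and abs(extent - expected_side) / expected_side > tolerance:
            logger.warning(
                "crop %s %d deviates more than %.0f%% from expected %d",
                label,
                extent,
                tolerance * 100,
                expected_side,
            )
    return TrayCrop(image[y0 : y1 + 1, x0 : x1 + 1].copy(), x0=x0, y0=y0, width=w, height=h)


@dataclass
class PreprocessResult:
    crop: TrayCrop
    angle_deg: float
    barrel: BarrelCoefficients | None

    @property
    def image(self) -> np.ndarray:
        return self.crop.image


def preprocess(
    image: np.ndarray,
    barrel: BarrelCoefficients | None = DEFAULT_BARREL,
    expected_side: int = 2780,
) -> PreprocessResult:
    """Full normalization: barrel correction, rotation, crop."""
    if barrel is not None and (barrel.a, barrel.b, barrel.c) != (0.0, 0.0, 0.0):
        image = correct_barrel(image, barrel)
    angle = estimate_rotation(image)
    rotated = rotate_image(image, angle)
    crop = crop_tray(rotated, expected_side=expected_side)
    return PreprocessResult(crop=crop, angle_deg=angle, barrel=barrel)
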