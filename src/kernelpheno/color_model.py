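"""Colorimetry and color-grade calibration.

Kernel color is quantified in CIELAB because lightness (L*) tracks the
commercial pellicle grade far better than raw RGB does.  Grading uses a
four-point ordinal scale — amber (1), light amber (2), light (3), extra
light (4) — and the calibration maps a human-scored training set onto three
L* cutoffs by ordinary least squares: regress score on median L*, then
invert the fitted line at the half-scores 1.5, 2.5 and 3.5.  Classification
of a lightness value (or of every pixel of a kernel) against those cutoffs
is scale-agnostic: thresholds and values only need to share a scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "CATEGORIES",
    "CATEGORY_CODES",
    "ColorThresholds",
    "REFERENCE_THRESHOLDS",
    "rgb_to_lab",
    "lab_to_rgb",
    "score_to_category",
    "category_to_score",
    "derive_thresholds",
    "classify_value",
    "pixel_composition",
    "PixelComposition",
]

#: Ordinal color grades, darkest to lightest.
CATEGORIES = ("amber", "light_amber", "light", "extra_light")

#: Industry short codes for the four grades.
CATEGORY_CODES = {
    "amber": "A",
    "light_amber": "LA",
    "light": "L",
    "extra_light": "EL",
}

_SCORE_OF = {name: i + 1 for i, name in enumerate(CATEGORIES)}
_CATEGORY_OF = {i + 1: name for i, name in enumerate(CATEGORIES)}


def category_to_score(category: str) -> int:
    """Numeric score (1–4) of a grade name ('amber' … 'extra_light')."""
    return _SCORE_OF[category]


def score_to_category(score: int) -> str:
    """Grade name of a numeric score 1–4."""
    return _CATEGORY_OF[int(score)]


# ---------------------------------------------------------------------------
# sRGB (D65, 2 degree observer) -> CIELAB
#
# IEC 61966-2-1 linearization and primaries.  The reference white is the
# image of (1, 1, 1) under the sRGB->XYZ matrix so that pure white maps to
# exactly (L*=100, a*=0, b*=0).

_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE = _SRGB_TO_XYZ @ np.ones(3)

_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ)

_DELTA = 6.0 / 29.0


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(ft: np.ndarray) -> np.ndarray:
    return np.where(ft > _DELTA, ft**3, 3 * _DELTA**2 * (ft - 4.0 / 29.0))


def rgb_to_lab(r, g, b):
    """Convert 8-bit sRGB channels to CIELAB (D65, 2 degree observer).

    Parameters
    ----------
    r, g, b : scalar or array-like
        Channel values in [0, 255] (integer or float).

    Returns
    -------
    (L, a, b) : tuple of floats or arrays
        L* in [0, 100]; a*, b* on the native CIELAB scale.
    """
    r, g, b = np.broadcast_arrays(
        np.asarray(r, float), np.asarray(g, float), np.asarray(b, float)
    )
    rgb = np.stack([r, g, b], axis=-1)
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    lin = _srgb_to_linear(rgb / 255.0)
    xyz = lin @ _SRGB_TO_XYZ.T
    f = _lab_f(xyz / _WHITE)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    bb = 200.0 * (f[..., 1] - f[..., 2])
    if L.ndim == 0:
        return float(L), float(a), float(bb)
    return L, a, bb


def lab_to_rgb(L, a, b):
    """Inverse of :func:`rgb_to_lab`; out-of-gamut values are clipped.

    Returns float channels in [0, 255].
    """
    L, a, b = np.broadcast_arrays(
        np.asarray(L, float), np.asarray(a, float), np.asarray(b, float)
    )
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    xyz = np.stack([_lab_f_inv(fx), _lab_f_inv(fy), _lab_f_inv(fz)], axis=-1) * _WHITE
    lin = np.clip(xyz @ _XYZ_TO_SRGB.T, 0.0, 1.0)
    srgb = np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)
    out = np.clip(srgb, 0.0, 1.0) * 255.0
    if out.ndim == 1:
        return float(out[0]), float(out[1]), float(out[2])
    return out[..., 0], out[..., 1], out[..., 2]


# ---------------------------------------------------------------------------
# Thresholds


@dataclass(frozen=True)
class ColorThresholds:
    """Three ordered L* cutoffs separating amber / light amber / light /
    extra light.

    ``scale_label`` records the lightness scale the cutoffs live on; values
    passed to :func:`classify_value` must share that scale.
    """

    t_a_la: float
    t_la_l: float
    t_l_el: float
    scale_label: str = "CIELAB L* (0-100)"

    def __post_init__(self):
        if not (self.t_a_la < self.t_la_l < self.t_l_el):
            raise ValueError(
                "thresholds must be strictly increasing: "
                f"{self.t_a_la}, {self.t_la_l}, {self.t_l_el}"
            )

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.t_a_la, self.t_la_l, self.t_l_el])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "t_A_LA": self.t_a_la,
                    "t_LA_L": self.t_la_l,
                    "t_L_EL": self.t_l_el,
                    "scale_label": self.scale_label,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ColorThresholds":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["t_A_LA"], d["t_LA_L"], d["t_L_EL"], d.get("scale_label", ""))


#: Calibration published for the original walnut capture system.  The cutoffs
#: are on that instrument's raw lightness scale (not the native 0-100 L*
#: scale); they are shipped verbatim and must only ever be compared with
#: lightness statistics on the same scale.
REFERENCE_THRESHOLDS = ColorThresholds(
    3929.14, 4610.63, 5292.13, scale_label="instrument raw L* scale (unspecified quantum range)"
)


def derive_thresholds(
    median_L, human_score, scale_label: str = "CIELAB L* (0-100)"
) -> ColorThresholds:
    """Calibrate grade cutoffs from human scores by inverse regression.

    Fits ``score = alpha + beta * L`` by OLS and solves for the lightness at
    the half-scores 1.5, 2.5 and 3.5.  Because the fit is linear the three
    cutoffs are always equally spaced.

    Raises
    ------
    ValueError
        If fewer than 2 distinct L* values are given, if scores are outside
        {1, 2, 3, 4}, or if the fitted slope is not positive (lighter
        kernels must receive higher scores).
    """
    L = np.asarray(median_L, float)
    s = np.asarray(human_score, float)
    if L.shape != s.shape or L.ndim != 1:
        raise ValueError("median_L and human_score must be 1-D and equal length")
    if np.unique(L).size < 2:
        raise ValueError("need at least 2 distinct L* values to fit a line")
    if not np.isin(s, [1, 2, 3, 4]).all():
        raise ValueError("human scores must be in {1, 2, 3, 4}")
    fit = _stats.linregress(L, s)
    if not np.isfinite(fit.slope) or fit.slope <= 0:
        raise ValueError(
            f"non-positive lightness-score slope ({fit.slope:.4g}); "
            "cannot invert the calibration line"
        )
    cuts = [(t - fit.intercept) / fit.slope for t in (1.5, 2.5, 3.5)]
    return ColorThresholds(*cuts, scale_label=scale_label)


def classify_value(L, thresholds: ColorThresholds):
    """Grade a lightness value (or array) against the three cutoffs.

    Intervals are closed on the left: a value exactly at a cutoff takes the
    lighter grade.  Returns a grade name, or an array of grade names.
    """
    L_arr = np.asarray(L, float)
    idx = np.searchsorted(thresholds.as_array, L_arr, side="right")
    if L_arr.ndim == 0:
        return CATEGORIES[int(idx)]
    return np.array(CATEGORIES, dtype=object)[idx]


@dataclass(frozen=True)
class PixelComposition:
    """Percentages of a kernel's pixels in each of the four color bands."""

    pct_amber: float
    pct_light_amber: float
    pct_light: float
    pct_extra_light: float

    @property
    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pct_amber, self.pct_light_amber, self.pct_light, self.pct_extra_light]
        )


def pixel_composition(pixel_L, thresholds: ColorThresholds) -> PixelComposition:
    """Per-pixel color-band composition of a kernel, in percent.

    ``pixel_L`` is the vector of per-pixel lightness values (same scale as
    the thresholds).  The four percentages sum to 100.
    """
    L = np.asarray(pixel_L, float).ravel()
    if L.size == 0:
        raise ValueError("pixel_composition requires a non-empty pixel vector")
    idx = np.searchsorted(thresholds.as_array, L, side="right")
    counts = np.bincount(idx, minlength=4)
    pct = counts / L.size * 100.0
    return PixelComposition(*pct.tolist())
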