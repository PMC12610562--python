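"""Sample identity, aggregation and method comparison.

Each tray holds five samples: ten nuts per sample, the two halves of each
nut in adjacent columns, with a label sticker under the first column of
each pair (1-based columns 1, 3, 5, 7, 9).  This module attaches decoded
labels to cells, pairs halves into nuts (per-nut statistics are the
unweighted mean of the two halves), converts between the long CSV schema
shared with CNN-based pipelines and a wide per-kernel table, and computes
the agreement statistics (r-squared, slope, mean difference) used to
benchmark one measurement method against another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .grid_segmentation import STAT_NAMES, KernelRecord
from .synthetic_tray import STICKER_COLUMNS

__all__ = [
    "SampleAssignment",
    "NutRecord",
    "LabelResolutionError",
    "decode_labels",
    "group_into_nuts",
    "nuts_to_frame",
    "long_to_wide",
    "wide_to_long",
    "MethodComparison",
    "compare_methods",
]


class LabelResolutionError(ValueError):
    pass


@dataclass
class SampleAssignment:
    """A decoded sample label and the 20 cells it covers."""

    image_id: str
    sticker_column: int  # 1-based odd column: 1, 3, 5, 7 or 9
    label: str
    member_cells: list = field(default_factory=list)  # 20 (row, col) pairs

    def __post_init__(self):
        if self.sticker_column not in STICKER_COLUMNS:
            raise ValueError(f"sticker column must be one of {STICKER_COLUMNS}")
        if not self.member_cells:
            c = self.sticker_column - 1  # 0-based first column of the pair
            self.member_cells = [(r, c) for r in range(10)] + [
                (r, c + 1) for r in range(10)
            ]


def _try_qr_decode(image) -> dict:
    """Decode QR stickers if a decoder library is importable.

    Returns {1-based column: label}; empty when no decoder is available or
    nothing decodes.
    """
    try:
        from pyzbar import pyzbar  # optional, typically absent
    except ImportError:
        return {}
    h, w = image.shape[:2]
    out = {}
    for res in pyzbar.decode(image):
        cx = res.rect.left + res.rect.width / 2.0
        # nearest sticker position across the tray width
        col = min(
            STICKER_COLUMNS,
            key=lambda c: abs(cx - (w * (0.5 + (c - 5) / 10.0))),
        )
        out[col] = res.data.decode()
    return out


def decode_labels(
    image: Optional[np.ndarray] = None,
    sidecar=None,
    image_id: str = "",
) -> list:
    """Resolve the five sample labels of a tray.

    QR decoding is attempted when an image and a decoder library are
    available; any unresolved sticker columns fall back to the sidecar CSV
    (columns ``image_id, column, label``).  Fewer than five resolved labels
    raises :class:`LabelResolutionError` naming the missing columns.
    """
    labels = {}
    if image is not None:
        labels.update(_try_qr_decode(image))
    if sidecar is not None:
        df = sidecar if isinstance(sidecar, pd.DataFrame) else pd.read_csv(sidecar)
        if image_id and "image_id" in df.columns:
            df = df[df["image_id"].astype(str) == str(image_id)]
        for _, row in df.iterrows():
            labels.setdefault(int(row["column"]), str(row["label"]))
    missing = [c for c in STICKER_COLUMNS if c not in labels]
    if missing:
        raise LabelResolutionError(
            f"unresolved sticker columns {missing} for image '{image_id}'"
        )
    return [
        SampleAssignment(image_id=image_id, sticker_column=c, label=labels[c])
        for c in STICKER_COLUMNS
    ]


@dataclass
class NutRecord:
    """One nut: the paired kernel halves and their averaged statistics."""

    label: str
    nut_index: int  # 1-10 (row + 1)
    halves: tuple  # (KernelRecord or None, KernelRecord or None) as used
    stats: dict
    n_pixels: float  # mean pixel count of the used halves (size proxy)
    n_halves: int
    single_half: bool


def _usable(rec: Optional[KernelRecord]) -> bool:
    return rec is not None and not rec.is_empty and not bool(rec.blank_flag)


def group_into_nuts(records, assignments) -> list:
    """Pair kernel halves into nuts and average their statistics.

    Halves sit at (row, c) and (row, c+1) for sticker column c.  Empty
    cells and blank-flagged halves are excluded; a nut with one usable half
    takes that half's statistics and is flagged ``single_half``.
    """
    by_cell = {(r.row, r.col): r for r in records}
    for a in assignments:
        for cell in a.member_cells:
            if cell not in by_cell:
                raise ValueError(f"no record for cell {cell} of sample '{a.label}'")
    nuts = []
    for a in assignments:
        c = a.sticker_column - 1
        for row in range(10):
            pair = (by_cell[(row, c)], by_cell[(row, c + 1)])
            used = [h for h in pair if _usable(h)]
            stats = {}
            if used:
                for name in STAT_NAMES:
                    stats[name] = float(np.mean([h.stats[name] for h in used]))
            nuts.append(
                NutRecord(
                    label=a.label,
                    nut_index=row + 1,
                    halves=pair,
                    stats=stats,
                    n_pixels=float(np.mean([h.n_pixels for h in used])) if used else np.nan,
                    n_halves=len(used),
                    single_half=len(used) == 1,
                )
            )
    return nuts


def nuts_to_frame(nuts) -> pd.DataFrame:
    rows = []
    for nut in nuts:
        row = {
            "label": nut.label,
            "nut_index": nut.nut_index,
            "n_halves": nut.n_halves,
            "single_half": nut.single_half,
            "n_pixels": nut.n_pixels,
        }
        for name in STAT_NAMES:
            row[name] = nut.stats.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Long/wide schema shared with CNN-based pipelines


def long_to_wide(
    long_table: pd.DataFrame,
    key: str = "kernel_id",
    statistic: str = "statistic",
    value: str = "value",
) -> pd.DataFrame:
    """Pivot the long (one row per kernel x statistic) schema to wide.

    Duplicate (kernel, statistic) keys raise; the pivot is lossless, so
    ``wide_to_long`` inverts it.
    """
    if long_table.duplicated([key, statistic]).any():
        dupes = long_table[long_table.duplicated([key, statistic])]
        raise ValueError(
            f"duplicate (kernel, statistic) keys, e.g. {dupes.iloc[0].tolist()}"
        )
    wide = long_table.pivot(index=key, columns=statistic, values=value)
    wide.columns.name = None
    return wide.reset_index()


def wide_to_long(
    wide_table: pd.DataFrame,
    key: str = "kernel_id",
    statistic: str = "statistic",
    value: str = "value",
) -> pd.DataFrame:
    long = wide_table.melt(id_vars=[key], var_name=statistic, value_name=value)
    return long.sort_values([key, statistic]).reset_index(drop=True)


@dataclass(frozen=True)
class MethodComparison:
    """Agreement statistics between two per-nut measurement vectors."""

    r_squared: float
    slope: float
    intercept: float
    mean_diff: float  # mean(x - y)
    mean_pct_diff: float  # mean((x - y) / x) * 100, sign-aware
    n: int


def compare_methods(x, y) -> MethodComparison:
    """Pairwise agreement between two methods' per-nut values.

    Returns the squared Pearson correlation along with the OLS slope and
    intercept of y on x, the mean difference and the sign-aware mean
    percent difference.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    fit = _stats.linregress(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(x != 0, (x - y) / x * 100.0, np.nan)
    return MethodComparison(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        mean_diff=float(np.mean(x - y)),
        mean_pct_diff=float(np.nanmean(pct)) if np.isfinite(pct).any() else float("nan"),
        n=int(x.size),
    )
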