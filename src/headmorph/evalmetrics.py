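"""Personalization-accuracy metrics: DICE, HD95, per-region score tables.

DICE(A, B) = 2|A n B| / (|A| + |B|); HD95 is the maximum of the two
directed 95th-percentile boundary distances (directed distance of a point =
minimum distance to the other boundary set; percentile by linear
interpolation between order statistics). HD95 defaults to voxel units; mm
is available where grids are anisotropic or physically meaningful
distances are wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imagevol import LabelMask


def dice(a: LabelMask, b: LabelMask) -> float:
    """Overlap coefficient of two binary masks on one grid.

    NaN (missing) when both masks are empty.
    """
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError("dice requires masks on identical grids")
    fa = a.data > 0
    fb = b.data > 0
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        return math.nan
    return 2.0 * int(np.logical_and(fa, fb).sum()) / denom


def _boundary_points(mask: LabelMask, units: str) -> np.ndarray:
    fg = mask.data > 0
    if not fg.any():
        raise ValueError("mask has no foreground voxels")
    boundary = fg & ~ndimage.binary_erosion(fg)
    idx = np.argwhere(boundary).astype(float)
    if units == "voxel":
        return idx
    if units == "mm":
        return mask.voxel_to_world(idx)
    raise ValueError(f"unknown units {units!r}")


def _directed_p95(src: np.ndarray, dst: np.ndarray) -> float:
    d, _ = cKDTree(dst).query(src, k=1)
    return float(np.percentile(d, 95, method="linear"))


def hd95(a: LabelMask, b: LabelMask, units: str = "voxel") -> float:
    """95th-percentile symmetric Hausdorff distance between mask boundaries."""
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError("hd95 requires masks on identical grids")
    pa = _boundary_points(a, units)
    pb = _boundary_points(b, units)
    return max(_directed_p95(pa, pb), _directed_p95(pb, pa))


def jaccard_from_dice(d: float) -> float:
    """Jaccard index from a DICE value: d / (2 - d)."""
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"DICE must lie in [0, 1], got {d}")
    return d / (2.0 - d)


@dataclass
class OverlapScores:
    """Per-region DICE and HD95 for one subject; NaN marks a missing entry."""

    subject_id: str
    dice: dict[str, float] = field(default_factory=dict)
    hd95: dict[str, float] = field(default_factory=dict)

    def regions(self) -> list[str]:
        return list(self.dice.keys() | self.hd95.keys())


def region_scores(
    warped_labels: dict[str, LabelMask],
    subject_labels: dict[str, LabelMask],
    regions: list[str],
    subject_id: str = "",
    units: str = "voxel",
) -> OverlapScores:
    """DICE + HD95 per named region; regions missing on either side get NaN."""
    out = OverlapScores(subject_id=subject_id)
    for name in regions:
        wa = warped_labels.get(name)
        su = subject_labels.get(name)
        if wa is None or su is None:
            out.dice[name] = math.nan
            out.hd95[name] = math.nan
            continue
        out.dice[name] = dice(wa, su)
        try:
            out.hd95[name] = hd95(wa, su, units=units)
        except ValueError:
            out.hd95[name] = math.nan
    return out


def _round_half_up(x: float, digits: int = 2) -> float:
    if math.isnan(x):
        return math.nan
    q = Decimal(10) ** -digits
    # snap away binary representation error (e.g. 5.61/6 = 0.93499999...)
    # before rounding, so means of printed decimals round as decimals do
    return float(Decimal(repr(round(x, digits + 8))).quantize(
        q, rounding=ROUND_HALF_UP
    ))


def aggregate_scores(
    rows: list[OverlapScores], digits: int = 2
) -> OverlapScores:
    """Per-region arithmetic mean over subjects, skipping missing entries.

    Reported values are rounded half-up to ``digits`` decimals, matching
    standard table reporting. A region missing in every row stays missing.
    """
    if not rows:
        raise ValueError("aggregate_scores needs at least one row")
    regions: list[str] = []
    for r in rows:
        for name in r.dice.keys() | r.hd95.keys():
            if name not in regions:
                regions.append(name)
    avg = OverlapScores(subject_id="Average")
    for metric in ("dice", "hd95"):
        for name in regions:
            vals = [
                getattr(r, metric).get(name, math.nan) for r in rows
            ]
            vals = [v for v in vals if not math.isnan(v)]
            getattr(avg, metric)[name] = (
                _round_half_up(float(np.mean(vals)), digits) if vals else math.nan
            )
    return avg


def scores_table(rows: list[OverlapScores], metric: str = "dice") -> pd.DataFrame:
    """Subjects x regions table for one metric, with an Average row."""
    if metric not in ("dice", "hd95"):
        raise ValueError("metric must be 'dice' or 'hd95'")
    data = {r.subject_id: getattr(r, metric) for r in rows}
    avg = aggregate_scores(rows)
    data["Average"] = getattr(avg, metric)
    return pd.DataFrame(data).T
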