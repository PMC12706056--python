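"""Pole-resolved and whole-cell fluorescence statistics.

The central quantities:

* normalized pole difference — (mean intensity in one pole region minus
  the other) divided by the mean cell intensity; pole regions span 30% of
  the cell length from each pole, eroded 2 px. Scale-invariant.
* SCF (signal correlation factor) — Pearson correlation of two channels
  over a 4-px-wide strip along the medial axis, trimmed 5 px from each
  pole.
* glycogen-sensor pole-area asymmetry — Otsu-segmented sensor area per
  pole half, difference normalized by cell area.
* future-daughter partitioning — constricting cells computationally split
  at the constriction into their two future daughters.
* association statistics — Spearman rank correlation and a total
  least-squares (first principal component) regression line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.filters import threshold_otsu

from .geometry import ConstrictionCall, MedialAxis, PoleRegions

__all__ = [
    "normalized_pole_difference",
    "scf",
    "glycogen_pole_area_difference",
    "split_at_constriction",
    "population_summary",
    "association_stats",
]


def normalized_pole_difference(
    channel: np.ndarray,
    regions: PoleRegions,
    cell_mask: np.ndarray,
    orientation: str = "pole1_first",
    rng: np.random.Generator | None = None,
) -> float:
    """Normalized pole signal difference of one channel.

    ``(mean(first pole) - mean(second pole)) / mean(whole cell)``. The
    sign convention is set by ``orientation``:

    * ``"pole1_first"`` / ``"pole2_first"`` — fixed by axis orientation;
    * ``"random"`` — a seeded coin flip (pass ``rng``). When several
      channels of the same cell are compared, draw the flip once and call
      with the resulting fixed orientation so per-cell signs stay
      comparable across channels.

    Uniform images give exactly 0; any positive rescaling of the channel
    leaves the value unchanged.
    """
    channel = np.asarray(channel, dtype=float)
    if not regions.pole1.any() or not regions.pole2.any():
        raise ValueError("empty pole region")
    if orientation == "random":
        if rng is None:
            raise ValueError("orientation='random' requires an rng")
        orientation = "pole2_first" if rng.random() < 0.5 else "pole1_first"
    if orientation not in ("pole1_first", "pole2_first"):
        raise ValueError(f"unknown orientation {orientation!r}")
    m1 = float(channel[regions.pole1].mean())
    m2 = float(channel[regions.pole2].mean())
    cell_mean = float(channel[np.asarray(cell_mask, dtype=bool)].mean())
    if cell_mean == 0:
        raise ValueError("zero mean cell intensity")
    diff = m1 - m2 if orientation == "pole1_first" else m2 - m1
    return diff / cell_mean


def _strip_mask(
    labeled: np.ndarray, axis: MedialAxis, cell_id: int, width_px: float, pole_trim_px: float
) -> np.ndarray:
    cell = np.asarray(labeled) == cell_id
    rr, cc = np.nonzero(cell)
    coords = np.column_stack([rr, cc]).astype(float)
    from scipy.spatial import cKDTree

    tree = cKDTree(axis.points)
    dist, idx = tree.query(coords)
    s = axis.arclen[idx]
    L = axis.length
    sel = (dist <= width_px / 2.0) & (s >= pole_trim_px) & (s <= L - pole_trim_px)
    strip = np.zeros_like(cell)
    strip[rr[sel], cc[sel]] = True
    return strip


def scf(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    labeled: np.ndarray,
    axis: MedialAxis,
    cell_id: int = 1,
    width_px: float = 4.0,
    pole_trim_px: float = 5.0,
    min_pixels: int = 10,
) -> float:
    """Signal correlation factor between two channels of one cell.

    Pixels within ``width_px / 2`` of the medial axis whose arc-length
    coordinate lies at least ``pole_trim_px`` from each pole form the SCF
    strip; the value is the Pearson correlation of the two channels over
    those pixels. Returns NaN (flagged) for undersized strips or
    zero-variance channels. Invariant under positive affine transforms of
    either channel.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share a shape")
    strip = _strip_mask(labeled, axis, cell_id, width_px, pole_trim_px)
    va, vb = a[strip], b[strip]
    if len(va) < min_pixels or np.ptp(va) == 0 or np.ptp(vb) == 0:
        return np.nan
    return float(np.corrcoef(va, vb)[0, 1])


def _otsu_foreground(channel: np.ndarray, cell: np.ndarray) -> np.ndarray:
    vals = channel[cell]
    if np.ptp(vals) == 0:
        return np.zeros_like(cell)
    thr = threshold_otsu(vals)
    return (channel > thr) & cell


def glycogen_pole_area_difference(
    sensor_channel: np.ndarray,
    labeled: np.ndarray,
    axis: MedialAxis,
    cell_id: int = 1,
    regions: PoleRegions | None = None,
    split: str = "halves",
) -> tuple[float, float, float]:
    """Glycogen-sensor area per pole and their normalized difference.

    The sensor signal is Otsu-segmented within the cell; each segmented
    pixel is assigned to the pole half of its axial coordinate
    (``split="halves"``, s < L/2 vs. s >= L/2 — a guaranteed partition) or
    to the 30% pole masks (``split="pole_masks"``, pixels outside both
    masks are unassigned). Returns (area pole 1, area pole 2,
    (a1 - a2) / cell area). Zero segmented area gives a difference of 0.
    """
    sensor_channel = np.asarray(sensor_channel, dtype=float)
    cell = np.asarray(labeled) == cell_id
    if not cell.any():
        raise KeyError(f"label {cell_id} not present in mask")
    seg = _otsu_foreground(sensor_channel, cell)
    cell_area = float(cell.sum())
    if not seg.any():
        return 0.0, 0.0, 0.0
    if split == "halves":
        rr, cc = np.nonzero(seg)
        s = axis.nearest_s(np.column_stack([rr, cc]))
        a1 = float(np.count_nonzero(s < axis.length / 2.0))
        a2 = float(len(s) - a1)
    elif split == "pole_masks":
        if regions is None:
            raise ValueError("split='pole_masks' requires PoleRegions")
        a1 = float(np.count_nonzero(seg & regions.pole1))
        a2 = float(np.count_nonzero(seg & regions.pole2))
    else:
        raise ValueError(f"unknown split {split!r}")
    return a1, a2, (a1 - a2) / cell_area


def split_at_constriction(
    labeled: np.ndarray,
    axis: MedialAxis,
    call: ConstrictionCall,
    sensor_channel: np.ndarray | None = None,
    cell_id: int = 1,
    orientation: str = "pole1_first",
) -> dict:
    """Computationally divide a constricting cell into its future daughters.

    Cell pixels are partitioned by the sign of ``s(pixel) -
    s_constriction`` — every pixel lands in exactly one part, so the two
    areas sum to the cell area. When a sensor channel is supplied, its
    Otsu-segmented area is split the same way. Signed differences follow
    the same orientation convention as the pole metrics.
    """
    if not call.present:
        raise ValueError("cell has no detected constriction")
    cell = np.asarray(labeled) == cell_id
    rr, cc = np.nonzero(cell)
    s = axis.nearest_s(np.column_stack([rr, cc]))
    part1 = s < call.s_constriction
    area1 = float(np.count_nonzero(part1))
    area2 = float(len(s) - area1)
    out = {"daughter1_area_px": area1, "daughter2_area_px": area2}
    sensor1 = sensor2 = np.nan
    if sensor_channel is not None:
        seg = _otsu_foreground(np.asarray(sensor_channel, dtype=float), cell)
        seg_sel = seg[rr, cc]
        sensor1 = float(np.count_nonzero(seg_sel & part1))
        sensor2 = float(np.count_nonzero(seg_sel & ~part1))
    out["daughter1_sensor_area_px"] = sensor1
    out["daughter2_sensor_area_px"] = sensor2
    sign = 1.0 if orientation == "pole1_first" else -1.0
    out["daughter_area_diff_px"] = sign * (area1 - area2)
    out["daughter_sensor_area_diff_px"] = (
        sign * (sensor1 - sensor2) if sensor_channel is not None else np.nan
    )
    return out


def population_summary(
    records: pd.DataFrame,
    group_col: str,
    min_constricting_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-group population means of the single-cell metrics.

    Mean division asymmetry (the normalized constriction offset) is
    reported only for groups whose constricting fraction exceeds
    ``min_constricting_fraction`` (strictly); otherwise the cell is
    suppressed (NaN, with ``division_asymmetry_suppressed = True``).
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    rows = []
    for key, grp in df.groupby(group_col, sort=True):
        n = len(grp)
        constricting = grp["constriction_present"].astype(bool)
        frac_con = float(constricting.mean())
        row = {
            group_col: key,
            "n_cells": n,
            "mean_cell_area_px": float(grp["area_px"].mean()),
            "fraction_constricting": frac_con,
        }
        if "nucleoid_area_px" in grp:
            row["mean_nucleoid_area_px"] = float(grp["nucleoid_area_px"].mean())
        if "nucleoid_count" in grp:
            row["mean_nucleoid_count"] = float(grp["nucleoid_count"].mean())
            row["fraction_single_nucleoid"] = float((grp["nucleoid_count"] == 1).mean())
        suppressed = frac_con <= min_constricting_fraction
        if suppressed or not constricting.any():
            row["mean_division_asymmetry"] = np.nan
        else:
            row["mean_division_asymmetry"] = float(
                grp.loc[constricting, "constriction_norm_offset"].mean()
            )
        row["division_asymmetry_suppressed"] = bool(suppressed)
        rows.append(row)
    return pd.DataFrame(rows)


def association_stats(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation and total least-squares regression line.

    The Spearman coefficient is the Pearson correlation of mid-ranks
    (average ranks for ties). The TLS slope is the slope of the first
    principal component of the centered (x, y) cloud, with the sign fixed
    so the component's x-loading is positive; the intercept passes the
    line through the centroid. Returns (rho, slope, intercept).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman undefined")
    rho = float(sps.spearmanr(x, y).statistic)

    xc = x - x.mean()
    yc = y - y.mean()
    cov = np.cov(np.vstack([xc, yc]))
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, np.argmax(evals)]
    if pc1[0] < 0:
        pc1 = -pc1
    if pc1[0] == 0:
        raise ValueError("principal component is vertical; slope undefined")
    slope = float(pc1[1] / pc1[0])
    intercept = float(y.mean() - slope * x.mean())
    return rho, slope, intercept
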