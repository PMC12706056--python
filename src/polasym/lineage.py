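"""Microcolony clustering, genealogy, polarity and growth-rate tracking.

Lineages are identified by density-based spatial clustering of cell
centroids (DBSCAN; epsilon 45 px / minpts 4 for agarose-pad microcolonies,
25 px / 10 for mother-machine trenches). Within a trench, the "mother"
cell at the closed end retains its old pole indefinitely and is tracked
across all frames. Polarity bookkeeping follows divisions: each daughter's
pole facing the division plane is new; the opposite pole inherits the
parent's identity. Generations count divisions since the start of the
series (founders = 0).

The vertical-trench convention is used throughout: the closed end is the
minimal image row, cells are oriented vertically, and daughters are
ordered top to bottom at division.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "GenealogyError",
    "CellTrack",
    "Genealogy",
    "cluster_microcolonies",
    "build_genealogy",
    "track_mother_cells",
    "assign_polarity_generations",
    "instantaneous_growth_rate",
    "per_generation_metrics",
]


class GenealogyError(ValueError):
    pass


def cluster_microcolonies(
    centroids: np.ndarray, epsilon: float, minpts: int
) -> np.ndarray:
    """Density-based clustering of cell centroids (DBSCAN).

    A core point has at least ``minpts`` neighbors within ``epsilon``
    (itself included). Clusters are connected components of core points
    under the epsilon graph, plus their border points; unreachable points
    are labeled -1 (noise). Ties are deterministic: clusters are numbered
    by their smallest core-point index, and a border point reachable from
    several clusters joins the lowest-numbered one.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.size == 0:
        raise ValueError("no centroids to cluster")
    if epsilon <= 0 or minpts < 1:
        raise ValueError("epsilon must be > 0 and minpts >= 1")
    n = len(centroids)
    tree = cKDTree(centroids)
    neighbors = tree.query_ball_point(centroids, r=epsilon)
    core = np.array([len(nb) >= minpts for nb in neighbors])
    labels = np.full(n, -1, dtype=int)

    # connected components over core points, seeds visited in index order
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if core[k] and labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    # border points: lowest-numbered cluster among core neighbors
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        core_nb = [labels[k] for k in neighbors[i] if core[k]]
        if core_nb:
            labels[i] = min(core_nb)
    return labels


@dataclass
class CellTrack:
    cell_id: int
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    generation: int = 0
    frames: list[int] = field(default_factory=list)
    labels: dict[int, int] = field(default_factory=dict)      # frame -> mask label
    top_row: dict[int, int] = field(default_factory=dict)
    bottom_row: dict[int, int] = field(default_factory=dict)
    length_px: dict[int, float] = field(default_factory=dict)
    old_pole: str | None = None        # "top" | "bottom" | None (unknown)
    old_pole_age: int | None = None    # divisions survived by the old pole

    @property
    def new_pole(self) -> str | None:
        if self.old_pole is None:
            return None
        return "bottom" if self.old_pole == "top" else "top"


@dataclass
class Genealogy:
    cells: dict[int, CellTrack] = field(default_factory=dict)
    n_frames: int = 0

    def founders(self) -> list[CellTrack]:
        return [c for c in self.cells.values() if c.parent is None]

    def to_json_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "cells": {
                str(cid): {
                    "parent": c.parent,
                    "children": c.children,
                    "generation": c.generation,
                    "frames": c.frames,
                    "labels": {str(f): int(l) for f, l in c.labels.items()},
                    "old_pole": c.old_pole,
                    "old_pole_age": c.old_pole_age,
                }
                for cid, c in self.cells.items()
            },
        }


def _frame_props(mask: np.ndarray) -> dict[int, dict]:
    props = {}
    for lab in np.unique(mask):
        if lab == 0:
            continue
        rr, cc = np.nonzero(mask == lab)
        props[int(lab)] = {
            "top": int(rr.min()),
            "bottom": int(rr.max()),
            "length": float(rr.max() - rr.min() + 1),
            "area": len(rr),
        }
    return props


def build_genealogy(
    frames: list[np.ndarray], min_child_overlap: float = 0.3
) -> Genealogy:
    """Link labeled masks across frames into a genealogy.

    Matching is greedy by mask overlap: each next-frame cell is assigned
    to the previous-frame cell covering the largest fraction of its area
    (at least ``min_child_overlap``). A previous cell with one successor
    continues; with two successors it divides (children ordered top to
    bottom); more than two successors is a genealogy error.
    """
    if not frames:
        raise ValueError("no frames")
    gen = Genealogy(n_frames=len(frames))
    next_id = 0
    current: dict[int, int] = {}  # mask label -> cell_id, for the latest frame

    def new_cell(parent, generation):
        nonlocal next_id
        c = CellTrack(cell_id=next_id, parent=parent, generation=generation)
        gen.cells[next_id] = c
        next_id += 1
        return c

    prev_mask = None
    for f, mask in enumerate(frames):
        props = _frame_props(mask)
        if f == 0:
            for lab in sorted(props):
                c = new_cell(None, 0)
                current[lab] = c.cell_id
        else:
            assignments: dict[int, list[int]] = {}  # prev cell_id -> [labels at f]
            orphans = []
            for lab in sorted(props):
                child = mask == lab
                child_area = props[lab]["area"]
                best, best_frac = None, 0.0
                for plab, cid in current.items():
                    ov = np.count_nonzero(child & (prev_mask == plab))
                    frac = ov / child_area
                    if frac > best_frac:
                        best, best_frac = cid, frac
                if best is not None and best_frac >= min_child_overlap:
                    assignments.setdefault(best, []).append(lab)
                else:
                    orphans.append(lab)
            new_current: dict[int, int] = {}
            for cid, labs in assignments.items():
                parent = gen.cells[cid]
                if len(labs) == 1:
                    new_current[labs[0]] = cid
                elif len(labs) == 2:
                    labs = sorted(labs, key=lambda l: props[l]["top"])
                    for lab in labs:
                        child = new_cell(cid, parent.generation + 1)
                        parent.children.append(child.cell_id)
                        new_current[lab] = child.cell_id
                else:
                    raise GenealogyError(
                        f"cell {cid} maps to {len(labs)} cells at frame {f}"
                    )
            for lab in orphans:
                c = new_cell(None, 0)
                new_current[lab] = c.cell_id
            current = new_current
        for lab, cid in current.items():
            c = gen.cells[cid]
            c.frames.append(f)
            c.labels[f] = lab
            c.top_row[f] = props[lab]["top"]
            c.bottom_row[f] = props[lab]["bottom"]
            c.length_px[f] = props[lab]["length"]
        prev_mask = mask
    return gen


@dataclass
class MotherTrack:
    labels: list[int]          # mother mask label per frame
    lengths_px: list[float]
    excluded: bool = False
    reason: str = ""


def track_mother_cells(frames: list[np.ndarray]) -> MotherTrack:
    """Track the mother cell (closed trench end) across one trench's frames.

    The mother in each frame is the cell whose pole is nearest the closed
    end (minimal row; ties break to the smaller label). The lineage is
    excluded — with a reason — when any frame is empty or when the mother
    mask loses overlap continuity between consecutive frames.
    """
    labels, lengths = [], []
    prev = None
    for f, mask in enumerate(frames):
        props = _frame_props(mask)
        if not props:
            return MotherTrack([], [], excluded=True, reason=f"empty frame {f}")
        lab = min(props, key=lambda l: (props[l]["top"], l))
        if prev is not None:
            ov = np.count_nonzero((mask == lab) & prev)
            if ov == 0:
                return MotherTrack(
                    [], [], excluded=True, reason=f"tracking lost at frame {f}"
                )
        labels.append(lab)
        lengths.append(props[lab]["length"])
        prev = mask == lab
    return MotherTrack(labels, lengths)


def assign_polarity_generations(
    gen: Genealogy, founder_old_pole: str | None = None
) -> Genealogy:
    """Assign old/new pole identity and generation numbers through divisions.

    At each division the pole facing the division plane is each daughter's
    new pole; the opposite pole inherits the parent's identity, so the
    old-pole age increments only in the daughter that kept it. Founders
    have unknown polarity unless ``founder_old_pole`` pins it (mother
    machine: "top", the closed trench end).
    """
    for c in gen.founders():
        c.generation = 0
        c.old_pole = founder_old_pole
        c.old_pole_age = 1 if founder_old_pole is not None else None

    order = sorted(gen.cells.values(), key=lambda c: (c.generation, c.cell_id))
    for parent in order:
        if not parent.children:
            continue
        if len(parent.children) != 2:
            raise GenealogyError(
                f"cell {parent.cell_id} divides into {len(parent.children)} cells"
            )
        kids = [gen.cells[k] for k in parent.children]
        f = kids[0].frames[0]
        kids.sort(key=lambda c: c.top_row[f])
        top_child, bottom_child = kids
        # top child: division plane below it -> new pole at the bottom
        top_child.old_pole = "top"
        bottom_child.old_pole = "bottom"
        for child in (top_child, bottom_child):
            child.generation = parent.generation + 1
        if parent.old_pole == "top":
            top_child.old_pole_age = (parent.old_pole_age or 0) + 1
            bottom_child.old_pole_age = 1
        elif parent.old_pole == "bottom":
            bottom_child.old_pole_age = (parent.old_pole_age or 0) + 1
            top_child.old_pole_age = 1
        else:
            top_child.old_pole_age = None
            bottom_child.old_pole_age = None
    return gen


def instantaneous_growth_rate(
    lengths: np.ndarray,
    times_min: np.ndarray,
    window: int = 5,
    division_indices: list[int] | None = None,
) -> np.ndarray:
    """Sliding-window exponential growth rates from a length series.

    Within each inter-division segment, the rate at a window's center is
    the least-squares slope of ln(length) against time; units 1/min.
    Windows crossing a division are skipped (NaN). Exact on noise-free
    exponentials.
    """
    lengths = np.asarray(lengths, dtype=float)
    times = np.asarray(times_min, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    if lengths.shape != times.shape:
        raise ValueError("lengths and times must match")
    n = len(lengths)
    rates = np.full(n, np.nan)
    bounds = sorted(set([0, n] + list(division_indices or [])))
    logl = np.log(lengths)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < window:
            continue
        for start in range(a, b - window + 1):
            sl = slice(start, start + window)
            slope = np.polyfit(times[sl], logl[sl], 1)[0]
            rates[start + window // 2] = slope
    return rates


def per_generation_metrics(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = ("old_pole_sensor_area_norm", "nucleoid_offset"),
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Population mean and bootstrap CI of per-generation lineage metrics.

    ``records`` needs columns ``lineage_id``, ``generation`` and the
    requested metrics (one row per lineage per generation). The CI
    resamples lineages (not cells) with replacement, ``n_boot`` times,
    seeded.
    """
    df = pd.DataFrame(records)
    rng = np.random.default_rng(seed)
    lineages = np.array(sorted(df["lineage_id"].unique()))
    if len(lineages) == 0:
        raise ValueError("no lineages")
    alpha = (1.0 - ci) / 2.0
    boot_idx = rng.integers(0, len(lineages), size=(n_boot, len(lineages)))

    rows = []
    for g, grp in df.groupby("generation", sort=True):
        by_lineage = grp.set_index("lineage_id")
        row = {"generation": g, "n_lineages": len(grp)}
        for m in metrics:
            vals = by_lineage[m]
            row[f"mean_{m}"] = float(vals.mean())
            boots = np.empty(n_boot)
            arr = vals.reindex(lineages).to_numpy()
            for b in range(n_boot):
                sample = arr[boot_idx[b]]
                boots[b] = np.nanmean(sample)
            row[f"ci_lo_{m}"] = float(np.nanquantile(boots, alpha))
            row[f"ci_hi_{m}"] = float(np.nanquantile(boots, 1.0 - alpha))
        rows.append(row)
    return pd.DataFrame(rows)
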