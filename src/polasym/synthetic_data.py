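"""Synthetic single-cell datasets with recorded ground truth.

Everything downstream of segmentation is testable without real images:
this module draws rod-shaped cells (optionally constricted off-center),
renders fluorescence channels with controllable structure (nucleoid
blobs, pole-depleted cytoplasm, polar glycogen-sensor accumulations),
simulates mother-machine lineages with additive old-pole inheritance,
and produces FRAP traces and AFM force curves from closed-form models.
Every artifact is a pure function of its seed, and the ground-truth
tables carry everything needed to score the estimators.

Default image scale is 0.066 um/px (typical 100x sCMOS); the point-spread
function is an isotropic Gaussian (default sigma 1 px) and noise is
additive Gaussian, so the signal-to-noise ratio is the controlled
variable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .afm import ForceCurve
from .frap import FrapTrace

__all__ = [
    "GroundTruth",
    "SnapshotParams",
    "SnapshotDataset",
    "LineageModelParams",
    "LineageSeries",
    "make_cell_mask",
    "render_fluorescence",
    "make_snapshot_dataset",
    "make_lineage_series",
    "make_lineage_set",
    "make_frap_dataset",
    "make_force_curve_set",
]

PIXEL_SIZE_UM = 0.066

CHANNEL_KINDS = ("uniform", "nucleoid", "pole_depleted", "glycogen_sensor")


@dataclass
class GroundTruth:
    """Per-cell generative parameters, serialized alongside every dataset."""

    cell_id: int
    true_length_px: float
    true_width_px: float
    true_constriction_rel: float  # NaN when absent
    true_constriction_depth: float
    true_nucleoid_rel_midpoint: float
    true_pole_depletion: float    # signed: >0 depletes pole 1, <0 pole 2
    true_glycogen_pole_areas_px: tuple[float, float]
    noise_sigma: float
    psf_sigma_px: float
    seed: int
    curvature_px: float = 0.0
    base_level: float = 1000.0
    # rendering frame bookkeeping (index space of the generated image)
    origin_col: float = 0.0   # column of the pole-1 tip (x = 0)
    mid_row: float = 0.0      # straight-cell centerline row
    true_nucleoid_rel_positions: tuple[float, ...] | None = None
    centerline_rc: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("true_constriction_rel", "true_nucleoid_rel_midpoint"):
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def as_record(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("centerline_rc")
        d.pop("true_nucleoid_rel_positions")
        a1, a2 = d.pop("true_glycogen_pole_areas_px")
        d["true_glycogen_pole1_area_px"] = a1
        d["true_glycogen_pole2_area_px"] = a2
        return d


def _capsule_half_width(x: np.ndarray, length: float, width: float) -> np.ndarray:
    """Half-width of a capsule (rod with hemispherical caps) vs axial position."""
    r = width / 2.0
    hw = np.full_like(x, r, dtype=float)
    left = x < r
    hw[left] = np.sqrt(np.maximum(0.0, r**2 - (r - x[left]) ** 2))
    right = x > length - r
    hw[right] = np.sqrt(np.maximum(0.0, r**2 - (x[right] - (length - r)) ** 2))
    hw[(x < 0) | (x > length)] = -1.0
    return hw


def _constriction_factor(
    x: np.ndarray, length: float, rel: float, depth: float, half_window: float
) -> np.ndarray:
    """Smooth cosine indentation: width multiplier, 1 - depth at the waist."""
    xc = rel * length
    f = np.ones_like(x, dtype=float)
    inside = np.abs(x - xc) <= half_window
    f[inside] = 1.0 - depth * 0.5 * (1.0 + np.cos(np.pi * (x[inside] - xc) / half_window))
    return f


def make_cell_mask(
    length_px: float,
    width_px: float,
    curvature: float = 0.0,
    constriction_rel: float | None = None,
    constriction_depth: float = 0.0,
    seed: int = 0,
    margin: int = 8,
    label: int = 1,
) -> tuple[np.ndarray, GroundTruth]:
    """Labeled mask of one rod-shaped cell with optional constriction.

    The cell is a capsule of the given length and width (hemispherical
    caps), optionally bent sinusoidally (``curvature`` = peak centerline
    deflection in px) and indented by a smooth cosine constriction of
    fractional ``constriction_depth`` at relative position
    ``constriction_rel`` — the indentation affects both outline halves, so
    the minimum-width column sits at the requested position.
    """
    if width_px < 4:
        raise ValueError("degenerate cell: width must be at least 4 px")
    if length_px <= 2 * width_px:
        raise ValueError("length must exceed twice the width")
    if constriction_rel is not None and not (0.0 <= constriction_depth < 1.0):
        raise ValueError("constriction_depth must be in [0, 1)")

    rows = int(np.ceil(width_px + 2 * abs(curvature))) + 2 * margin
    cols = int(np.ceil(length_px)) + 2 * margin
    r_idx, c_idx = np.mgrid[0:rows, 0:cols]
    x = c_idx.astype(float) - margin           # axial coordinate, pole 1 at x=0
    mid_row = (rows - 1) / 2.0
    dy = curvature * np.sin(np.pi * np.clip(x, 0, length_px) / length_px)
    hw = _capsule_half_width(x[0], length_px, width_px)[np.newaxis, :]
    hw = np.broadcast_to(hw, x.shape).copy()
    if constriction_rel is not None and constriction_depth > 0:
        fac = _constriction_factor(
            x[0], length_px, constriction_rel, constriction_depth, half_window=width_px
        )
        hw = hw * fac[np.newaxis, :]
    mask = (np.abs(r_idx - (mid_row + dy)) <= hw).astype(np.uint16) * label

    xs = np.linspace(0.0, length_px, int(length_px) * 2 + 1)
    centerline = np.column_stack(
        [mid_row + curvature * np.sin(np.pi * xs / length_px), xs + margin]
    )
    gt = GroundTruth(
        cell_id=label,
        true_length_px=float(length_px),
        true_width_px=float(width_px),
        true_constriction_rel=float(constriction_rel) if constriction_rel is not None else np.nan,
        true_constriction_depth=float(constriction_depth) if constriction_rel is not None else 0.0,
        true_nucleoid_rel_midpoint=0.5,
        true_pole_depletion=0.0,
        true_glycogen_pole_areas_px=(0.0, 0.0),
        noise_sigma=0.0,
        psf_sigma_px=0.0,
        seed=int(seed),
        curvature_px=float(curvature),
        origin_col=float(margin),
        mid_row=mid_row,
        centerline_rc=centerline,
    )
    return mask, gt


def _axial_grid(mask_shape, gt: GroundTruth):
    r_idx, c_idx = np.mgrid[0 : mask_shape[0], 0 : mask_shape[1]]
    x = c_idx.astype(float) - gt.origin_col
    return r_idx, c_idx, x


def _centerline_point(gt: GroundTruth, x: float) -> tuple[float, float]:
    dy = gt.curvature_px * np.sin(np.pi * np.clip(x, 0, gt.true_length_px) / gt.true_length_px)
    return gt.mid_row + dy, gt.origin_col + x


def render_fluorescence(
    mask: np.ndarray,
    gt: GroundTruth,
    channel_kind: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one fluorescence channel for a generated cell mask.

    The structure-dependent intensity profile (times ``gt.base_level``) is
    convolved with a Gaussian PSF of ``gt.psf_sigma_px`` and additive
    Gaussian noise of ``gt.noise_sigma`` is applied.

    Channel kinds
    -------------
    uniform
        Flat cytoplasmic signal.
    nucleoid
        Gaussian blob(s) centered at the true relative midpoint(s) on the
        centerline, over a dim cytoplasmic background.
    pole_depleted
        Uniform signal minus a cosine-tapered polar deficit of fractional
        depth ``|true_pole_depletion|`` spanning 30% of the length from
        the depleted pole (pole 1 for positive values, pole 2 negative).
    glycogen_sensor
        Bright polar disks whose in-mask pixel counts are recorded back
        into ``gt.true_glycogen_pole_areas_px``, over a dim background.
    """
    if channel_kind not in CHANNEL_KINDS:
        raise ValueError(f"unknown channel_kind {channel_kind!r}")
    cell = np.asarray(mask) > 0
    base = gt.base_level
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([gt.seed, CHANNEL_KINDS.index(channel_kind)])
        )
    r_idx, _, x = _axial_grid(cell.shape, gt)
    L, W = gt.true_length_px, gt.true_width_px

    if channel_kind == "uniform":
        img = np.where(cell, base, 0.0)
    elif channel_kind == "nucleoid":
        positions = gt.true_nucleoid_rel_positions or (gt.true_nucleoid_rel_midpoint,)
        img = np.where(cell, 0.05 * base, 0.0)
        sig_x, sig_r = W / 2.5, W / 4.0
        for rel in positions:
            rc, cc = _centerline_point(gt, rel * L)
            blob = np.exp(
                -((x - (cc - gt.origin_col)) ** 2) / (2 * sig_x**2)
                - ((r_idx - rc) ** 2) / (2 * sig_r**2)
            )
            img = img + np.where(cell, base * blob, 0.0)
    elif channel_kind == "pole_depleted":
        d = gt.true_pole_depletion
        xx = x if d >= 0 else (L - x)  # distance from the depleted pole
        span = 0.30 * L
        taper = np.where(xx <= span, 0.5 * (1.0 + np.cos(np.pi * np.clip(xx, 0, span) / span)), 0.0)
        img = np.where(cell, base * (1.0 - abs(d) * taper), 0.0)
    else:  # glycogen_sensor
        img = np.where(cell, 0.2 * base, 0.0)
        realized = []
        for pole, area in zip((1, 2), gt.true_glycogen_pole_areas_px):
            if area <= 0:
                realized.append(0.0)
                continue
            radius = np.sqrt(area / np.pi)
            xc = min(radius + 1.0, L / 2.0) if pole == 1 else max(L - radius - 1.0, L / 2.0)
            rc, cc = _centerline_point(gt, xc)
            disk = ((r_idx - rc) ** 2 + (x - (cc - gt.origin_col)) ** 2) <= radius**2
            disk &= cell
            img = np.where(disk, 3.0 * base, img)
            realized.append(float(disk.sum()))
        gt.true_glycogen_pole_areas_px = (realized[0], realized[1])

    if gt.psf_sigma_px > 0:
        img = ndi.gaussian_filter(img, gt.psf_sigma_px)
    if gt.noise_sigma > 0:
        img = img + rng.normal(0.0, gt.noise_sigma, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# snapshot datasets


def _sample(rng: np.random.Generator, spec):
    """Draw one value from a scalar, (low, high) uniform range, or callable."""
    if callable(spec):
        return spec(rng)
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        return rng.uniform(*spec)
    return spec


@dataclass
class SnapshotParams:
    """Population distributions for snapshot datasets.

    Each field accepts a constant, a ``(low, high)`` uniform range, or a
    callable ``rng -> value``. Defaults sketch a transition-phase
    population: moderately variable rod geometry, ~30% of cells
    constricting with clearly off-center sites, nucleoids spread around
    mid-cell, no pole depletion and no sensor signal unless requested.
    """

    length_px: object = (55.0, 85.0)
    width_px: object = (11.0, 13.0)
    curvature_px: object = (0.0, 1.5)
    constriction_prob: float = 0.30
    constriction_rel: object = (0.45, 0.65)
    constriction_depth: object = (0.35, 0.60)
    nucleoid_rel_midpoint: object = (0.38, 0.62)
    pole_depletion: object = 0.0
    glycogen_pole1_area_px: object = 0.0
    glycogen_pole2_area_px: object = 0.0
    noise_sigma: object = 20.0
    psf_sigma_px: float = 1.0
    base_level: float = 1000.0
    channels: tuple[str, ...] = ("uniform", "nucleoid", "pole_depleted", "glycogen_sensor")


@dataclass
class SyntheticCell:
    mask: np.ndarray
    channels: dict[str, np.ndarray]
    gt: GroundTruth


@dataclass
class SnapshotDataset:
    cells: list[SyntheticCell]
    table: pd.DataFrame
    seed: int
    params: SnapshotParams


def make_snapshot_dataset(
    n_cells: int, params: SnapshotParams | None = None, seed: int = 0
) -> SnapshotDataset:
    """A reproducible set of single-cell masks, channels and ground truth."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    params = params or SnapshotParams()
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        cell_seed = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(cell_seed)
        width = float(_sample(crng, params.width_px))
        length = float(_sample(crng, params.length_px))
        length = max(length, 2 * width + 2.0)
        constricting = crng.random() < params.constriction_prob
        rel = float(_sample(crng, params.constriction_rel)) if constricting else None
        depth = float(_sample(crng, params.constriction_depth)) if constricting else 0.0
        mask, gt = make_cell_mask(
            length, width,
            curvature=float(_sample(crng, params.curvature_px)),
            constriction_rel=rel, constriction_depth=depth, seed=cell_seed,
        )
        gt.cell_id = i
        gt.true_nucleoid_rel_midpoint = float(
            np.clip(_sample(crng, params.nucleoid_rel_midpoint), 0.0, 1.0)
        )
        gt.true_pole_depletion = float(_sample(crng, params.pole_depletion))
        gt.true_glycogen_pole_areas_px = (
            float(_sample(crng, params.glycogen_pole1_area_px)),
            float(_sample(crng, params.glycogen_pole2_area_px)),
        )
        gt.noise_sigma = float(_sample(crng, params.noise_sigma))
        gt.psf_sigma_px = params.psf_sigma_px
        gt.base_level = params.base_level
        chans = {kind: render_fluorescence(mask, gt, kind) for kind in params.channels}
        cells.append(SyntheticCell(mask, chans, gt))
    table = pd.DataFrame([c.gt.as_record() for c in cells])
    return SnapshotDataset(cells, table, seed, params)


# ---------------------------------------------------------------------------
# mother-machine lineages


@dataclass
class LineageModelParams:
    """Additive-inheritance model of old-pole glycogen accumulation.

    Per generation g the old-pole sensor area follows
    ``a_g = inheritance_fraction * a_{g-1} + synthesis_per_gen_px`` and
    the true nucleoid offset toward the new pole is
    ``offset_coupling * a_g / cell_area + N(0, division_noise_sd)``; the
    division plane is displaced toward the new pole by that offset.
    """

    generations: int = 8
    growth_rate_per_min: float = 0.010
    inheritance_fraction: float = 0.95
    synthesis_per_gen_px: float = 30.0
    offset_coupling: float = 1.0
    division_noise_sd: float = 0.015
    seed: int = 0
    # trench layout and imaging cadence
    frame_dt_min: float = 10.0
    birth_length_px: float = 45.0
    width_px: float = 12.0
    trench_depth_px: int = 300
    trench_width_px: int = 40
    initial_pole_area_px: float = 0.0
    noise_sigma: float = 20.0
    psf_sigma_px: float = 1.0
    base_level: float = 1000.0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0.0 <= self.inheritance_fraction <= 1.0):
            raise ValueError("inheritance_fraction must be in [0, 1]")
        if self.synthesis_per_gen_px < 0:
            raise ValueError("synthesis_per_gen_px must be >= 0")

    @property
    def frames_per_generation(self) -> int:
        return max(2, round(np.log(2.0) / (self.growth_rate_per_min * self.frame_dt_min)))


@dataclass
class _SimCell:
    uid: int
    length: float
    old_pole: str             # "top" or "bottom"
    pole_areas: tuple[float, float]  # sensor area at (top, bottom) pole
    nucleoid_rel_from_top: float
    generation: int
    parent: int | None


@dataclass
class LineageSeries:
    lineage_id: int
    frames: list[dict]            # {"mask", "channels", "labels": {label: uid}, "mother_label"}
    genealogy: dict               # uid -> {"parent", "children", "generation", "old_pole"}
    per_generation: pd.DataFrame
    params: LineageModelParams
    division_frames: list[int]


def _render_trench_frame(cells: list[_SimCell], params: LineageModelParams, rng):
    H, Wt = params.trench_depth_px, params.trench_width_px
    mask = np.zeros((H, Wt), dtype=np.uint16)
    nuc = np.zeros((H, Wt), dtype=float)
    sen = np.zeros((H, Wt), dtype=float)
    r_idx, c_idx = np.mgrid[0:H, 0:Wt]
    mid_col = (Wt - 1) / 2.0
    base = params.base_level
    y = 2.0  # closed end margin
    labels = {}
    visible = []
    for order, cell in enumerate(cells):
        top, bottom = y, y + cell.length
        y = bottom + 1.0
        if top >= H - 2:
            break
        bottom = min(bottom, H - 2.0)
        if bottom - top < 8:
            break
        label = order + 1
        r = params.width_px / 2.0
        yy = r_idx.astype(float)
        hw = np.full((H, Wt), -1.0)
        inside_ax = (yy >= top) & (yy <= bottom)
        hw[inside_ax] = r
        capt = yy < top + r
        hw = np.where(capt & inside_ax, np.sqrt(np.maximum(0, r**2 - (top + r - yy) ** 2)), hw)
        capb = yy > bottom - r
        hw = np.where(capb & inside_ax, np.sqrt(np.maximum(0, r**2 - (yy - (bottom - r)) ** 2)), hw)
        body = np.abs(c_idx - mid_col) <= hw
        mask[body] = label
        labels[label] = cell.uid
        visible.append((label, cell, top, bottom))

        nuc[body] = 0.05 * base
        sen[body] = 0.2 * base
        # nucleoid blob at the true relative midpoint, measured from the top pole
        rc = top + cell.nucleoid_rel_from_top * (bottom - top)
        sig_ax, sig_tr = params.width_px / 2.5, params.width_px / 4.0
        blob = np.exp(
            -((r_idx - rc) ** 2) / (2 * sig_ax**2) - ((c_idx - mid_col) ** 2) / (2 * sig_tr**2)
        )
        nuc = np.where(body, nuc + base * blob, nuc)
        for pole, area in zip(("top", "bottom"), cell.pole_areas):
            if area <= 0:
                continue
            radius = np.sqrt(area / np.pi)
            yc = top + radius + 1.0 if pole == "top" else bottom - radius - 1.0
            disk = ((r_idx - yc) ** 2 + (c_idx - mid_col) ** 2) <= radius**2
            sen = np.where(disk & body, 3.0 * base, sen)

    if params.psf_sigma_px > 0:
        nuc = ndi.gaussian_filter(nuc, params.psf_sigma_px)
        sen = ndi.gaussian_filter(sen, params.psf_sigma_px)
    if params.noise_sigma > 0:
        nuc = nuc + rng.normal(0, params.noise_sigma, nuc.shape)
        sen = sen + rng.normal(0, params.noise_sigma, sen.shape)
    mother_label = min(labels) if labels else None
    return {
        "mask": mask,
        "channels": {"nucleoid": nuc, "glycogen_sensor": sen},
        "labels": labels,
        "mother_label": mother_label,
    }


def make_lineage_series(params: LineageModelParams, lineage_id: int = 0) -> LineageSeries:
    """Simulate one mother-machine trench over the requested generations.

    The mother cell sits at the closed (top) end and keeps its old pole
    there. Each generation its old-pole sensor area follows the additive
    inheritance model, the nucleoid shifts toward the new (bottom) pole by
    the coupled offset, and division is displaced the same way, so the
    old-pole daughter is the larger one. Up to two non-mother cells remain
    visible below the mother before being pushed out of the trench.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, lineage_id]))
    fpg = params.frames_per_generation
    growth_per_frame = 2.0 ** (1.0 / fpg)

    next_uid = 0

    def make_uid():
        nonlocal next_uid
        u = next_uid
        next_uid += 1
        return u

    genealogy: dict[int, dict] = {}
    per_gen_rows = []
    frames = []
    division_frames: list[int] = []

    area_scale = params.birth_length_px * params.width_px  # nominal cell area
    a_prev = params.initial_pole_area_px
    mother = _SimCell(
        make_uid(), params.birth_length_px, "top", (a_prev, 0.0), 0.5, 0, None
    )
    genealogy[mother.uid] = {"parent": None, "children": [], "generation": 0, "old_pole": "top"}
    others: list[_SimCell] = []

    frame = 0
    for g in range(1, params.generations + 1):
        a_g = params.inheritance_fraction * a_prev + params.synthesis_per_gen_px
        offset = params.offset_coupling * a_g / (2.0 * area_scale) + rng.normal(
            0.0, params.division_noise_sd
        )
        offset = float(np.clip(offset, -0.40, 0.40))
        mother.pole_areas = (a_g, mother.pole_areas[1])
        mother.nucleoid_rel_from_top = 0.5 + offset

        # sizer homeostasis: the mother divides on reaching twice the
        # nominal birth length, keeping cell size stable across generations
        # despite the asymmetric division displacement
        meas_frame = None
        division_length = 2.0 * params.birth_length_px
        while True:
            fr = _render_trench_frame([mother] + others, params, rng)
            frames.append(fr)
            meas_frame = frame
            frame += 1
            mother.length *= growth_per_frame
            for c in others:
                c.length *= growth_per_frame
            if mother.length >= division_length:
                break
        # measured cell area of the mother at the last pre-division frame
        meas_mask = frames[meas_frame]["mask"]
        mother_area = float(np.count_nonzero(meas_mask == frames[meas_frame]["mother_label"]))
        per_gen_rows.append(
            {
                "lineage_id": lineage_id,
                "generation": g,
                "true_pole_area_px": a_g,
                "true_offset": offset,
                "mother_area_px": mother_area,
                "true_pole_area_norm": a_g / mother_area if mother_area else np.nan,
                "measurement_frame": meas_frame,
            }
        )

        # division: plane displaced toward the new (bottom) pole
        top_frac = 0.5 + offset
        top_len = mother.length * top_frac
        bottom_len = mother.length - top_len
        top_uid, bottom_uid = make_uid(), make_uid()
        a_inherit = params.inheritance_fraction * a_g
        a_rest = (1.0 - params.inheritance_fraction) * a_g
        top_child = _SimCell(
            top_uid, top_len, "top", (a_inherit, 0.0), 0.5, g, mother.uid
        )
        bottom_child = _SimCell(
            bottom_uid, bottom_len, "bottom", (a_rest, mother.pole_areas[1]), 0.5, g, mother.uid
        )
        genealogy[mother.uid]["children"] = [top_uid, bottom_uid]
        genealogy[top_uid] = {
            "parent": mother.uid, "children": [], "generation": g, "old_pole": "top",
        }
        genealogy[bottom_uid] = {
            "parent": mother.uid, "children": [], "generation": g, "old_pole": "bottom",
        }
        division_frames.append(frame)
        others = ([bottom_child] + others)[:2]
        mother = top_child
        a_prev = a_inherit

    return LineageSeries(
        lineage_id, frames, genealogy, pd.DataFrame(per_gen_rows), params, division_frames
    )


def make_lineage_set(
    n_lineages: int, params: LineageModelParams | None = None
) -> list[LineageSeries]:
    """Independent trench lineages sharing parameters, seeded per lineage."""
    params = params or LineageModelParams()
    return [make_lineage_series(params, lineage_id=i) for i in range(n_lineages)]


# ---------------------------------------------------------------------------
# FRAP traces


def make_frap_dataset(
    tau_s: float = 10.0,
    bleach_depth: float = 0.8,
    plateau: float = 1.0,
    photobleach_rate: float = 0.005,
    frame_dt_s: float = 0.05,
    n_frames: int = 600,
    n_control_cells: int = 3,
    noise_sigma: float = 0.01,
    seed: int = 0,
    baseline: float = 1.0,
    n_bleached: int = 1,
    pre_bleach_frames: int = 10,
) -> tuple[list[FrapTrace], dict]:
    """Single-exponential FRAP recovery traces under global photobleaching.

    Bleached trace (t >= t0):
    ``baseline * exp(-photobleach_rate * t)
    * [1 - bleach_depth * (1 - plateau * (1 - exp(-(t - t0)/tau)))]``,
    which for a fully mobile pool (plateau = 1) is
    ``baseline * exp(-k t) * [1 - bleach_depth * exp(-(t - t0)/tau)]``.
    Controls decay as ``baseline * exp(-k t)``. The default cadence is a
    50-ms frame interval over 30 s.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if n_control_cells < 1:
        raise ValueError("need at least one control cell")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_dt_s
    t0 = pre_bleach_frames * frame_dt_s
    decay = baseline * np.exp(-photobleach_rate * t)

    traces = []
    for i in range(n_bleached):
        recover = np.ones(n_frames)
        post = t >= t0
        recover[post] = 1.0 - bleach_depth * (
            1.0 - plateau * (1.0 - np.exp(-(t[post] - t0) / tau_s))
        )
        raw = decay * recover
        if noise_sigma > 0:
            raw = raw + rng.normal(0, noise_sigma, n_frames)
        traces.append(
            FrapTrace(t, raw, bleach_index=pre_bleach_frames, is_control=False, cell_id=f"bleach{i}")
        )
    for i in range(n_control_cells):
        raw = decay.copy()
        if noise_sigma > 0:
            raw = raw + rng.normal(0, noise_sigma, n_frames)
        traces.append(
            FrapTrace(t, raw, bleach_index=pre_bleach_frames, is_control=True, cell_id=f"ctrl{i}")
        )
    gt = {
        "tau_s": tau_s,
        "half_time_s": tau_s * np.log(2.0),
        "bleach_depth": bleach_depth,
        "plateau": plateau,
        "photobleach_rate": photobleach_rate,
        "t0_s": t0,
        "seed": seed,
    }
    return traces, gt


# ---------------------------------------------------------------------------
# AFM force curves


def make_force_curve_set(
    contact_z_nm: float = 500.0,
    segment_slopes: tuple[float, ...] = (0.05,),
    segment_len_nm: tuple[float, ...] | None = None,
    rupture_depth_nm: float | None = None,
    rupture_drop_nN: float = 0.0,
    noise_sigma: float = 0.0,
    n_curves: int = 1,
    seed: int = 0,
    z_max_nm: float = 2000.0,
    dz_nm: float = 1.0,
    spring_constant: float = 0.35,
) -> tuple[list[ForceCurve], dict]:
    """Piecewise-linear approach force curves with optional rupture.

    After the contact point the force rises piecewise-linearly with the
    given slopes (N/m) over the given segment lengths (the last segment
    extends to the end of the 2-um ramp); an optional instantaneous force
    drop of ``rupture_drop_nN`` occurs at ``rupture_depth_nm`` of
    indentation. Ground truth (contact/rupture sample indices, slopes) is
    returned alongside.
    """
    slopes = tuple(float(s) for s in segment_slopes)
    if any(s < 0 for s in slopes):
        raise ValueError("slopes must be >= 0")
    if segment_len_nm is None:
        segment_len_nm = ()
    if len(segment_len_nm) not in (len(slopes), len(slopes) - 1):
        raise ValueError("segment lengths must match the slopes (last segment may be open)")
    if contact_z_nm >= z_max_nm:
        raise ValueError("contact beyond the ramp")
    max_depth = z_max_nm - contact_z_nm
    if rupture_depth_nm is not None and not (0 < rupture_depth_nm < max_depth):
        raise ValueError("rupture depth outside the indentation range")

    z = np.arange(0.0, z_max_nm + dz_nm / 2, dz_nm)
    depth = np.maximum(0.0, z - contact_z_nm)
    # breakpoints of the piecewise-linear indentation response
    bps = np.concatenate([[0.0], np.cumsum(segment_len_nm)])
    if len(bps) < len(slopes) + 1:
        bps = np.concatenate([bps, [max_depth + dz_nm]])
    force = np.zeros_like(z)
    for k, slope in enumerate(slopes):
        lo, hi = bps[k], bps[k + 1]
        seg = np.clip(depth, lo, hi) - lo
        force += slope * seg
    contact_index = int(np.searchsorted(z, contact_z_nm, side="right"))
    rupture_index = None
    if rupture_depth_nm is not None and rupture_drop_nN > 0:
        rupture_index = int(np.argmax(depth >= rupture_depth_nm))
        force[rupture_index:] -= rupture_drop_nN

    rng = np.random.default_rng(seed)
    curves = []
    for i in range(n_curves):
        f = force.copy()
        if noise_sigma > 0:
            f = f + rng.normal(0, noise_sigma, f.shape)
        curves.append(
            ForceCurve(z, f, spring_constant_N_per_m=spring_constant, position=i)
        )
    gt = {
        "contact_index": contact_index,
        "contact_z_nm": contact_z_nm,
        "rupture_index": rupture_index,
        "rupture_depth_nm": rupture_depth_nm,
        "rupture_drop_nN": rupture_drop_nN,
        "segment_slopes": slopes,
        "seed": seed,
    }
    return curves, gt
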