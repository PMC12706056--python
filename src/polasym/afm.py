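"""AFM approach force-curve analysis.

Operations on force-distance approach curves recorded on immobilized
bacteria: contact-point detection, surface stiffness from the terminal
portion of the curve, depth-resolved stiffness tomography along the cell's
medial axis, membrane-rupture detection, post-rupture (intracellular)
stiffness, and cell height from contact-point grids.

Conventions
-----------
``z_nm`` is the piezo extension along the approach, increasing toward the
sample; force is in nN. Slopes of force vs. z are therefore in nN/nm,
numerically equal to N/m, and are reported as raw stiffness (no contact
mechanics model is fitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "StiffnessTomogram",
    "find_contact_point",
    "surface_stiffness",
    "stiffness_tomogram",
    "detect_rupture",
    "penetration_stiffness",
    "cell_height",
]


@dataclass
class ForceCurve:
    """A single approach force-distance curve.

    Parameters
    ----------
    z_nm : ndarray
        Tip-sample piezo extension, monotonically increasing along the
        approach, in nm.
    force_nN : ndarray
        Vertical force in nN, same length as ``z_nm``.
    spring_constant_N_per_m : float
        Cantilever spring constant (metadata; curves are assumed already
        converted to force).
    position : tuple or str or None
        Scan-grid coordinate or an on/off-target label.
    """

    z_nm: np.ndarray
    force_nN: np.ndarray
    spring_constant_N_per_m: float = 0.35
    position: object = None
    cell_id: object = None
    label: str | None = None
    contact_index: int | None = None
    rupture_index: int | None = None

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.z_nm.shape != self.force_nN.shape:
            raise ValueError("z and force must have the same length")
        if self.z_nm.ndim != 1:
            raise ValueError("force curve arrays must be 1-D")
        dz = np.diff(self.z_nm)
        if len(dz) and not np.all(dz > 0):
            raise ValueError("z_nm must be strictly increasing along approach")
        if not np.all(np.isfinite(self.force_nN)):
            raise ValueError("force contains non-finite samples")


@dataclass
class StiffnessTomogram:
    """Depth-resolved stiffness along a cell's medial axis.

    ``stiffness[i, j]`` is the force-curve slope (N/m) at axial position
    ``positions[i]`` within indentation bin ``j`` (bins tile the
    indentation range in ``bin_nm`` steps after the contact point).
    ``deviation`` subtracts, per depth bin, the median across positions,
    so its per-bin median is zero by construction.
    """

    positions: np.ndarray
    depth_bin_edges_nm: np.ndarray
    stiffness: np.ndarray
    deviation: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        med = np.nanmedian(self.stiffness, axis=0, keepdims=True)
        self.deviation = self.stiffness - med


def find_contact_point(
    curve: ForceCurve,
    noise_window: int = 50,
    k_sigma: float = 5.0,
    sustain: int = 10,
) -> int | None:
    """Detect the tip-sample contact point by baseline threshold crossing.

    The baseline mean and standard deviation are estimated from the first
    ``noise_window`` samples. Contact is the first index where the force
    exceeds ``baseline + k_sigma * sigma`` and stays above for ``sustain``
    consecutive samples. Returns ``None`` (curve flagged) when no such
    crossing exists.
    """
    f = curve.force_nN
    if len(f) < noise_window:
        raise ValueError(f"need at least {noise_window} pre-contact samples")
    base = f[:noise_window]
    mu, sigma = float(np.mean(base)), float(np.std(base))
    # noise-free baselines would give a zero threshold band; keep a tiny
    # positive margin so contact is still the first positive deflection
    thr = mu + k_sigma * max(sigma, 1e-12)
    above = f > thr
    # first index from which `sustain` consecutive samples are above threshold
    if sustain > 1:
        ok = np.convolve(above.astype(int), np.ones(sustain, dtype=int), "valid") == sustain
        idx = np.flatnonzero(ok)
    else:
        idx = np.flatnonzero(above)
    if len(idx) == 0:
        curve.contact_index = None
        return None
    curve.contact_index = int(idx[0])
    return curve.contact_index


def surface_stiffness(curve: ForceCurve, force_fraction: float = 0.8, min_samples: int = 5) -> float:
    """Stiffness (N/m) from the terminal high-force portion of the approach.

    Fits a least-squares slope of force vs. z over the contiguous run of
    samples at the end of the curve whose force lies between
    ``force_fraction`` (default 80%) and 100% of the maximum force.
    """
    f, z = curve.force_nN, curve.z_nm
    fmax = float(np.max(f))
    if fmax <= 0:
        raise ValueError("curve never leaves the baseline; no stiffness defined")
    lo = force_fraction * fmax
    # walk back from the end while force stays inside the window
    i = len(f)
    while i > 0 and f[i - 1] >= lo:
        i -= 1
    sel = slice(i, len(f))
    if len(f[sel]) < min_samples:
        raise ValueError(f"fewer than {min_samples} samples in the {force_fraction:.0%}-100% force window")
    slope = np.polyfit(z[sel], f[sel], 1)[0]
    return float(slope)


def _binned_slopes(
    curve: ForceCurve, bin_nm: float, n_bins: int, min_samples: int
) -> np.ndarray:
    ci = curve.contact_index
    if ci is None:
        ci = find_contact_point(curve)
    if ci is None:
        raise ValueError("contact point not found for tomography curve")
    depth = curve.z_nm[ci:] - curve.z_nm[ci]
    force = curve.force_nN[ci:]
    out = np.full(n_bins, np.nan)
    which = np.floor(depth / bin_nm).astype(int)
    for b in range(n_bins):
        sel = which == b
        if np.count_nonzero(sel) >= min_samples:
            out[b] = np.polyfit(depth[sel], force[sel], 1)[0]
    return out


def stiffness_tomogram(
    curves: list[ForceCurve],
    positions=None,
    bin_nm: float = 20.0,
    min_samples: int = 5,
) -> StiffnessTomogram:
    """Depth-resolved stiffness map along the medial axis.

    Every consecutive ``bin_nm`` (default 20 nm) indentation segment after
    the contact point is fitted with a least-squares slope, for each curve
    (axial position). Bins with fewer than ``min_samples`` samples are
    dropped (NaN). The deviation map subtracts the per-depth median across
    positions.
    """
    if len(curves) < 3:
        raise ValueError("tomography requires at least 3 axial positions")
    if positions is None:
        positions = [c.position if c.position is not None else i for i, c in enumerate(curves)]
    max_depth = 0.0
    for c in curves:
        ci = c.contact_index if c.contact_index is not None else find_contact_point(c)
        if ci is None:
            raise ValueError("contact point not found for tomography curve")
        max_depth = max(max_depth, float(c.z_nm[-1] - c.z_nm[ci]))
    n_bins = int(np.floor(max_depth / bin_nm))
    if n_bins < 1:
        raise ValueError("indentation range shorter than one depth bin")
    stiff = np.vstack([_binned_slopes(c, bin_nm, n_bins, min_samples) for c in curves])
    edges = np.arange(n_bins + 1) * bin_nm
    return StiffnessTomogram(np.asarray(positions), edges, stiff)


def detect_rupture(curve: ForceCurve, min_drop_nN: float = 0.5, span: int = 3) -> int | None:
    """Locate a membrane rupture event on the approach curve.

    Rupture is the first post-contact sample whose force is at least
    ``min_drop_nN`` below the maximum over the preceding ``span`` samples,
    while z continues to advance (guaranteed by the approach ordering).
    Returns ``None`` when no drop occurs — a valid outcome for curves that
    never penetrate.
    """
    ci = curve.contact_index
    if ci is None:
        ci = find_contact_point(curve)
    if ci is None:
        raise ValueError("contact point required before rupture detection")
    f = curve.force_nN
    for i in range(ci + 1, len(f)):
        recent = f[max(ci, i - span): i]
        if len(recent) and np.max(recent) - f[i] >= min_drop_nN:
            curve.rupture_index = int(i)
            return curve.rupture_index
    curve.rupture_index = None
    return None


def post_rupture_slope(curve: ForceCurve, min_samples: int = 5) -> float:
    """Least-squares slope (N/m) from the rupture point to the curve end."""
    ri = curve.rupture_index
    if ri is None:
        ri = detect_rupture(curve)
    if ri is None:
        raise ValueError("no rupture event on this curve")
    if len(curve.z_nm) - ri < min_samples:
        raise ValueError("too few samples after rupture")
    return float(np.polyfit(curve.z_nm[ri:], curve.force_nN[ri:], 1)[0])


def penetration_stiffness(
    curves: list[ForceCurve], min_drop_nN: float = 0.5
) -> pd.DataFrame:
    """Per-cell median intracellular stiffness from puncturing force curves.

    For each curve exhibiting a rupture, the post-rupture slope is fitted;
    curves without rupture are excluded and counted. Medians are taken per
    (cell, on/off-target label) group, typically over the 8x8 = 64 curves
    recorded per position.
    """
    rows = []
    for c in curves:
        if c.contact_index is None:
            find_contact_point(c)
        ri = detect_rupture(c, min_drop_nN=min_drop_nN)
        slope = np.nan
        if ri is not None and len(c.z_nm) - ri >= 5:
            slope = post_rupture_slope(c)
        rows.append({
            "cell_id": c.cell_id,
            "label": c.label,
            "ruptured": ri is not None,
            "post_rupture_slope_N_per_m": slope,
        })
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["cell_id", "label"], dropna=False)
        .agg(
            n_curves=("ruptured", "size"),
            n_ruptured=("ruptured", "sum"),
            median_stiffness_N_per_m=("post_rupture_slope_N_per_m", "median"),
        )
        .reset_index()
    )
    out["flagged_no_rupture"] = out["n_ruptured"] == 0
    return out


def cell_height(contact_z_grid: np.ndarray, cell_footprint: np.ndarray) -> tuple[np.ndarray, float]:
    """Cell height from a grid of contact-point z values.

    The glass reference is the median contact z over off-cell grid points;
    height at each on-cell point is ``glass_z - contact_z`` (the tip meets
    a taller surface earlier along the approach). Returns the height grid
    (NaN off-cell) and the maximum height over the footprint. Invariant to
    any global z offset, which cancels in the difference.
    """
    contact_z_grid = np.asarray(contact_z_grid, dtype=float)
    cell_footprint = np.asarray(cell_footprint, dtype=bool)
    if contact_z_grid.shape != cell_footprint.shape:
        raise ValueError("grid and footprint shapes differ")
    off = ~cell_footprint
    if not off.any():
        raise ValueError("no off-cell reference points")
    glass_z = float(np.median(contact_z_grid[off]))
    heights = np.where(cell_footprint, glass_z - contact_z_grid, np.nan)
    if cell_footprint.any():
        summary = float(np.nanmax(heights))
    else:
        summary = 0.0
    return heights, summary
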