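"""Per-cell morphometry from labeled segmentation masks.

Implements the medial-axis based geometry stack for rod-shaped bacteria:

* ``compute_medial_axis`` — a subpixel centerline obtained by fitting the
  transverse center of the cell as a polynomial of the axial coordinate,
  weighted by the squared interior distance transform, then extended to
  the mask boundary and resampled at 1-px arc-length steps.
* ``width_profiles`` — left/right half-widths measured along the local
  normal at every axis sample.
* ``detect_constriction`` — peak finding on the smoothed, normalized,
  inverted half-width profiles; a constriction is called when both cell
  halves show a matching width minimum.
* ``pole_regions`` — the two polar masks (30% of cell length from each
  pole, eroded 2 px) used for pole-resolved intensity statistics.

Coordinates are 0-based (row, col); arc length is in px; all intervals
are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "MedialAxis",
    "WidthProfile",
    "ConstrictionCall",
    "PoleRegions",
    "AxisUndefinedError",
    "morphology_features",
    "feature_filter",
    "compute_medial_axis",
    "width_profiles",
    "detect_constriction",
    "pole_regions",
]


class AxisUndefinedError(ValueError):
    """Raised when a cell is too round (or degenerate) for a medial axis."""


@dataclass
class MedialAxis:
    """Ordered subpixel centerline of one cell.

    ``points[0]`` is pole 1, fixed deterministically as the endpoint with
    the smaller (row, col) in lexicographic order; biological old/new
    polarity is assigned only by the lineage layer.
    """

    points: np.ndarray  # (N, 2) float, (row, col)
    arclen: np.ndarray  # (N,), cumulative arc length, arclen[0] == 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arclen = np.asarray(self.arclen, dtype=float)
        if len(self.points) != len(self.arclen):
            raise ValueError("points and arclen length mismatch")
        if np.any(np.diff(self.arclen) <= 0):
            raise ValueError("arc length must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arclen[-1])

    def nearest_s(self, coords: np.ndarray) -> np.ndarray:
        """Arc-length coordinate of the nearest axis point for (row, col) coords."""
        tree = cKDTree(self.points)
        _, idx = tree.query(np.atleast_2d(coords))
        return self.arclen[idx]


@dataclass
class WidthProfile:
    """Raw half-width samples along the axis; NaN marks invalid samples
    (normals that fail to intersect the outline, e.g. at the caps)."""

    s: np.ndarray
    half_width_left: np.ndarray
    half_width_right: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.s)
        if len(self.half_width_left) != n or len(self.half_width_right) != n:
            raise ValueError("profile arrays must match the axis sample count")

    @property
    def total_width(self) -> np.ndarray:
        return self.half_width_left + self.half_width_right


@dataclass
class ConstrictionCall:
    present: bool
    s_constriction: float = np.nan
    rel_signed_position: float = np.nan  # s/L - 0.5; 0 = center, +/-0.5 = poles
    norm_offset: float = np.nan          # |rel_signed_position|
    reason: str = ""


@dataclass
class PoleRegions:
    """Polar pixel masks used for pole-resolved intensity statistics."""

    pole1: np.ndarray  # boolean mask, pixels nearest the pole-1 axis end
    pole2: np.ndarray
    fraction_of_length: float = 0.30
    erosion_px: int = 2

    def __post_init__(self) -> None:
        if np.logical_and(self.pole1, self.pole2).any():
            raise ValueError("pole regions must be disjoint")


def _cell_mask(labeled: np.ndarray, cell_id: int) -> np.ndarray:
    labeled = np.asarray(labeled)
    mask = labeled == cell_id
    if not mask.any():
        raise KeyError(f"label {cell_id} not present in mask")
    return mask


def _circularity(mask: np.ndarray) -> float:
    area = int(mask.sum())
    perim = measure.perimeter(mask)
    if perim == 0:
        return 1.0
    return float(4.0 * np.pi * area / perim**2)


def morphology_features(labeled: np.ndarray, cell_id: int) -> dict:
    """Area, medial-axis length, width and circularity of one cell.

    * area: pixel count
    * length: medial-axis arc length (NaN when the axis is undefined)
    * width: 2 x median half-width over valid interior profile samples
    * circularity: 4*pi*area / perimeter**2
    """
    mask = _cell_mask(labeled, cell_id)
    area = int(mask.sum())
    circ = _circularity(mask)
    length = np.nan
    width = np.nan
    try:
        axis = compute_medial_axis(labeled, cell_id)
        length = axis.length
        prof = width_profiles(labeled, axis, cell_id=cell_id)
        hw = np.concatenate([prof.half_width_left, prof.half_width_right])
        hw = hw[np.isfinite(hw)]
        if len(hw):
            width = 2.0 * float(np.median(hw))
    except AxisUndefinedError:
        pass
    return {
        "cell_id": cell_id,
        "area_px": area,
        "length_px": length,
        "width_px": width,
        "circularity": circ,
    }


def feature_filter(
    records, thresholds: dict[str, tuple[float | None, float | None]]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records whose thresholded features fall inside their intervals.

    ``thresholds`` maps a feature name to a closed ``(min, max)`` interval;
    either bound may be ``None`` (open). Returns the kept records and a
    per-feature count of removals (a record failing several features
    counts once per feature).
    """
    df = pd.DataFrame(records)
    keep = np.ones(len(df), dtype=bool)
    removed: dict[str, int] = {}
    for feat, (lo, hi) in thresholds.items():
        vals = df[feat].to_numpy()
        ok = np.ones(len(df), dtype=bool)
        if lo is not None:
            ok &= vals >= lo
        if hi is not None:
            ok &= vals <= hi
        removed[feat] = int((~ok).sum())
        keep &= ok
    return df[keep].reset_index(drop=True), removed


def compute_medial_axis(
    labeled: np.ndarray,
    cell_id: int = 1,
    degree: int = 3,
    circularity_cap: float = 0.9,
    step_px: float = 1.0,
) -> MedialAxis:
    """Subpixel centerline from a weighted polynomial fit to the mask interior.

    The region is rotated (in coordinates, not pixels) onto its principal
    axis; the transverse pixel coordinate is fitted as a ``degree``-order
    polynomial of the axial coordinate, with the interior distance
    transform entering the least-squares problem so that deep-interior
    pixels dominate (residuals are weighted by the distance transform,
    i.e. the objective weights are its square). The fitted curve is
    extended until it exits the mask and resampled at ``step_px``
    arc-length steps.

    Raises
    ------
    AxisUndefinedError
        For near-circular regions (circularity >= ``circularity_cap``) or
        disconnected labels, where a medial axis is meaningless.
    """
    mask = _cell_mask(labeled, cell_id)
    n_comp = ndi.label(mask)[1]
    if n_comp != 1:
        raise AxisUndefinedError(f"label {cell_id} is not a single connected region")
    circ = _circularity(mask)
    if circ >= circularity_cap:
        raise AxisUndefinedError(
            f"cell {cell_id} too round for a medial axis (circularity {circ:.2f})"
        )

    rr, cc = np.nonzero(mask)
    coords = np.column_stack([rr, cc]).astype(float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    e_axis = evecs[:, np.argmax(evals)]   # principal (long) direction
    e_perp = evecs[:, np.argmin(evals)]

    u = centered @ e_axis
    v = centered @ e_perp
    edt = ndi.distance_transform_edt(mask)
    w = edt[rr, cc]  # np.polyfit squares these weights internally -> edt^2
    deg = min(degree, max(1, len(np.unique(np.round(u))) - 1))
    poly = np.polynomial.Polynomial.fit(u, v, deg, w=w)

    # sample the fitted curve finely, extending beyond the data range so the
    # axis reaches the mask boundary, then keep the inside run
    half_span = (u.max() - u.min()) / 2.0 + edt.max() + 2.0
    u_fine = np.arange(-half_span, half_span, 0.25) + (u.max() + u.min()) / 2.0
    v_fine = poly(u_fine)
    pts = centroid + np.outer(u_fine, e_axis) + np.outer(v_fine, e_perp)
    ri = np.clip(np.round(pts[:, 0]).astype(int), 0, mask.shape[0] - 1)
    ci = np.clip(np.round(pts[:, 1]).astype(int), 0, mask.shape[1] - 1)
    inside = mask[ri, ci]
    # contiguous inside run containing the sample nearest the centroid
    center_idx = int(np.argmin(np.abs(u_fine - (u.max() + u.min()) / 2.0)))
    if not inside[center_idx]:
        inside_idx = np.flatnonzero(inside)
        if len(inside_idx) == 0:
            raise AxisUndefinedError(f"fitted axis misses the mask for cell {cell_id}")
        center_idx = int(inside_idx[np.argmin(np.abs(inside_idx - center_idx))])
    lo = center_idx
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = center_idx
    while hi < len(inside) - 1 and inside[hi + 1]:
        hi += 1
    pts = pts[lo: hi + 1]
    if len(pts) < 3:
        raise AxisUndefinedError(f"axis degenerate for cell {cell_id}")

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s_raw = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_raw[-1]
    n_samples = max(int(np.floor(total / step_px)) + 1, 2)
    s_new = np.linspace(0.0, total, n_samples)
    pts_new = np.column_stack(
        [np.interp(s_new, s_raw, pts[:, 0]), np.interp(s_new, s_raw, pts[:, 1])]
    )

    # deterministic orientation: pole 1 = lexicographically smaller endpoint
    a, b = tuple(pts_new[0]), tuple(pts_new[-1])
    if b < a:
        pts_new = pts_new[::-1]
        s_new = s_new[-1] - s_new[::-1]
    return MedialAxis(pts_new, s_new)


def _ray_polyline_distance(origin, direction, segments_a, segments_b):
    """Distance along +direction from origin to the nearest polyline crossing.

    ``segments_a``/``segments_b`` are (M, 2) arrays of segment endpoints.
    Returns inf when the ray does not cross the polyline.
    """
    # solve origin + t*d = a + sseg*e by Cramer's rule with 2-D cross products
    d = direction
    e = segments_b - segments_a           # (M, 2)
    w = segments_a - origin               # (M, 2)
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        sseg = (w[:, 0] * d[1] - w[:, 1] * d[0]) / denom
    valid = (np.abs(denom) > 1e-12) & (sseg >= 0.0) & (sseg <= 1.0) & (t > 1e-9)
    if not valid.any():
        return np.inf
    return float(np.min(t[valid]))


def width_profiles(
    labeled: np.ndarray, axis: MedialAxis, cell_id: int = 1
) -> WidthProfile:
    """Half-widths from the axis to the subpixel outline along local normals.

    At each axis sample the tangent is estimated by central differences;
    the left/right half-width is the distance to the nearest crossing of
    the 0.5-level mask contour along the +/- normal. Samples whose normal
    fails to intersect the outline (the hemispherical caps) are NaN. Raw,
    unsmoothed values are stored; smoothing happens in
    ``detect_constriction``.
    """
    mask = _cell_mask(labeled, cell_id)
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)
    seg_a = contour[:-1]
    seg_b = contour[1:]

    pts = axis.points
    tangents = np.gradient(pts, axis.arclen, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    tangents = tangents / np.where(norms == 0, 1, norms)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    n = len(pts)
    left = np.full(n, np.nan)
    right = np.full(n, np.nan)
    for i in range(n):
        dl = _ray_polyline_distance(pts[i], normals[i], seg_a, seg_b)
        dr = _ray_polyline_distance(pts[i], -normals[i], seg_a, seg_b)
        if np.isfinite(dl):
            left[i] = dl
        if np.isfinite(dr):
            right[i] = dr
    return WidthProfile(axis.arclen.copy(), left, right)


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """NaN-tolerant centered moving mean with edge shrinkage."""
    valid = np.isfinite(x).astype(float)
    filled = np.where(np.isfinite(x), x, 0.0)
    kernel = np.ones(window)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _half_peaks(half_width, window, cap_lo, cap_hi, min_prominence, min_distance):
    sm = _moving_mean(half_width, window)
    finite = np.isfinite(sm)
    if finite.sum() < 2:
        return np.array([], dtype=int), np.array([])
    hi = np.nanmax(sm)
    if hi <= 0:
        return np.array([], dtype=int), np.array([])
    # normalize by the cell's maximum width so a relative indentation of
    # depth d appears as a peak of height ~d; min-max scaling would blow
    # pixel jitter on non-constricting cells up to the full [0, 1] range
    inverted = 1.0 - sm / hi
    inverted = np.where(finite, inverted, -np.inf)  # NaN samples cannot be peaks
    peaks, props = find_peaks(inverted, prominence=min_prominence, distance=min_distance)
    keep = (peaks >= cap_lo) & (peaks <= cap_hi)
    return peaks[keep], props["prominences"][keep]


def detect_constriction(
    profile: WidthProfile,
    min_prominence: float = 0.1,
    min_distance: int = 15,
    smooth_window: int = 5,
    cap_fraction: float = 0.10,
) -> ConstrictionCall:
    """Call a constriction from matching width minima on both cell halves.

    Each half-profile is smoothed (moving mean, ``smooth_window`` samples),
    min-max normalized to [0, 1] over the cell and inverted, so width
    minima become peaks; peaks need a prominence of at least
    ``min_prominence`` on the normalized scale and a separation of
    ``min_distance`` samples. The first and last ``cap_fraction`` of the
    arc length are excluded (the hemispherical caps always end in spurious
    width minima). A constriction is called when each half has a peak and
    the two peak positions agree within ``min_distance`` samples; its
    position is the mean of the matched pair.
    """
    n = len(profile.s)
    n_valid = int(np.isfinite(profile.half_width_left).sum())
    if min(n_valid, int(np.isfinite(profile.half_width_right).sum())) < 2 * min_distance:
        return ConstrictionCall(False, reason="profile too short")
    cap = int(np.floor(cap_fraction * n))
    cap_lo, cap_hi = cap, n - 1 - cap
    p1, prom1 = _half_peaks(
        profile.half_width_left, smooth_window, cap_lo, cap_hi, min_prominence, min_distance
    )
    p2, prom2 = _half_peaks(
        profile.half_width_right, smooth_window, cap_lo, cap_hi, min_prominence, min_distance
    )
    if len(p1) == 0 or len(p2) == 0:
        return ConstrictionCall(False, reason="no peak on one or both halves")
    # a genuine constriction indents both halves at the same site, so the
    # total width must also dip there; bends and outline jitter produce
    # shallow one-sided dips that pass the half-profile threshold but not
    # this combined one
    pt, _ = _half_peaks(
        profile.total_width, smooth_window, cap_lo, cap_hi, min_prominence, min_distance
    )
    # best pair of one peak per half within the matching tolerance
    best = None
    for i, a in enumerate(p1):
        for j, b in enumerate(p2):
            if abs(int(a) - int(b)) > min_distance:
                continue
            mid = 0.5 * (int(a) + int(b))
            if len(pt) == 0 or np.min(np.abs(pt - mid)) > min_distance:
                continue
            score = prom1[i] + prom2[j]
            if best is None or score > best[0]:
                best = (score, a, b)
    if best is None:
        return ConstrictionCall(False, reason="half-peaks do not match")
    _, a, b = best
    s_c = 0.5 * (profile.s[int(a)] + profile.s[int(b)])
    length = profile.s[-1]
    rel = s_c / length - 0.5
    return ConstrictionCall(True, float(s_c), float(rel), float(abs(rel)))


def pole_regions(
    labeled: np.ndarray,
    axis: MedialAxis,
    cell_id: int = 1,
    fraction: float = 0.30,
    erosion: int = 2,
) -> PoleRegions:
    """The two polar masks used for pole-resolved intensity statistics.

    A pixel belongs to pole k when the arc-length coordinate of its
    nearest axis point lies within ``fraction`` of the cell length from
    that pole. Each region is then binary-eroded by ``erosion`` px against
    the full image frame. Raises when erosion empties a region.
    """
    mask = _cell_mask(labeled, cell_id)
    rr, cc = np.nonzero(mask)
    s = axis.nearest_s(np.column_stack([rr, cc]))
    L = axis.length
    reg1 = np.zeros_like(mask)
    reg2 = np.zeros_like(mask)
    sel1 = s <= fraction * L
    sel2 = s >= (1.0 - fraction) * L
    # guarantee disjoint regions even when fraction >= 0.5 (boundary pixels
    # go to pole 1, consistent with half-open interval convention)
    sel2 &= ~sel1
    reg1[rr[sel1], cc[sel1]] = True
    reg2[rr[sel2], cc[sel2]] = True
    if erosion > 0:
        reg1 = ndi.binary_erosion(reg1, iterations=erosion, border_value=0)
        reg2 = ndi.binary_erosion(reg2, iterations=erosion, border_value=0)
    if not reg1.any() or not reg2.any():
        raise ValueError(f"pole region of cell {cell_id} empty after erosion")
    return PoleRegions(reg1, reg2, fraction, erosion)
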