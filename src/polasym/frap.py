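"""FRAP trace correction, normalization and recovery fitting.

The workflow mirrors standard pole-bleach experiments on agarose pads:
global photobleaching is corrected with the mean intensity of non-bleached
control cells, each bleached trace is normalized so the first post-bleach
frame is 0 and the maximum post-bleach intensity is 1, and the recovery is
fitted with a single exponential ``v(t) = A * (1 - exp(-(t - t0)/tau))``.
The half-time to maximal recovery is ``tau * ln 2``; the immobile fraction
is ``1 - A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "FrapFit",
    "bleach_correction",
    "normalize_trace",
    "fit_half_time",
]


@dataclass
class FrapTrace:
    """Intensity time series for one ROI (bleached cell or control)."""

    times_s: np.ndarray
    raw_intensity: np.ndarray
    bleach_index: int
    is_control: bool = False
    roi: object = None
    cell_id: object = None
    corrected_intensity: np.ndarray | None = None
    normalized: np.ndarray | None = None
    flags: list = field(default_factory=list)
    fit: "FrapFit | None" = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.raw_intensity = np.asarray(self.raw_intensity, dtype=float)
        if self.times_s.shape != self.raw_intensity.shape:
            raise ValueError("times and intensities must have equal length")
        if not (0 <= self.bleach_index < len(self.times_s)):
            raise ValueError("bleach_index outside the series")


@dataclass
class FrapFit:
    amplitude: float
    tau_s: float
    half_time_s: float
    converged: bool


def bleach_correction(traces: list[FrapTrace]) -> list[FrapTrace]:
    """Correct all traces for global photobleaching using control cells.

    The correction factor at each timepoint is
    ``factor(t) = mean_control(t=0) / mean_control(t)`` — it is exactly 1
    at t = 0 — and multiplies every trace. Raises when no control traces
    are present, timepoints disagree, or the control mean is non-positive.
    """
    controls = [t for t in traces if t.is_control]
    if not controls:
        raise ValueError("at least one control (non-bleached) trace is required")
    t0 = controls[0].times_s
    for t in traces:
        if t.times_s.shape != t0.shape or not np.allclose(t.times_s, t0):
            raise ValueError("all traces must share a common time base")
    mean_control = np.mean([t.raw_intensity for t in controls], axis=0)
    if np.any(mean_control <= 0):
        raise ValueError("control mean intensity is non-positive at some timepoint")
    factor = mean_control[0] / mean_control
    for t in traces:
        t.corrected_intensity = t.raw_intensity * factor
    return traces


def normalize_trace(
    trace: FrapTrace, background: float = 0.0, min_post_frames: int = 3
) -> FrapTrace:
    """Normalize a corrected trace to [0, 1] over the post-bleach span.

    After background subtraction, values map to
    ``(I - I_post) / (I_max_post - I_post)`` where ``I_post`` is the
    intensity at the first post-bleach frame and ``I_max_post`` the
    maximum over post-bleach frames — so the first post-bleach frame is 0
    and the frame of maximal recovery is exactly 1. A trace with no
    recovery (``I_max_post == I_post``) is flagged and left unnormalized.
    """
    if trace.corrected_intensity is None:
        raise ValueError("run bleach_correction first")
    bi = trace.bleach_index
    if len(trace.times_s) - bi < min_post_frames:
        raise ValueError(f"need at least {min_post_frames} post-bleach frames")
    intens = trace.corrected_intensity - background
    i_post = intens[bi]
    i_max = np.max(intens[bi:])
    if i_max <= i_post:
        trace.flags.append("no_recovery")
        return trace
    trace.normalized = (intens - i_post) / (i_max - i_post)
    return trace


def _recovery(t, amplitude, tau):
    return amplitude * (1.0 - np.exp(-t / tau))


def fit_half_time(
    trace: FrapTrace, maxfev: int = 500, tol: float = 1e-8
) -> FrapFit:
    """Fit the normalized post-bleach recovery with a single exponential.

    Model: ``v(t) = A * (1 - exp(-(t - t0)/tau))`` over post-bleach frames,
    with t0 the first post-bleach time. Initialization A = 1,
    tau = (t_end - t0)/3. The half-time to maximal recovery is the time at
    which the fitted curve reaches A/2, i.e. ``tau * ln 2``. Traces that
    fail to converge within ``maxfev`` evaluations are flagged.
    """
    if trace.normalized is None:
        raise ValueError("trace must be normalized before fitting")
    bi = trace.bleach_index
    t = trace.times_s[bi:] - trace.times_s[bi]
    v = trace.normalized[bi:]
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach frames to fit")
    span = t[-1] if t[-1] > 0 else 1.0
    p0 = (1.0, span / 3.0)
    try:
        popt, _ = curve_fit(
            _recovery, t, v, p0=p0,
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=maxfev, xtol=tol, ftol=tol, gtol=tol,
        )
        amplitude, tau = float(popt[0]), float(popt[1])
        fit = FrapFit(amplitude, tau, tau * math.log(2.0), converged=True)
    except RuntimeError:
        trace.flags.append("fit_not_converged")
        fit = FrapFit(np.nan, np.nan, np.nan, converged=False)
    trace.fit = fit
    return fit
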