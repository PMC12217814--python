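"""Classification of long-time PDE states: H, PS, T or CP.

Two scalar metrics are tracked along a trajectory: the approximate
propagation speed

    c_tilde(t) = ||dt rho_s||_2 / ||dx rho_s||_2,

with the three species fields stacked into a single vector (for an exact
traveling wave ``rho(x - v t)`` this equals ``|v|``), and the distance
from the uniform state

    d_H(t) = ( sum_s || rho_s(., t) - phi_s ||_2 )^(1/2),

computed exactly as printed, i.e. the square root of the *sum of norms*.
Norms are continuum L2 norms ``(integral f^2 dx)^(1/2)``.

The default decision rules on the window ``T* = [t*-500, t*]`` with
``t* >= 700``:

    (i)   sup d_H < 0.05                                   -> H
    (ii)  d_H(t*) >= 0.05 and sup c_tilde < 0.01           -> PS
    (iii) ... c_tilde(t*) >= 0.01 and sup |c_tilde'| < 1e-5 -> T
    (iv)  ... c_tilde(t*) >= 0.01 and sup |c_tilde'| >= 1e-5 -> CP

Shorter runs (scaled-down fixtures) may pass an explicit window; the
defaults reproduce the printed thresholds bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pde import Trajectory

__all__ = ["ClassifierMetrics", "metrics", "classify", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = {
    "d_H": 0.05,
    "c_tilde": 0.01,
    "c_tilde_slope": 1e-5,
    "t_star_min": 700.0,
    "window": 500.0,
}


@dataclass
class ClassifierMetrics:
    t: np.ndarray            # midpoint times of frame pairs
    c_tilde: np.ndarray
    d_H: np.ndarray          # at midpoint times
    c_tilde_slope: np.ndarray
    label: str | None = None
    detail: dict = field(default_factory=dict)


def _savitzky_slope(t: np.ndarray, y: np.ndarray, half_window: int = 5) -> np.ndarray:
    """Local least-squares slope of y(t) over a sliding window."""
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        tt, yy = t[lo:hi], y[lo:hi]
        out[i] = np.polyfit(tt, yy, 1)[0] if len(tt) > 1 else 0.0
    return out


def metrics(traj: Trajectory, slope_half_window: int = 5) -> ClassifierMetrics:
    """Classifier metric time series from stored frames.

    Time derivatives are centered differences of consecutive frames;
    space derivatives are centered differences on the periodic grid.
    ``c_tilde'`` is a sliding-window least-squares slope to keep rule
    (iii)/(iv) insensitive to frame-sampling noise.
    """
    if len(traj.times) < 2:
        raise ValueError("need at least two frames to compute metrics")
    dx = float(traj.x[1] - traj.x[0])
    frames = traj.frames
    t = traj.times
    dt = np.diff(t)
    dfdt = (frames[1:] - frames[:-1]) / dt[:, None, None]
    mid = 0.5 * (frames[1:] + frames[:-1])
    dfdx = (np.roll(mid, -1, axis=2) - np.roll(mid, 1, axis=2)) / (2 * dx)
    num = np.sqrt((dfdt**2).sum(axis=(1, 2)) * dx)
    den = np.sqrt((dfdx**2).sum(axis=(1, 2)) * dx)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_tilde = np.where(den > 1e-14, num / np.maximum(den, 1e-300), 0.0)
    t_mid = 0.5 * (t[1:] + t[:-1])

    base = np.array(
        [mid[:, 0].mean(axis=1), mid[:, 1].mean(axis=1), mid[:, 2].mean(axis=1)]
    ).T
    # d_H as printed: sqrt of the *sum over species of L2 norms*
    norms = np.sqrt(((mid - base[:, :, None]) ** 2).sum(axis=2) * dx)
    d_H = np.sqrt(norms.sum(axis=1))
    slope = _savitzky_slope(t_mid, c_tilde, slope_half_window)
    return ClassifierMetrics(t_mid, c_tilde, d_H, slope)


def classify(
    traj: Trajectory,
    thresholds: dict | None = None,
    t_star: float | None = None,
    window: float | None = None,
) -> str:
    """Label a trajectory H / PS / T / CP by the printed decision rules.

    ``t_star`` defaults to the final stored time; the averaging window
    defaults to the configured 500 time units (clipped to the available
    range for scaled-down runs, which is reported in ``detail``).
    Raises if the run is shorter than the minimum decision time unless a
    window is given explicitly.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    m = metrics(traj)
    t_end = float(traj.times[-1]) if t_star is None else float(t_star)
    win = th["window"] if window is None else float(window)
    if t_end < th["t_star_min"] and window is None:
        raise ValueError(
            f"trajectory ends at t={t_end} < minimum decision time "
            f"{th['t_star_min']}; pass an explicit window for scaled-down runs"
        )
    sel = (m.t >= t_end - win) & (m.t <= t_end)
    if sel.sum() < 3:
        raise ValueError("too few frames in the decision window")
    d_H = m.d_H[sel]
    c_t = m.c_tilde[sel]
    slope = m.c_tilde_slope[sel]
    label: str
    if d_H.max() < th["d_H"]:
        label = "H"
    elif c_t.max() < th["c_tilde"]:
        label = "PS"
    elif c_t[-1] >= th["c_tilde"]:
        label = "T" if np.abs(slope).max() < th["c_tilde_slope"] else "CP"
    else:
        label = "undetermined"
    m.label = label
    m.detail = {
        "t_star": t_end,
        "window": win,
        "sup_d_H": float(d_H.max()),
        "d_H_end": float(d_H[-1]),
        "sup_c_tilde": float(c_t.max()),
        "c_tilde_end": float(c_t[-1]),
        "sup_c_tilde_slope": float(np.abs(slope).max()),
    }
    classify.last_metrics = m  # diagnostic hook
    return label
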