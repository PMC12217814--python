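"""Reference experiments: the documented parameter sets, run end to end.

These drivers tie the modules together into the benchmark computations
of the package: the large-domain traveling-wave run, the co-moving
Newton polish, continuation of the traveling branch in domain size and
composition, and thermodynamic-limit speed extrapolation.  They are used
both by the acceptance script and by the test suite, so every number
they produce is recomputed from scratch.
"""

from __future__ import annotations

import logging

import numpy as np

from . import pde, waves
from .params import ModelParams

log = logging.getLogger(__name__)

FIG4_POINT = dict(Pe=7.5, L=25.0, phi_a=0.36, phi_p=0.3)


def traveling_run(
    seed: int,
    t_end: float = 500.0,
    dx: float = 0.05,
    amplitude: float = 0.05,
    noise_amplitude: float = 1e-3,
    params: ModelParams | None = None,
) -> tuple[ModelParams, pde.Trajectory, float]:
    """Time-step the reference traveling-state protocol.

    Homogeneous state plus the left-traveling mode at finite amplitude
    plus seeded uniform noise, integrated with the first-order
    finite-volume scheme; returns the trajectory and the measured
    propagation speed ``c`` (phase drift of the fundamental mode over
    the last fifth of the run).
    """
    p = params if params is not None else ModelParams(**FIG4_POINT)
    N = int(round(p.L / dx))
    ic = pde.make_initial_condition(
        "left", p, N, amplitude=amplitude, noise_amplitude=noise_amplitude,
        seed=seed, allow_stable=True,
    )
    traj = pde.integrate(ic, t_end, p, snap_dt=1.0)
    c = pde.measure_speed(traj)
    return p, traj, c


def polish_to_L(
    p: ModelParams,
    frame: np.ndarray,
    c0: float,
    L_target: float = 140.0,
    points_per_unit: float = 20.0,
) -> tuple[np.ndarray, float]:
    """Newton-polish a time-stepped frame and continue the branch to
    ``L_target``.  Returns (profiles, c) at the target domain size."""
    N0 = frame.shape[1]
    sol = waves.solve_finite_L(p, N=N0, init_guess=(frame, c0))
    prof = np.stack([sol.profiles[k] for k in ("+", "-", "0")])
    c = sol.c
    ladder = [L for L in (35, 50, 70, 100, 140, 200, 280, 400, 560)
              if p.L < L <= L_target]
    if ladder:
        prof, c, _ = waves.continue_in_L(
            p, prof, c, L_targets=tuple(ladder),
            points_per_unit=points_per_unit,
        )
    return prof, c


def continue_in_composition(
    prof: np.ndarray,
    c: float,
    Pe: float,
    L: float,
    targets: list[tuple[float, float]],
    points_per_unit: float = 20.0,
) -> tuple[np.ndarray, float]:
    """Thread the traveling branch through a list of compositions."""
    N = int(round(points_per_unit * L))
    for pa, pp in targets:
        p = ModelParams(Pe=Pe, L=L, phi_a=pa, phi_p=pp)
        sol = waves.solve_finite_L(p, N=N, init_guess=(prof, c))
        prof = np.stack([sol.profiles[k] for k in ("+", "-", "0")])
        c = sol.c
        log.info("continued to (%.3f, %.3f): c = %.5f", pa, pp, c)
    return prof, c


def terminal_phi_p(
    prof: np.ndarray,
    c: float,
    Pe: float,
    L: float,
    phi_a: float,
    phi_p_start: float,
    step: float = 0.01,
    min_step: float = 0.0025,
    points_per_unit: float = 20.0,
) -> tuple[float, np.ndarray, float]:
    """Follow the branch to decreasing passive load until it terminates.

    The single-structure traveling branch ends at a fold where the
    profile must restructure (an additional interface); the terminal
    composition is located by step halving.  Returns
    ``(phi_p_terminal, profiles, c)`` at the last converged composition.
    """
    N = int(round(points_per_unit * L))
    pp = phi_p_start
    while step >= min_step:
        trial = pp - step
        if trial <= 0:
            break
        p = ModelParams(Pe=Pe, L=L, phi_a=phi_a, phi_p=trial)
        try:
            sol = waves.solve_finite_L(p, N=N, init_guess=(prof, c))
        except RuntimeError:
            step *= 0.5
            continue
        prof = np.stack([sol.profiles[k] for k in ("+", "-", "0")])
        c = sol.c
        pp = trial
        log.info("branch alive at phi_p = %.4f (c = %.5f)", pp, c)
    # step back from the fold by a safety margin: solutions within a
    # minimum step of the terminus are too fragile to continue in L
    margin = 2.0 * min_step
    p = ModelParams(Pe=Pe, L=L, phi_a=phi_a, phi_p=pp + margin)
    sol = waves.solve_finite_L(p, N=N, init_guess=(prof, c))
    prof = np.stack([sol.profiles[k] for k in ("+", "-", "0")])
    return pp + margin, prof, sol.c


def outer_speed(
    phi_a: float,
    phi_p: float,
    Pe: float,
    prof140: np.ndarray,
    c140: float,
    L_targets: tuple = (200, 280, 400),
) -> tuple[float, list]:
    """Thermodynamic-limit speed at a composition (1/L extrapolation)."""
    return waves.outer_speed_by_continuation(
        phi_a, phi_p, Pe, prof140, c140, L_start=140.0, L_targets=L_targets
    )


def acceptance_targets(seed: int) -> dict:
    """Recompute the benchmark quantities from scratch.

    t1  signed propagation speed of the time-stepped attractor at the
        reference composition (dx = 0.05, t = 500);
    t2  thermodynamic-limit speed magnitude at the reference composition
        (smooth-branch continuation);
    t3  same at reduced passive load (single-interface regime);
    t4  same at the terminal composition of the branch (transition);
    t5  same slightly below the terminal composition in phi_a.
    """
    Pe = FIG4_POINT["Pe"]
    pa = FIG4_POINT["phi_a"]
    pp0 = FIG4_POINT["phi_p"]
    out: dict = {}

    p, traj, c_run = traveling_run(seed)
    out["t1"] = {"value": float(c_run), "n": traj.frames.shape[2]}
    log.info("t1: c = %.4f", c_run)

    prof140, c140 = polish_to_L(p, traj.frames[-1], c_run, L_target=140.0)
    n_used = 8000  # grid of the largest co-moving solve (L = 400)

    c2, hist = outer_speed(pa, pp0, Pe, prof140, c140)
    out["t2"] = {"value": float(abs(c2)), "n": n_used}
    log.info("t2: |c_inf| = %.4f (history %s)", abs(c2), hist)

    prof26, c26 = continue_in_composition(
        prof140, c140, Pe, 140.0,
        [(pa, 0.29), (pa, 0.28), (pa, 0.27), (pa, 0.26)],
    )
    c3, _ = outer_speed(pa, 0.26, Pe, prof26, c26)
    out["t3"] = {"value": float(abs(c3)), "n": n_used}
    log.info("t3: |c_inf| = %.4f", abs(c3))

    pp_term, prof_t, c_t = terminal_phi_p(prof26, c26, Pe, 140.0, pa, 0.26)
    c4, _ = outer_speed(pa, pp_term, Pe, prof_t, c_t)
    out["t4"] = {"value": float(abs(c4)), "n": n_used}
    log.info("t4: terminal phi_p = %.4f, |c_inf| = %.4f", pp_term, abs(c4))

    try:
        prof5, c5f = continue_in_composition(
            prof_t, c_t, Pe, 140.0, [(pa - 0.005, pp_term), (pa - 0.01, pp_term)]
        )
        c5, _ = outer_speed(pa - 0.01, pp_term, Pe, prof5, c5f)
    except RuntimeError:
        prof5, c5f = continue_in_composition(
            prof_t, c_t, Pe, 140.0, [(pa - 0.005, pp_term)]
        )
        c5, _ = outer_speed(pa - 0.005, pp_term, Pe, prof5, c5f)
    out["t5"] = {"value": float(abs(c5)), "n": n_used}
    log.info("t5: |c_inf| = %.4f", abs(c5))
    return out
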