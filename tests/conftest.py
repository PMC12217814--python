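import numpy as np
import pytest

from aplg.params import ModelParams
from aplg import pde


@pytest.fixture(scope="session")
def fig2_params():
    """Strongly phase-separating state point (large Pe, low passive load)."""
    return ModelParams(Pe=20.0, L=2.0, phi_a=0.5, phi_p=0.1)


@pytest.fixture(scope="session")
def fig2_trajectory(fig2_params):
    """Relaxed PS run reused across tests (noise-seeded, t=30)."""
    ic = pde.make_initial_condition(
        "noise", fig2_params, 200, noise_amplitude=1e-3, seed=3
    )
    return pde.integrate(ic, 30.0, fig2_params, snap_dt=0.25)


@pytest.fixture(scope="session")
def relaxed_ps_profile():
    """Finely resolved stationary PS profile for coexistence oracles.

    Pe=7.5 inside the binodal at nu=0.3, seeded from the analytic
    interface profile (two mirrored fronts placed by the lever rule) and
    relaxed with centered fluxes on a fine grid, so that spatial
    derivatives of the final profile are accurate.
    """
    from scipy.optimize import brentq
    from aplg import coexistence as cx

    p = ModelParams(Pe=7.5, L=12.0, phi_a=0.61, phi_p=0.09)
    N = 960
    dx = p.L / N
    x = (np.arange(N) + 0.5) * dx
    ip = cx.interface_profile(p.Pe, p.nu, half_width=10.0, n=1601)

    def rho_of(half):
        s = half - np.abs(x - 0.5 * p.L)
        return np.interp(s, ip["x"], ip["rho"])

    # liquid-slab half width tuned so the mean density is exact; the
    # passive field then satisfies rho_0 = nu (1 - rho) identically at t=0
    half = brentq(lambda h: rho_of(h).mean() - p.phi, 1.0, 5.5, xtol=1e-14)
    rho = rho_of(half)
    s = half - np.abs(x - 0.5 * p.L)
    m = np.interp(s, ip["x"], ip["m"]) * np.sign(x - 0.5 * p.L)
    r0 = p.nu * (1 - rho)
    ra = rho - r0
    ic = pde.DensityField(x, 0.5 * (ra + m), 0.5 * (ra - m), r0)
    traj = pde.integrate(ic, 400.0, p, snap_dt=100.0, scheme="centered")
    return p, traj.field(-1)


@pytest.fixture(scope="session")
def fig4_attractor():
    """Traveling attractor at the large-domain reference point.

    Left-mode finite-amplitude kick plus seeded noise; run long enough
    for the default (unscaled) classifier window.  Reused by the
    traveling-wave and acceptance checks.
    """
    p = ModelParams(Pe=7.5, L=25.0, phi_a=0.36, phi_p=0.3)
    ic = pde.make_initial_condition(
        "left", p, 500, amplitude=0.05, noise_amplitude=1e-3, seed=1,
        allow_stable=True,
    )
    traj = pde.integrate(ic, 1200.0, p, snap_dt=1.0)
    return p, traj


@pytest.fixture(scope="session")
def traveling_solution(fig4_attractor):
    """Newton-converged co-moving profile seeded from the attractor."""
    from aplg import pde as _pde, waves

    p, traj = fig4_attractor
    c0 = _pde.measure_speed(traj)
    sol = waves.solve_finite_L(p, N=500, init_guess=(traj.frames[-1], c0))
    return sol


def make_traveling_frames(L=4.0, N=128, v=0.3, nt=40, dt=0.5):
    """Synthetic rigidly traveling trajectory rho_s(x - v t)."""
    x = (np.arange(N) + 0.5) * (L / N)
    times = np.arange(nt) * dt
    frames = np.empty((nt, 3, N))
    for i, t in enumerate(times):
        base = 0.4 + 0.1 * np.sin(2 * np.pi * (x - v * t) / L)
        frames[i, 0] = 0.5 * base + 0.02 * np.cos(4 * np.pi * (x - v * t) / L)
        frames[i, 1] = 0.5 * base
        frames[i, 2] = 0.2 + 0.05 * np.cos(2 * np.pi * (x - v * t) / L)
    return pde.Trajectory(x, times, frames)
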