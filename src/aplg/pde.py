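"""Finite-volume integration of the exact hydrodynamic equations.

The densities ``rho_+``, ``rho_-``, ``rho_0`` of right-moving, left-moving
and passive particles evolve (in one space dimension, periodic) as

    dt rho_s = dx[ d_s(rho) dx rho_s + rho_s D(rho) dx rho ]
               - Pe dx[ rho_s s(rho) m + s_sign d_s(rho) rho_s ]
               - s_sign m,

where ``m = rho_+ - rho_-`` is the magnetization, ``rho`` the total
density, and ``s_sign`` is +1, -1, 0 for the three species.  The equation
set is integrated with a first-order finite-volume scheme in space and
forward Euler with adaptive time stepping.  The advective flux is
upwinded on the sign of the local advective velocity (default); a
centered second-order flux is available for linear-response work where
upwind numerical diffusion would pollute measured growth rates.

The scheme is conservative: the cell sums of ``rho_a = rho_+ + rho_-``
and ``rho_0`` are preserved to machine precision (the orientation-flip
reaction only exchanges ``rho_+`` and ``rho_-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .coefficients import ALPHA, BETA
from .params import ModelParams

__all__ = [
    "DensityField",
    "Trajectory",
    "rhs",
    "integrate",
    "make_initial_condition",
    "measure_speed",
]


@dataclass
class DensityField:
    """Periodic finite-volume density triple on ``N`` cells of width ``L/N``."""

    x: np.ndarray
    rho_plus: np.ndarray
    rho_minus: np.ndarray
    rho_zero: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.x)
        for a in (self.rho_plus, self.rho_minus, self.rho_zero):
            if len(a) != n:
                raise ValueError("field arrays must share the grid size")

    @property
    def N(self) -> int:
        return len(self.x)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def L(self) -> float:
        return self.N * self.dx

    @property
    def rho(self) -> np.ndarray:
        return self.rho_plus + self.rho_minus + self.rho_zero

    @property
    def rho_a(self) -> np.ndarray:
        return self.rho_plus + self.rho_minus

    @property
    def m(self) -> np.ndarray:
        return self.rho_plus - self.rho_minus

    def stack(self) -> np.ndarray:
        """(3, N) array in species order (+, -, 0)."""
        return np.stack([self.rho_plus, self.rho_minus, self.rho_zero])

    @classmethod
    def from_stack(cls, x: np.ndarray, arr: np.ndarray, time: float = 0.0):
        return cls(x, arr[0].copy(), arr[1].copy(), arr[2].copy(), time)

    def copy(self) -> "DensityField":
        return DensityField(
            self.x.copy(),
            self.rho_plus.copy(),
            self.rho_minus.copy(),
            self.rho_zero.copy(),
            self.time,
        )


@dataclass
class Trajectory:
    """Sampled PDE trajectory: frames of shape ``(nt, 3, N)``."""

    x: np.ndarray
    times: np.ndarray
    frames: np.ndarray
    params: ModelParams | None = None

    @property
    def L(self) -> float:
        return len(self.x) * float(self.x[1] - self.x[0])

    def field(self, i: int) -> DensityField:
        return DensityField.from_stack(self.x, self.frames[i], float(self.times[i]))

    @property
    def rho(self) -> np.ndarray:
        """Total density kymograph, shape ``(nt, N)``."""
        return self.frames.sum(axis=1)


# ---------------------------------------------------------------------------
# numba kernels (default polynomial coefficients hard-wired for speed)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rhs_kernel(rp, rm, r0, dx, Pe, centered, drp, drm, dr0):  # pragma: no cover
    n = rp.shape[0]
    umax = 0.0
    # face fluxes: face i sits between cells i and i+1 (periodic)
    for i in range(n):
        ip = i + 1 if i + 1 < n else 0
        rpl, rpr = rp[i], rp[ip]
        rml, rmr = rm[i], rm[ip]
        r0l, r0r = r0[i], r0[ip]
        rl = rpl + rml + r0l
        rr = rpr + rmr + r0r
        rf = 0.5 * (rl + rr)
        ds_f = (1.0 - rf) * (1.0 - ALPHA * rf + BETA * rf * rf)
        D_f = (1.0 + ALPHA) - (ALPHA + BETA) * rf + BETA * rf * rf
        s_f = D_f - 1.0
        grad_r = (rr - rl) / dx
        m_f = 0.5 * ((rpl - rml) + (rpr - rmr))

        # species loop unrolled: sigma = +1, -1, 0
        for k in range(3):
            if k == 0:
                sig = 1.0
                cl, cr = rpl, rpr
            elif k == 1:
                sig = -1.0
                cl, cr = rml, rmr
            else:
                sig = 0.0
                cl, cr = r0l, r0r
            fdiff = ds_f * (cr - cl) / dx + 0.5 * (cl + cr) * D_f * grad_r
            u = Pe * (s_f * m_f + sig * ds_f)
            au = abs(u)
            if au > umax:
                umax = au
            if centered:
                gadv = u * 0.5 * (cl + cr)
            else:
                gadv = u * (cl if u > 0.0 else cr)
            flux = fdiff - gadv
            if k == 0:
                drp[i] += flux / dx
                drp[ip] -= flux / dx
            elif k == 1:
                drm[i] += flux / dx
                drm[ip] -= flux / dx
            else:
                dr0[i] += flux / dx
                dr0[ip] -= flux / dx
    for i in range(n):
        mi = rp[i] - rm[i]
        drp[i] -= mi
        drm[i] += mi
    return umax


@njit(cache=True)
def _advance_kernel(rp, rm, r0, dx, Pe, centered, t, t_target, cfl):  # pragma: no cover
    n = rp.shape[0]
    drp = np.zeros(n)
    drm = np.zeros(n)
    dr0 = np.zeros(n)
    np1 = np.empty(n)
    nm1 = np.empty(n)
    n01 = np.empty(n)
    while t < t_target - 1e-14:
        for i in range(n):
            drp[i] = 0.0
            drm[i] = 0.0
            dr0[i] = 0.0
        umax = _rhs_kernel(rp, rm, r0, dx, Pe, centered, drp, drm, dr0)
        dt = cfl * 0.5 * dx * dx
        if umax > 0.0:
            dt_adv = cfl * dx / umax
            if dt_adv < dt:
                dt = dt_adv
        if t + dt > t_target:
            dt = t_target - t
        # positivity guard: retry with halved dt on violation
        while True:
            ok = True
            for i in range(n):
                np1[i] = rp[i] + dt * drp[i]
                nm1[i] = rm[i] + dt * drm[i]
                n01[i] = r0[i] + dt * dr0[i]
                if (
                    np1[i] < -1e-14
                    or nm1[i] < -1e-14
                    or n01[i] < -1e-14
                    or np1[i] + nm1[i] + n01[i] > 1.0 + 1e-12
                ):
                    ok = False
                    break
            if ok:
                break
            dt *= 0.5
            if dt < 1e-12:
                return -1.0
        for i in range(n):
            rp[i] = np1[i]
            rm[i] = nm1[i]
            r0[i] = n01[i]
        t += dt
    return t


def rhs(fieldv: DensityField, params: ModelParams, scheme: str = "upwind") -> np.ndarray:
    """Finite-volume time derivatives, shape ``(3, N)`` in order (+, -, 0).

    Raises on NaN or out-of-range densities.
    """
    st = fieldv.stack()
    if not np.all(np.isfinite(st)):
        raise FloatingPointError("non-finite density in rhs")
    if np.any(st < -1e-10) or np.any(st.sum(axis=0) > 1.0 + 1e-10):
        raise FloatingPointError("density outside [0, 1] in rhs")
    n = fieldv.N
    drp = np.zeros(n)
    drm = np.zeros(n)
    dr0 = np.zeros(n)
    _rhs_kernel(
        fieldv.rho_plus,
        fieldv.rho_minus,
        fieldv.rho_zero,
        fieldv.dx,
        params.Pe,
        scheme == "centered",
        drp,
        drm,
        dr0,
    )
    return np.stack([drp, drm, dr0])


def integrate(
    ic: DensityField,
    t_end: float,
    params: ModelParams,
    *,
    cfl: float = 0.9,
    snap_dt: float = 1.0,
    scheme: str = "upwind",
    observers=None,
) -> Trajectory:
    """Integrate to ``t_end`` with forward Euler and adaptive dt.

    The time step obeys the diffusive stability bound
    ``dt <= cfl * dx**2 / 2`` (the identity ``rho*D + d_s = 1`` makes the
    total-density diffusivity exactly one) together with an advective
    bound ``dt <= cfl * dx / max|u|``; a positivity guard halves dt where
    needed.  Frames are stored every ``snap_dt`` time units (and at
    ``t_end``); ``observers`` is an optional list of callables invoked as
    ``obs(field)`` at every snapshot.
    """
    if t_end <= ic.time:
        raise ValueError("t_end must exceed the initial time")
    rp = ic.rho_plus.copy()
    rm = ic.rho_minus.copy()
    r0 = ic.rho_zero.copy()
    centered = scheme == "centered"
    snap_times = np.arange(ic.time, t_end + 0.5 * snap_dt, snap_dt)
    if snap_times[-1] < t_end - 1e-12:
        snap_times = np.append(snap_times, t_end)
    times = [ic.time]
    frames = [np.stack([rp, rm, r0]).copy()]
    t = ic.time
    for t_next in snap_times[1:]:
        t = _advance_kernel(rp, rm, r0, ic.dx, params.Pe, centered, t, float(t_next), cfl)
        if t < 0:
            raise FloatingPointError(
                f"time step underflow (dt < 1e-12) near t = {t_next}"
            )
        frame = np.stack([rp, rm, r0]).copy()
        times.append(t)
        frames.append(frame)
        if observers:
            f = DensityField.from_stack(ic.x, frame, t)
            for obs in observers:
                obs(f)
    return Trajectory(ic.x.copy(), np.asarray(times), np.asarray(frames), params)


def _grid(params: ModelParams, N: int) -> np.ndarray:
    dx = params.L / N
    return (np.arange(N) + 0.5) * dx


def make_initial_condition(
    kind: str,
    params: ModelParams,
    N: int,
    *,
    amplitude: float = 1e-2,
    noise_amplitude: float = 1e-3,
    seed: int | None = None,
    q_index: int | None = None,
    allow_stable: bool = False,
) -> DensityField:
    """Seeded initial conditions for the hydrodynamic equations.

    kind
        ``"homogeneous"`` - the uniform state;
        ``"noise"`` - uniform state plus mean-subtracted per-cell uniform
        noise of relative amplitude ``noise_amplitude``;
        ``"left"`` / ``"right"`` - the real part of the dominant unstable
        eigenvector at the most unstable admissible wavenumber
        ``q = 2*pi*k/L``, traveling left/right (plus the same noise);
        ``"pair"`` - symmetric sum of the left and right modes (plus noise).

    Eigenmode kinds raise ``ValueError`` at linearly stable state points.
    Species means equal ``phi_sigma`` exactly after perturbation.
    """
    from . import stability

    x = _grid(params, N)
    base = np.array([params.phi_a / 2.0, params.phi_a / 2.0, params.phi_p])
    fields = np.repeat(base[:, None], N, axis=1)

    if kind not in {"homogeneous", "noise", "left", "right", "pair"}:
        raise ValueError(f"unknown initial-condition kind {kind!r}")

    if kind in {"left", "right", "pair"}:
        q, lam, vec = stability.most_unstable_mode(params, q_index=q_index)
        if lam.real <= 0 and not allow_stable:
            raise ValueError(
                "eigenmode initial condition requested at a linearly stable "
                f"state point (max growth rate {lam.real:.3e}); pass "
                "allow_stable=True for a finite-amplitude kick along the "
                "least-stable mode"
            )
        # plane wave exp(lam*t + i*q*x): phase velocity -Im(lam)/q.
        # 'vec' is the eigenvector of the branch with Im(lam) >= 0 (left-
        # traveling); its conjugate at -q gives the right-traveling wave.
        mode_left = np.real(vec[:, None] * np.exp(1j * q * x)[None, :])
        mode_right = np.real(np.conj(vec)[:, None] * np.exp(1j * q * x)[None, :])
        if kind == "left":
            fields = fields + amplitude * mode_left
        elif kind == "right":
            fields = fields + amplitude * mode_right
        else:
            fields = fields + 0.5 * amplitude * (mode_left + mode_right)

    if kind in {"noise", "left", "right", "pair"} and noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        for k in range(3):
            eta = rng.uniform(-1.0, 1.0, N)
            eta -= eta.mean()
            fields[k] += noise_amplitude * base[k] * eta

    # restore exact species means (eigenmodes integrate to zero already)
    for k in range(3):
        fields[k] += base[k] - fields[k].mean()
    fields = np.clip(fields, 0.0, None)
    return DensityField(x, fields[0], fields[1], fields[2], 0.0)


def measure_speed(traj: Trajectory, fraction: float = 0.2) -> float:
    """Propagation speed ``c`` (wave velocity times ``L``) of a settled profile.

    Tracks the phase of the fundamental Fourier mode of the total density
    over the last ``fraction`` of the stored frames: for a rigidly
    traveling profile ``rho(x - v t)`` the mode phase drifts linearly at
    rate ``-2*pi*v/L``.  Returns ``c = L * v`` (positive = rightward).
    Stationary profiles give ``c ~ 0``.
    """
    nt = len(traj.times)
    i0 = max(0, int(nt * (1.0 - fraction)) - 1)
    rho = traj.rho[i0:]
    t = traj.times[i0:]
    if len(t) < 3:
        raise ValueError("too few frames to measure a speed")
    mode = np.fft.rfft(rho, axis=1)[:, 1]
    if np.min(np.abs(mode)) < 1e-12:
        return 0.0
    phase = np.unwrap(np.angle(mode))
    slope = np.polyfit(t, phase, 1)[0]
    v = -slope * traj.L / (2.0 * np.pi)
    return float(traj.L * v)
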