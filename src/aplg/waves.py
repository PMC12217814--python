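"""Traveling-wave solvers: finite-L co-moving profiles and the large-L
outer problem of matched asymptotics.

A traveling solution has the form ``rho_s(x, t) = P_s(x - c t / L)``
with wave velocity ``c/L``; substituting into the hydrodynamic equations
gives a co-moving boundary-value problem.  Two regimes are solved:

finite L
    The full three-species co-moving system on a periodic grid:
    unknowns are the profiles plus the speed ``c``, subject to the three
    species-mass averages and a translational gauge (the total density
    is pinned to ``phi`` at one node).

large L (outer problem)
    In the thermodynamic limit the magnetization is slaved,
    ``m = -(Pe/2L) d/dz [d_s(rho) rho_a] + O(1/L^2)``, and the system
    reduces to two equations for ``rho_a``, ``rho_0`` on the unit-scaled
    coordinate.  Sharp interfaces, when present, collapse to points
    whose jump values are the liquid/vapor tie-line endpoints of the
    coexistence construction; the outer problem is solved with Dirichlet
    endpoint values (or periodically when no interface exists), with
    species-mass constraints selecting the speed.

An exact consequence of the co-moving total-density first integral is
that a traveling solution cannot contain two bulk plateaus of different
density (``c z P + P' - Pe (1 - P) m = J`` evaluated in bulks forces
``P = LJ/c``): genuinely phase-separated profiles cannot travel.
``no_traveling_ps_check`` verifies this plateau theorem on any converged
solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._newton import BlockSystem, newton_solve
from .coefficients import ALPHA, BETA
from .params import ModelParams

__all__ = [
    "TravelingSolution",
    "solve_finite_L",
    "solve_outer",
    "insert_interface",
    "no_traveling_ps_check",
]


def _coeffs(r):
    ds = (1.0 - r) * (1.0 - ALPHA * r + BETA * r * r)
    D = (1.0 + ALPHA) - (ALPHA + BETA) * r + BETA * r * r
    return ds, D, D - 1.0


@dataclass
class TravelingSolution:
    """Converged co-moving profile with speed and diagnostics."""

    z: np.ndarray
    profiles: dict            # keys among {"+", "-", "0", "a"}
    c: float
    residual_norm: float
    regime: str               # finite-L | outer-smooth | outer-1-interface | outer-2-interface
    params: ModelParams | None = None
    interfaces: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def rho(self) -> np.ndarray:
        if "0" in self.profiles and "a" in self.profiles:
            return self.profiles["a"] + self.profiles["0"]
        return self.profiles["+"] + self.profiles["-"] + self.profiles["0"]

    @property
    def rho_a(self) -> np.ndarray:
        if "a" in self.profiles:
            return self.profiles["a"]
        return self.profiles["+"] + self.profiles["-"]

    @property
    def m(self) -> np.ndarray:
        """Magnetization: stored for finite-L; leading-order slaved value
        ``m^(1)/L = -(Pe/2L) d/dz[d_s rho_a]`` for outer solutions."""
        if "+" in self.profiles:
            return self.profiles["+"] - self.profiles["-"]
        # outer: slaved magnetization at first order (per unit 1/L)
        dz = self.z[1] - self.z[0]
        ds, _, _ = _coeffs(self.rho)
        w = ds * self.rho_a
        return -(0.5 * (self.params.Pe if self.params else 1.0)) * np.gradient(
            w, dz
        )


# ---------------------------------------------------------------------------
# finite-L problem
# ---------------------------------------------------------------------------


def _finite_L_residual(u, N, dz, L, Pe):
    rp, rm, r0, c = u[:N], u[N : 2 * N], u[2 * N : 3 * N], u[3 * N]
    r = rp + rm + r0
    m = rp - rm
    out = []
    rpf = 0.5 * (rp + np.roll(rp, -1))
    rmf = 0.5 * (rm + np.roll(rm, -1))
    r0f = 0.5 * (r0 + np.roll(r0, -1))
    rf = rpf + rmf + r0f
    mf = rpf - rmf
    ds_f, D_f, s_f = _coeffs(rf)
    grad_r = (np.roll(r, -1) - r) / dz
    for sig, prof, pf in ((1.0, rp, rpf), (-1.0, rm, rmf), (0.0, r0, r0f)):
        grad = (np.roll(prof, -1) - prof) / dz
        flux = (
            (c / L) * pf
            + ds_f * grad
            + pf * D_f * grad_r
            - Pe * (pf * s_f * mf + sig * ds_f * pf)
        )
        div = (flux - np.roll(flux, 1)) / dz
        res = div - sig * m
        out.append(res[1:])  # node-0 rows replaced by constraints
    return np.concatenate(out)


def solve_finite_L(
    params: ModelParams,
    N: int = 1600,
    init_guess: "TravelingSolution | tuple | None" = None,
    tol: float = 1e-10,
    max_iter: int = 80,
) -> TravelingSolution:
    """Newton solve of the periodic co-moving problem at finite L.

    ``init_guess`` is either a previous :class:`TravelingSolution`, a
    tuple ``(profiles_3xN, c)``, or a PDE field/trajectory frame paired
    with a speed estimate.  Unknowns are the 3N profile values plus
    ``c``; rows are the co-moving equations at nodes 1..N-1 per species,
    the three species-mass averages, and the gauge ``rho(z_g) = phi``
    at the node where the seed's total density crosses ``phi``.
    """
    L, Pe = params.L, params.Pe
    dz = L / N
    z = np.arange(N) * dz
    if init_guess is None:
        raise ValueError("solve_finite_L needs an initial guess (seed profile)")
    if isinstance(init_guess, TravelingSolution):
        if "+" in init_guess.profiles:
            prof = np.stack(
                [init_guess.profiles[k] for k in ("+", "-", "0")]
            )
        else:
            # outer seed: split rho_a evenly and ignore m
            prof = np.stack(
                [
                    0.5 * init_guess.profiles["a"],
                    0.5 * init_guess.profiles["a"],
                    init_guess.profiles["0"],
                ]
            )
        zs = init_guess.z / init_guess.z[-1] * z[-1] if init_guess.z[-1] > 0 else z
        prof = np.stack([np.interp(z, zs, p) for p in prof])
        c0 = init_guess.c
    else:
        prof, c0 = init_guess
        prof = np.asarray(prof, dtype=float)
        if prof.shape[1] != N:
            zz = np.linspace(0, L, prof.shape[1], endpoint=False)
            prof = np.stack([np.interp(z, zz, p) for p in prof])

    # translational gauge node: total density crossing phi with max slope
    rtot = prof.sum(axis=0)
    cross = np.nonzero((rtot - params.phi) * (np.roll(rtot, -1) - params.phi) <= 0)[0]
    jg = int(cross[np.argmax(np.abs(np.gradient(rtot))[cross])]) if len(cross) else 0
    # adjust the seed so the gauge holds exactly at jg
    prof = prof + (params.phi - rtot[jg]) / 3.0

    targets = np.array([params.phi_a / 2.0, params.phi_a / 2.0, params.phi_p])

    def residual(u):
        return _finite_L_residual(u, N, dz, L, Pe)

    def constraints(u):
        vals = np.empty(4)
        for k in range(3):
            vals[k] = u[k * N : (k + 1) * N].mean() - targets[k]
        vals[3] = u[jg] + u[N + jg] + u[2 * N + jg] - params.phi
        jac = np.zeros((4, 3 * N + 1))
        for k in range(3):
            jac[k, k * N : (k + 1) * N] = 1.0 / N
        jac[3, [jg, N + jg, 2 * N + jg]] = 1.0
        return vals, jac

    sys = BlockSystem(
        residual, constraints, n_blocks=3, N=N, n_extra=1,
        row_nodes=np.tile(np.arange(1, N), 3), periodic=True,
    )
    u0 = np.concatenate([prof.ravel(), [c0]])
    u, norm, ok = newton_solve(sys, u0, tol=tol, max_iter=max_iter)
    if not ok:
        raise RuntimeError(
            f"finite-L traveling solve did not converge (|F| = {norm:.3e})"
        )
    sol = TravelingSolution(
        z=z,
        profiles={"+": u[:N], "-": u[N : 2 * N], "0": u[2 * N : 3 * N]},
        c=float(u[3 * N]),
        residual_norm=float(norm),
        regime="finite-L",
        params=params,
    )
    return sol


# ---------------------------------------------------------------------------
# outer problem (unit-scaled coordinate zeta = z / L)
# ---------------------------------------------------------------------------


def _outer_flux(ra, r0, c, dz, Pe, periodic):
    """Face fluxes of the outer system between consecutive nodes."""
    if periodic:
        ra1, r01 = np.roll(ra, -1), np.roll(r0, -1)
    else:
        ra1, r01 = ra[1:], r0[1:]
        ra, r0 = ra[:-1], r0[:-1]
    raf = 0.5 * (ra + ra1)
    r0f = 0.5 * (r0 + r01)
    rf = raf + r0f
    ds_f, D_f, s_f = _coeffs(rf)
    r = ra + r0
    r1 = ra1 + r01
    ds_n, _, _ = _coeffs(r)
    ds_n1, _, _ = _coeffs(r1)
    w, w1 = ds_n * ra, ds_n1 * ra1
    dw = (w1 - w) / dz
    grad_r = (r1 - r) / dz
    fa = (
        c * raf
        + ds_f * (ra1 - ra) / dz
        + raf * D_f * grad_r
        + 0.5 * Pe * Pe * (raf * s_f + ds_f) * dw
    )
    f0 = (
        c * r0f
        + ds_f * (r01 - r0) / dz
        + r0f * D_f * grad_r
        + 0.5 * Pe * Pe * r0f * s_f * dw
    )
    return fa, f0


def _outer_periodic_residual(u, N, dz, Pe):
    ra, r0, c = u[:N], u[N : 2 * N], u[2 * N]
    fa, f0 = _outer_flux(ra, r0, c, dz, Pe, periodic=True)
    ra_res = (fa - np.roll(fa, 1)) / dz
    r0_res = (f0 - np.roll(f0, 1)) / dz
    return np.concatenate([ra_res[1:], r0_res[1:]])


def _outer_dirichlet_residual(u, N, dz, Pe, bc_v, bc_l):
    """Interior residuals with pinned endpoint values (vapor at 0, liquid at 1)."""
    ra = np.empty(N)
    r0 = np.empty(N)
    ra[0], r0[0] = bc_v
    ra[-1], r0[-1] = bc_l
    ra[1:-1] = u[: N - 2]
    r0[1:-1] = u[N - 2 : 2 * (N - 2)]
    c = u[2 * (N - 2)]
    fa, f0 = _outer_flux(ra, r0, c, dz, Pe, periodic=False)  # length N-1 faces
    ra_res = (fa[1:] - fa[:-1]) / dz
    r0_res = (f0[1:] - f0[:-1]) / dz
    return np.concatenate([ra_res, r0_res])


def solve_outer(
    phi_a: float,
    phi_p: float,
    Pe: float,
    N: int = 1024,
    n_interfaces: int | None = None,
    init_guess=None,
    tol: float = 1e-10,
    max_iter: int = 80,
) -> TravelingSolution:
    """Large-L outer traveling-wave problem at composition (phi_a, phi_p).

    Computes ``nu = phi_p/(1 - phi)`` and the coexistence endpoints at
    (Pe, nu).  If the binodal is degenerate there is no interface and
    the problem is solved periodically (smooth regime); otherwise the
    profile is solved on the unit interval with Dirichlet values equal
    to the vapor (left) and liquid (right) tie-line endpoints, plus the
    two species-mass constraints; the remaining unknown is the speed
    ``c``.  ``n_interfaces=2`` solves the two-segment problem with an
    interior interface at an unknown position and tie-line ratio (see
    :func:`insert_interface` for seeding).
    """
    from . import coexistence as cx

    phi = phi_a + phi_p
    if phi >= 1:
        raise ValueError("phi_a + phi_p must be < 1")
    nu = phi_p / (1.0 - phi)
    coex = cx.binodal_at_nu(Pe, nu)
    if n_interfaces is None:
        n_interfaces = 0 if coex.degenerate else 1

    if n_interfaces == 0:
        return _solve_outer_smooth(phi_a, phi_p, Pe, N, init_guess, tol, max_iter)
    if n_interfaces == 1:
        return _solve_outer_one(phi_a, phi_p, Pe, N, coex, init_guess, tol, max_iter)
    if n_interfaces == 2:
        return _solve_outer_two(phi_a, phi_p, Pe, N, coex, init_guess, tol, max_iter)
    raise ValueError("n_interfaces must be 0, 1 or 2")


def _solve_outer_smooth(phi_a, phi_p, Pe, N, init_guess, tol, max_iter):
    dz = 1.0 / N
    z = np.arange(N) * dz
    phi = phi_a + phi_p
    if init_guess is None:
        raise ValueError("smooth outer solve needs an initial guess")
    prof, c0 = init_guess
    prof = np.asarray(prof, dtype=float)
    if prof.shape[1] != N:
        zz = np.linspace(0, 1, prof.shape[1], endpoint=False)
        prof = np.stack([np.interp(z, zz, p) for p in prof])
    rtot = prof.sum(axis=0)
    cross = np.nonzero((rtot - phi) * (np.roll(rtot, -1) - phi) <= 0)[0]
    jg = int(cross[0]) if len(cross) else 0
    prof = prof + (phi - rtot[jg]) / 2.0

    def residual(u):
        return _outer_periodic_residual(u, N, dz, Pe)

    def constraints(u):
        vals = np.array(
            [
                u[:N].mean() - phi_a,
                u[N : 2 * N].mean() - phi_p,
                u[jg] + u[N + jg] - phi,
            ]
        )
        jac = np.zeros((3, 2 * N + 1))
        jac[0, :N] = 1.0 / N
        jac[1, N : 2 * N] = 1.0 / N
        jac[2, [jg, N + jg]] = 1.0
        return vals, jac

    sys = BlockSystem(
        residual, constraints, n_blocks=2, N=N, n_extra=1,
        row_nodes=np.tile(np.arange(1, N), 2), periodic=True,
    )
    u0 = np.concatenate([prof.ravel(), [c0]])
    u, norm, ok = newton_solve(sys, u0, tol=tol, max_iter=max_iter)
    if not ok:
        raise RuntimeError(f"smooth outer solve did not converge (|F|={norm:.2e})")
    params = ModelParams(Pe=Pe, L=1.0, phi_a=phi_a, phi_p=phi_p)
    return TravelingSolution(
        z=z,
        profiles={"a": u[:N], "0": u[N : 2 * N]},
        c=float(u[2 * N]),
        residual_norm=float(norm),
        regime="outer-smooth",
        params=params,
    )


def _endpoint_values(coex):
    (av, pv), (al, pl) = coex.endpoints
    return (av, pv), (al, pl)


_BINODAL_SPLINES: dict = {}


def _binodal_splines(Pe: float):
    """Cached cubic splines of (phi_v, phi_l)(nu) for interface endpoints."""
    if Pe not in _BINODAL_SPLINES:
        from scipy.interpolate import CubicSpline
        from . import coexistence as cx

        nu_c = cx.critical_nu(Pe)
        nus = np.linspace(1e-3, 0.995 * nu_c, 80)
        tab = [cx.binodal_at_nu(Pe, float(n)) for n in nus]
        _BINODAL_SPLINES[Pe] = (
            CubicSpline(nus, [r.phi_v for r in tab]),
            CubicSpline(nus, [r.phi_l for r in tab]),
            nu_c,
        )
    return _BINODAL_SPLINES[Pe]


def _tie_endpoints(Pe: float, nuh: float):
    sp_v, sp_l, _ = _binodal_splines(Pe)
    pv, pl = float(sp_v(nuh)), float(sp_l(nuh))
    return (pv - nuh * (1 - pv), nuh * (1 - pv)), (pl - nuh * (1 - pl), nuh * (1 - pl))


def _solve_outer_one(phi_a, phi_p, Pe, N, coex, init_guess, tol, max_iter):
    """Single-interface outer problem with the interface tie-line ratio as
    an unknown.

    The stationary-state relation ``nu = phi_p/(1-phi)`` does not bind
    traveling states (the fluxes J, J0 are nonzero); the interface ratio
    ``nu_hat`` is fixed by matching to the outer profile instead.  The
    Dirichlet endpoint values are the coexistence endpoints at
    ``(Pe, nu_hat)``; the two species-mass constraints close the system
    for the unknowns (interior profiles, c, nu_hat).  Eq-(5)'s nu serves
    as the seed for ``nu_hat``.
    """
    dz = 1.0 / (N - 1)
    z = np.linspace(0.0, 1.0, N)
    nu0 = coex.nu

    if init_guess is None:
        bc_v, bc_l = _tie_endpoints(Pe, nu0)
        ra = bc_v[0] + (bc_l[0] - bc_v[0]) * z
        r0 = bc_v[1] + (bc_l[1] - bc_v[1]) * z
        c0 = 1.0
    else:
        if len(init_guess) == 3:
            prof, c0, nu0 = init_guess
        else:
            prof, c0 = init_guess
        prof = np.asarray(prof, dtype=float)
        zz = np.linspace(0, 1, prof.shape[1])
        ra = np.interp(z, zz, prof[0])
        r0 = np.interp(z, zz, prof[1])

    wts = np.full(N, dz)
    wts[0] = wts[-1] = 0.5 * dz
    M = N - 2

    def build(u):
        rra = np.empty(N)
        rr0 = np.empty(N)
        rra[1:-1] = u[:M]
        rr0[1:-1] = u[M : 2 * M]
        c, nuh = u[2 * M], u[2 * M + 1]
        bc_v, bc_l = _tie_endpoints(Pe, nuh)
        rra[0], rr0[0] = bc_v
        rra[-1], rr0[-1] = bc_l
        return rra, rr0, c

    def residual(u):
        rra, rr0, c = build(u)
        fa, f0 = _outer_flux(rra, rr0, c, dz, Pe, periodic=False)
        return np.concatenate([(fa[1:] - fa[:-1]) / dz, (f0[1:] - f0[:-1]) / dz])

    def constraints(u):
        rra, rr0, _ = build(u)
        vals = np.array(
            [(wts * rra).sum() - phi_a, (wts * rr0).sum() - phi_p]
        )
        jac = np.zeros((2, 2 * M + 2))
        jac[0, :M] = wts[1:-1]
        jac[1, M : 2 * M] = wts[1:-1]
        eps = 1e-7
        u2 = u.copy()
        u2[2 * M + 1] += eps
        rra2, rr02, _ = build(u2)
        v2 = np.array([(wts * rra2).sum() - phi_a, (wts * rr02).sum() - phi_p])
        jac[:, 2 * M + 1] = (v2 - vals) / eps
        return vals, jac

    sys = BlockSystem(
        residual, constraints, n_blocks=2, N=M, n_extra=2,
        row_nodes=np.tile(np.arange(M), 2), periodic=False,
    )
    u0 = np.concatenate([ra[1:-1], r0[1:-1], [c0, nu0]])
    u, norm, ok = newton_solve(sys, u0, tol=tol, max_iter=max_iter)
    nuh = float(u[2 * M + 1])
    _, _, nu_c = _binodal_splines(Pe)
    if not ok or not (0 < nuh < nu_c):
        raise RuntimeError(
            f"single-interface outer solve did not converge (|F|={norm:.2e}, "
            f"nu_hat={nuh:.3f}); a second interface may be required"
        )
    rra, rr0, c = build(u)
    params = ModelParams(Pe=Pe, L=1.0, phi_a=phi_a, phi_p=phi_p)
    sp_v, sp_l, _ = _binodal_splines(Pe)
    return TravelingSolution(
        z=z,
        profiles={"a": rra, "0": rr0},
        c=float(c),
        residual_norm=float(norm),
        regime="outer-1-interface",
        params=params,
        interfaces=[{"zeta": 0.0, "nu": nuh,
                     "phi_v": float(sp_v(nuh)), "phi_l": float(sp_l(nuh))}],
        meta={"nu_eq5": coex.nu, "nu_hat": nuh},
    )


def _solve_outer_two(phi_a, phi_p, Pe, N, coex, init_guess, tol, max_iter):
    """Two-interface outer problem.

    The domain splits into two smooth segments separated by an interior
    interface at unknown position ``zeta_1`` whose jump follows the tie
    line of an unknown local ratio ``nu_hat``; the boundary interface at
    ``zeta = 0 == 1`` follows the global-``nu`` tie line.  Unknowns:
    the two segment profiles, ``c``, ``zeta_1`` and ``nu_hat``.  The
    interior-interface endpoint values come from the coexistence
    construction at ``(Pe, nu_hat)`` (cached spline over ``nu``).
    Solved as a bordered Newton system with flux continuity across the
    interior interface closing the count.
    """
    from . import coexistence as cx
    from scipy.interpolate import CubicSpline

    bc_v, bc_l = _endpoint_values(coex)
    nu = coex.nu

    # spline of the binodal in nu for fast interior-endpoint evaluation
    nu_c = cx.critical_nu(Pe)
    nus = np.linspace(max(1e-4, 0.2 * nu), 0.999 * nu_c, 60)
    pv_tab, pl_tab = [], []
    for nn in nus:
        r = cx.binodal_at_nu(Pe, nn)
        pv_tab.append(r.phi_v)
        pl_tab.append(r.phi_l)
    sp_v = CubicSpline(nus, pv_tab)
    sp_l = CubicSpline(nus, pl_tab)

    if init_guess is None:
        raise ValueError("two-interface solve needs an initial guess "
                         "(use insert_interface on a failed single-interface seed)")
    (prof1, prof2, c0, z1_0, nuh_0) = init_guess
    n1 = prof1.shape[1]
    n2 = prof2.shape[1]

    def endpoints_hat(nuh):
        pv, pl = float(sp_v(nuh)), float(sp_l(nuh))
        vap = (pv - nuh * (1 - pv), nuh * (1 - pv))
        liq = (pl - nuh * (1 - pl), nuh * (1 - pl))
        return vap, liq

    def unpack(u):
        i = 0
        s1a = u[i : i + n1 - 2]; i += n1 - 2
        s10 = u[i : i + n1 - 2]; i += n1 - 2
        s2a = u[i : i + n2 - 2]; i += n2 - 2
        s20 = u[i : i + n2 - 2]; i += n2 - 2
        c, z1, nuh = u[i], u[i + 1], u[i + 2]
        return s1a, s10, s2a, s20, c, z1, nuh

    def residual(u):
        s1a, s10, s2a, s20, c, z1, nuh = unpack(u)
        vap_h, liq_h = endpoints_hat(nuh)
        # segment 1: from global vapor endpoint (z=0) up to vapor side of
        # the interior interface (z=z1); segment 2: liquid side of the
        # interior interface (z=z1) to global liquid endpoint (z=1).
        dz1 = z1 / (n1 - 1)
        dz2 = (1.0 - z1) / (n2 - 1)
        ra1 = np.concatenate([[bc_v[0]], s1a, [vap_h[0]]])
        r01 = np.concatenate([[bc_v[1]], s10, [vap_h[1]]])
        ra2 = np.concatenate([[liq_h[0]], s2a, [bc_l[0]]])
        r02 = np.concatenate([[liq_h[1]], s20, [bc_l[1]]])
        fa1, f01 = _outer_flux(ra1, r01, c, dz1, Pe, periodic=False)
        fa2, f02 = _outer_flux(ra2, r02, c, dz2, Pe, periodic=False)
        res = [
            (fa1[1:] - fa1[:-1]) / dz1,
            (f01[1:] - f01[:-1]) / dz1,
            (fa2[1:] - fa2[:-1]) / dz2,
            (f02[1:] - f02[:-1]) / dz2,
        ]
        return np.concatenate(res)

    def constraints(u):
        s1a, s10, s2a, s20, c, z1, nuh = unpack(u)
        vap_h, liq_h = endpoints_hat(nuh)
        dz1 = z1 / (n1 - 1)
        dz2 = (1.0 - z1) / (n2 - 1)
        ra1 = np.concatenate([[bc_v[0]], s1a, [vap_h[0]]])
        r01 = np.concatenate([[bc_v[1]], s10, [vap_h[1]]])
        ra2 = np.concatenate([[liq_h[0]], s2a, [bc_l[0]]])
        r02 = np.concatenate([[liq_h[1]], s20, [bc_l[1]]])
        mass_a = np.trapezoid(ra1, dx=dz1) + np.trapezoid(ra2, dx=dz2) - phi_a
        mass_0 = np.trapezoid(r01, dx=dz1) + np.trapezoid(r02, dx=dz2) - phi_p
        # flux continuity across the interior interface (leading order)
        fa1, f01 = _outer_flux(ra1[-2:], r01[-2:], c, dz1, Pe, periodic=False)
        fa2, f02 = _outer_flux(ra2[:2], r02[:2], c, dz2, Pe, periodic=False)
        cont_a = fa1[-1] - fa2[0]
        cont_0 = f01[-1] - f02[0]
        vals = np.array([mass_a, mass_0, cont_a, cont_0])
        # constraint Jacobian by finite differences (cheap: 4 x n)
        eps = 1e-7
        jac = np.zeros((4, len(u)))
        base = vals

        def cvals(uu):
            s1a, s10, s2a, s20, c, z1, nuh = unpack(uu)
            vap_h, liq_h = endpoints_hat(nuh)
            dz1 = z1 / (n1 - 1)
            dz2 = (1.0 - z1) / (n2 - 1)
            ra1 = np.concatenate([[bc_v[0]], s1a, [vap_h[0]]])
            r01 = np.concatenate([[bc_v[1]], s10, [vap_h[1]]])
            ra2 = np.concatenate([[liq_h[0]], s2a, [bc_l[0]]])
            r02 = np.concatenate([[liq_h[1]], s20, [bc_l[1]]])
            ma = np.trapezoid(ra1, dx=dz1) + np.trapezoid(ra2, dx=dz2) - phi_a
            m0 = np.trapezoid(r01, dx=dz1) + np.trapezoid(r02, dx=dz2) - phi_p
            fa1, f01 = _outer_flux(ra1[-2:], r01[-2:], c, dz1, Pe, periodic=False)
            fa2, f02 = _outer_flux(ra2[:2], r02[:2], c, dz2, Pe, periodic=False)
            return np.array([ma, m0, fa1[-1] - fa2[0], f01[-1] - f02[0]])

        for k in range(len(u)):
            du = np.zeros_like(u)
            du[k] = eps
            jac[:, k] = (cvals(u + du) - base) / eps
        return vals, jac

    # the segment-length dependence of dz makes every row depend on
    # (c, z1, nuh); solve the bordered system as sparse least squares
    from scipy.optimize import least_squares

    def full_res(u):
        cv, _ = constraints(u)
        return np.concatenate([residual(u), cv])

    u0 = np.concatenate(
        [prof1[0][1:-1], prof1[1][1:-1], prof2[0][1:-1], prof2[1][1:-1],
         [c0, z1_0, nuh_0]]
    )
    # sparsity pattern: banded within segments, dense in the 3 parameters
    import scipy.sparse as spm

    nres = 2 * (n1 - 2) + 2 * (n2 - 2) + 4
    S = spm.lil_matrix((nres, len(u0)), dtype=bool)
    off_r = 0
    off_c = 0
    for nn in (n1 - 2, n1 - 2, n2 - 2, n2 - 2):
        for i in range(nn):
            S[off_r + i, off_c + max(0, i - 1) : off_c + min(nn, i + 2)] = True
        off_r += nn
        off_c += nn
    S[:, -3:] = True
    S[-4:, :] = True
    sol = least_squares(
        full_res, u0, jac_sparsity=S, method="trf",
        xtol=3e-16, ftol=3e-16, gtol=1e-14, max_nfev=400,
    )
    norm = np.linalg.norm(full_res(sol.x), np.inf)
    if norm > 1e-7:
        raise RuntimeError(
            f"two-interface outer solve did not converge (|F|={norm:.2e})"
        )
    s1a, s10, s2a, s20, c, z1, nuh = unpack(sol.x)
    vap_h, liq_h = endpoints_hat(nuh)
    z_1 = np.linspace(0, z1, n1)
    z_2 = np.linspace(z1, 1.0, n2)
    ra = np.concatenate([[bc_v[0]], s1a, [vap_h[0]], [liq_h[0]], s2a, [bc_l[0]]])
    r0 = np.concatenate([[bc_v[1]], s10, [vap_h[1]], [liq_h[1]], s20, [bc_l[1]]])
    z = np.concatenate([z_1, z_2])
    params = ModelParams(Pe=Pe, L=1.0, phi_a=phi_a, phi_p=phi_p)
    return TravelingSolution(
        z=z,
        profiles={"a": ra, "0": r0},
        c=float(c),
        residual_norm=float(norm),
        regime="outer-2-interface",
        params=params,
        interfaces=[
            {"zeta": 0.0, "nu": nu, "phi_v": coex.phi_v, "phi_l": coex.phi_l},
            {"zeta": float(z1), "nu": float(nuh),
             "phi_v": float(sp_v(nuh)), "phi_l": float(sp_l(nuh))},
        ],
        meta={"nu_hat": float(nuh), "zeta_1": float(z1)},
    )


def continue_in_L(
    params: ModelParams,
    prof: np.ndarray,
    c: float,
    L_targets: tuple = (35, 50, 70, 100, 140),
    points_per_unit: float = 20.0,
) -> tuple[np.ndarray, float, list]:
    """Thread a finite-L traveling solution along increasing L.

    Returns the final (profiles, c) plus the list of (L, c) pairs.  The
    grid resolution keeps ~``points_per_unit`` nodes per unit length so
    the O(1)-wide interface stays resolved.
    """
    history = [(params.L, c)]
    for L in L_targets:
        p = params.replace(L=float(L))
        N = int(round(points_per_unit * L))
        sol = solve_finite_L(p, N=N, init_guess=(prof, c))
        prof = np.stack([sol.profiles[k] for k in ("+", "-", "0")])
        c = sol.c
        history.append((float(L), c))
    return prof, c, history


def _continue_in_L_tolerant(params, prof, c, L_targets, points_per_unit):
    """Like continue_in_L but stops at the first non-convergent step."""
    history = [(params.L, c)]
    for L in L_targets:
        p = params.replace(L=float(L))
        N = int(round(points_per_unit * L))
        try:
            sol = solve_finite_L(p, N=N, init_guess=(prof, c))
        except RuntimeError:
            break
        prof = np.stack([sol.profiles[k] for k in ("+", "-", "0")])
        c = sol.c
        history.append((float(L), c))
    return prof, c, history


def outer_speed_by_continuation(
    phi_a: float,
    phi_p: float,
    Pe: float,
    prof: np.ndarray,
    c: float,
    L_start: float = 140.0,
    L_targets: tuple = (200, 280, 400),
    points_per_unit: float = 20.0,
) -> tuple[float, list]:
    """Wave speed of the large-L outer problem by 1/L extrapolation.

    Solves the co-moving finite-L problem at increasing L and Richardson-
    extrapolates c in 1/L from the last two solves.  This evaluates the
    outer (thermodynamic-limit) speed through its defining limit, which
    is insensitive to how the interface boundary layer would have to be
    truncated in a direct Dirichlet discretization of the outer
    equations.
    """
    params = ModelParams(Pe=Pe, L=L_start, phi_a=phi_a, phi_p=phi_p)
    # intermediate rungs give a usable extrapolation even if the branch
    # becomes hard to thread at the largest domains
    ladder = tuple(sorted(set(L_targets) | {int(1.2 * L_start)}))
    _, c_end, hist = _continue_in_L_tolerant(
        params, prof, c, ladder, points_per_unit
    )
    if len(hist) < 2:
        raise RuntimeError(
            f"L-continuation failed immediately at ({phi_a}, {phi_p})"
        )
    (L1, c1), (L2, c2) = hist[-2], hist[-1]
    a = (c1 - c2) / (1.0 / L1 - 1.0 / L2)
    c_inf = c2 - a / L2
    return float(c_inf), hist


def insert_interface(solution: TravelingSolution) -> float:
    """Steepest-gradient location for seeding an extra interface.

    Returns ``z*`` = argmax over z of ``|d rho / dz|`` (ties broken to
    the smaller z).  Raises for essentially flat profiles.
    """
    rho = solution.rho
    dz = np.diff(solution.z)
    if np.any(dz <= 0):
        grad = np.gradient(rho, solution.z)
    else:
        grad = np.gradient(rho, solution.z)
    amax = np.abs(grad).max()
    if amax < 1e-8:
        raise ValueError("flat profile: no interface location to insert")
    idx = int(np.argmax(np.abs(grad) >= amax * (1 - 1e-12)))
    return float(solution.z[idx])


def no_traveling_ps_check(
    solution: TravelingSolution,
    grad_threshold: float = 5e-2,
    min_plateau_fraction: float = 0.10,
    flatness: float = 5e-2,
    tol: float = 1e-4,
) -> dict:
    """Plateau theorem check: a traveling (c != 0) profile cannot hold two
    bulk plateaus of different density.

    A plateau is a maximal run with ``|rho'|`` below ``grad_threshold``
    covering at least ``min_plateau_fraction`` of the domain *and* with
    total density variation below ``flatness`` (this distinguishes true
    bulks from the smoothly varying outer regions of traveling profiles,
    whose gradients are O(1/L) but whose variation stays O(1)).
    Returns a dict with ``verdict`` (pass/fail), the plateau mean
    densities and their spread.  The theorem is silent for c = 0
    (stationary phase separation has two genuine bulks).
    """
    rho = solution.rho
    z = solution.z
    n = len(z)
    grad = np.gradient(rho, z)
    flat = np.abs(grad) < grad_threshold
    plateaus = []
    idx = np.nonzero(flat)[0]
    if len(idx):
        splits = np.nonzero(np.diff(idx) > 1)[0]
        runs = np.split(idx, splits + 1)
        # merge wrap-around run
        if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
            runs[0] = np.concatenate([runs[-1], runs[0]])
            runs = runs[:-1]
        for run in runs:
            if (
                len(run) >= min_plateau_fraction * n
                and rho[run].max() - rho[run].min() < flatness
            ):
                plateaus.append(float(rho[run].mean()))
    spread = max(plateaus) - min(plateaus) if len(plateaus) >= 2 else 0.0
    traveling = abs(solution.c) > 1e-8
    verdict = (not traveling) or len(plateaus) < 2 or spread < tol
    return {
        "verdict": bool(verdict),
        "c": solution.c,
        "plateaus": plateaus,
        "spread": spread,
        "n_plateaus": len(plateaus),
    }
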