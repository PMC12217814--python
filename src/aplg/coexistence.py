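"""Phase coexistence: binodal, tie lines and interface profiles.

For stationary phase-separated states in large domains the passive
density is slaved to the vacancies, ``rho_0 = nu (1 - rho)`` with
``nu = phi_p / (1 - phi)``, and the total density obeys the planar
profile equation

    g(rho, rho', rho'') = g0(rho) + Lam(rho) rho'^2 - kap(rho) rho''
                        = const,

obtained by eliminating the magnetization from the stationary
hydrodynamics (zero-flux first integrals).  The elimination gives in
closed form

    g0(rho)  = -(2/Pe) ln(1 - rho) + Pe d_s(rho) [rho - nu (1 - rho)],
    Lam(rho) = -2 d_s(rho) / (Pe (1 - rho)^2),
    kap(rho) =  d_s(rho) / (Pe (1 - rho)),

(derived by computer algebra and frozen here; a residual oracle on
relaxed PDE steady states validates them in the test suite).  ``g0``
plays the role of a chemical potential.  The gradient terms become exact
against a transformed density ``R(rho)`` satisfying
``kap R'' + (Lam + kap') R' = 0``; for these coefficients the quadrature
is elementary:

    R'(rho) = 1 / ((1 - rho) d_s(rho)),

and an effective free energy ``Phi(R)`` with ``dPhi/dR = g0`` turns the
coexistence problem into the classical common-tangent construction:
``g0(phi_v) = g0(phi_l)`` and equal tangent intercepts of ``Phi(R)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .coefficients import self_diffusion, self_diffusion_deriv

__all__ = [
    "effective_terms",
    "EffectiveTerms",
    "CoexistenceResult",
    "binodal_at_nu",
    "binodal_curve",
    "critical_nu",
    "tie_line",
    "interface_profile",
]


@dataclass(frozen=True)
class EffectiveTerms:
    """Callables (g0, Lam, kap, R, R') for given (Pe, nu)."""

    Pe: float
    nu: float

    def g0(self, rho):
        rho = np.asarray(rho, dtype=float)
        ds = self_diffusion(rho)
        return -(2.0 / self.Pe) * np.log1p(-rho) + self.Pe * ds * (
            rho - self.nu * (1.0 - rho)
        )

    def g0_deriv(self, rho):
        rho = np.asarray(rho, dtype=float)
        ds = self_diffusion(rho)
        dsp = self_diffusion_deriv(rho)
        return (2.0 / self.Pe) / (1.0 - rho) + self.Pe * (
            dsp * (rho - self.nu * (1.0 - rho)) + ds * (1.0 + self.nu)
        )

    def g0_u(self, u):
        """g0 evaluated at rho = 1 - exp(-u), stable for large u.

        The liquid binodal branch can lie exponentially close to full
        packing at large Pe; this form avoids catastrophic rounding in
        ``1 - rho``.
        """
        u = np.asarray(u, dtype=float)
        one_minus = np.exp(-u)
        rho = -np.expm1(-u)
        from .coefficients import ALPHA, BETA

        poly = 1.0 - ALPHA * rho + BETA * rho * rho
        ds = one_minus * poly
        return (2.0 / self.Pe) * u + self.Pe * ds * (
            rho - self.nu * one_minus
        )

    def Lam(self, rho):
        rho = np.asarray(rho, dtype=float)
        return -2.0 * self_diffusion(rho) / (self.Pe * (1.0 - rho) ** 2)

    def kap(self, rho):
        rho = np.asarray(rho, dtype=float)
        return self_diffusion(rho) / (self.Pe * (1.0 - rho))

    def R_deriv(self, rho):
        rho = np.asarray(rho, dtype=float)
        return 1.0 / ((1.0 - rho) * self_diffusion(rho))

    def R(self, rho):
        """R(rho) by quadrature from the reference density 0.5.

        Only differences of R matter; the gauge (reference point and
        overall scale) drops out of the construction.
        """
        scalar = np.isscalar(rho) or np.ndim(rho) == 0
        rr = np.atleast_1d(np.asarray(rho, dtype=float))
        out = np.array([quad(self.R_deriv, 0.5, r, limit=200)[0] for r in rr])
        return float(out[0]) if scalar else out

    def g_residual(self, rho, d1, d2):
        """g(rho, rho', rho'') for profile arrays (constant at coexistence)."""
        return self.g0(rho) + self.Lam(rho) * d1**2 - self.kap(rho) * d2


def effective_terms(Pe: float, nu: float) -> EffectiveTerms:
    """Effective-potential terms of the profile equation at (Pe, nu)."""
    if Pe <= 0:
        raise ValueError("Pe must be positive")
    if nu < 0:
        raise ValueError("nu must be non-negative")
    return EffectiveTerms(Pe, nu)


@dataclass
class CoexistenceResult:
    """Coexisting bulk states at fixed (Pe, nu)."""

    Pe: float
    nu: float
    phi_v: float
    phi_l: float
    terms: EffectiveTerms

    @property
    def degenerate(self) -> bool:
        return abs(self.phi_l - self.phi_v) < 1e-10

    def endpoint(self, which: str) -> tuple[float, float]:
        """Tie-line endpoint (phi_a, phi_p) of the vapor or liquid phase."""
        rho = {"vapor": self.phi_v, "liquid": self.phi_l}[which]
        rho0 = self.nu * (1.0 - rho)
        return rho - rho0, rho0

    @property
    def endpoints(self) -> np.ndarray:
        return np.array([self.endpoint("vapor"), self.endpoint("liquid")])


def _spinodal_interval(t: EffectiveTerms) -> tuple[float, float] | None:
    """Interval where g0 decreases (local instability of the bulk term)."""
    rho = np.linspace(1e-4, 0.999, 4001)
    dg = t.g0_deriv(rho)
    neg = np.where(dg < 0)[0]
    if len(neg) == 0:
        return None
    lo_i, hi_i = neg[0], neg[-1]
    lo = brentq(t.g0_deriv, rho[max(lo_i - 1, 0)], rho[lo_i]) if lo_i > 0 else rho[0]
    hi = (
        brentq(t.g0_deriv, rho[hi_i], rho[min(hi_i + 1, len(rho) - 1)])
        if hi_i < len(rho) - 1
        else rho[-1]
    )
    return lo, hi


def binodal_at_nu(Pe: float, nu: float) -> CoexistenceResult:
    """Coexisting densities (phi_v, phi_l) by the common-tangent construction.

    Solves ``g0(phi_v) = g0(phi_l) = gbar`` together with the
    equal-intercept condition
    ``int_{phi_v}^{phi_l} (g0(rho) - gbar) R'(rho) drho = 0``.
    The two coupled conditions reduce to a single monotone scalar problem
    in the common level ``gbar``, bracketed between the local extrema of
    ``g0`` and solved by bisection; this is robust arbitrarily close to
    the critical point.  At/below the critical point the degenerate
    result ``phi_v = phi_l`` (the marginal density) is returned.
    """
    t = effective_terms(Pe, nu)
    iv = _spinodal_interval(t)
    if iv is None:
        # above the critical point: g0 monotone, single phase; return the
        # degenerate result at the marginal (inflection) density
        rho = np.linspace(1e-3, 0.999, 2001)
        mid = float(rho[np.argmin(t.g0_deriv(rho))])
        return CoexistenceResult(Pe, nu, mid, mid, t)
    lo, hi = iv
    g_hi = float(t.g0(lo))  # local max of g0 (left edge of decreasing branch)
    g_lo = float(t.g0(hi))  # local min

    tiny = 1e-11

    def outer_roots(gbar):
        """Vapor/liquid roots of g0 = gbar outside the unstable interval."""
        a = 1e-9
        if t.g0(a) > gbar - 1e-15:
            pv = a
        else:
            pv = brentq(lambda r: t.g0(r) - gbar, a, lo, xtol=1e-15)
        # liquid root in u = -log(1 - rho): resolves rho arbitrarily close to 1
        def f_u(u):
            return t.g0_u(u) - gbar

        u_lo = -np.log1p(-hi)
        u_hi = u_lo + 1.0
        while f_u(u_hi) < 0 and u_hi < 600.0:
            u_hi += 5.0
        ul = brentq(f_u, u_lo, u_hi, xtol=1e-14, rtol=8.9e-16)
        return pv, ul  # liquid phase returned as u-coordinate

    from .coefficients import ALPHA, BETA

    def equal_area(gbar):
        pv, ul = outer_roots(gbar)
        # split at the unstable interval's upper edge; integrate the upper
        # part in u = -log(1-rho) where R' drho = e^u du / poly(rho)
        u_split = -np.log1p(-hi)
        part1 = quad(
            lambda r: (t.g0(r) - gbar) * t.R_deriv(r), pv, hi, limit=400
        )[0]

        def integrand_u(u):
            rho = -np.expm1(-u)
            poly = 1.0 - ALPHA * rho + BETA * rho * rho
            return (t.g0_u(u) - gbar) * np.exp(u) / poly

        part2 = quad(integrand_u, u_split, ul, limit=400)[0]
        return part1 + part2

    a = g_lo + tiny * max(1.0, abs(g_lo))
    b = g_hi - tiny * max(1.0, abs(g_hi))
    if not (a < b):
        mid = 0.5 * (lo + hi)
        return CoexistenceResult(Pe, nu, mid, mid, t)
    fa, fb = equal_area(a), equal_area(b)
    if fa * fb > 0:
        # extremely shallow double well: effectively at the critical point
        mid = 0.5 * (lo + hi)
        return CoexistenceResult(Pe, nu, mid, mid, t)
    gbar = brentq(equal_area, a, b, xtol=1e-15, rtol=8.9e-16)
    pv, ul = outer_roots(gbar)
    pl = -float(np.expm1(-ul))
    return CoexistenceResult(Pe, nu, pv, pl, t)


def critical_nu(Pe: float, nu_hi: float = 4.0) -> float:
    """Largest nu with a genuine coexistence region at this Pe."""

    def has_coex(nu):
        return _spinodal_interval(effective_terms(Pe, nu)) is not None

    if not has_coex(0.0):
        raise ValueError(f"no phase separation at Pe={Pe} even for nu=0")
    if has_coex(nu_hi):
        return nu_hi
    return brentq(lambda nu: 1.0 if has_coex(nu) else -1.0, 0.0, nu_hi, xtol=1e-10)


def binodal_curve(Pe: float, n_nu: int = 60) -> dict:
    """Binodal swept in nu with continuation; returns curve data.

    The returned dict has keys ``nu`` (n,), ``phi_v``/``phi_l`` (n,), and
    ``points`` (2n, 2): (phi_a, phi_p) pairs of both branches, vapor
    branch followed by the reversed liquid branch (a connected curve).
    """
    nu_c = critical_nu(Pe)
    nus = nu_c * (1.0 - (1.0 - np.linspace(0.0, 1.0, n_nu)) ** 2)  # dense near nu_c
    pv_list, pl_list, nu_list = [], [], []
    for nu in nus:
        res = binodal_at_nu(Pe, nu)
        if res.degenerate:
            break
        nu_list.append(nu)
        pv_list.append(res.phi_v)
        pl_list.append(res.phi_l)
    nu_arr = np.array(nu_list)
    pv = np.array(pv_list)
    pl = np.array(pl_list)
    vap = np.column_stack([pv - nu_arr * (1 - pv), nu_arr * (1 - pv)])
    liq = np.column_stack([pl - nu_arr * (1 - pl), nu_arr * (1 - pl)])
    pts = np.vstack([vap, liq[::-1]])
    return {"nu": nu_arr, "phi_v": pv, "phi_l": pl, "points": pts}


def tie_line(phi_a: float, phi_p: float, Pe: float) -> dict:
    """Tie line through the state point (phi_a, phi_p).

    Computes ``nu = phi_p/(1 - phi)``, the coexisting endpoints at that
    nu, and the lever-rule volume fraction of liquid.  Raises if the
    point is outside the binodal (single phase).
    """
    phi = phi_a + phi_p
    if phi >= 1:
        raise ValueError("phi_a + phi_p must be < 1")
    nu = phi_p / (1.0 - phi)
    res = binodal_at_nu(Pe, nu)
    if res.degenerate or not (res.phi_v < phi < res.phi_l):
        raise ValueError(
            f"({phi_a}, {phi_p}) is outside the binodal at Pe={Pe}: single phase"
        )
    x_l = (phi - res.phi_v) / (res.phi_l - res.phi_v)
    return {
        "nu": nu,
        "phi_v": res.phi_v,
        "phi_l": res.phi_l,
        "endpoints": res.endpoints,
        "liquid_fraction": x_l,
        "result": res,
    }


def interface_profile(
    Pe: float,
    nu: float,
    half_width: float = 15.0,
    n: int = 801,
    coex: CoexistenceResult | None = None,
) -> dict:
    """Stationary liquid-vapor interface profile at (Pe, nu).

    Solves ``kap rho'' = g0(rho) - g0(phi_v) + Lam rho'^2`` as a boundary
    value problem on ``[-half_width, half_width]`` connecting the vapor
    bulk (left) to the liquid bulk (right); the translational gauge is
    fixed by the finite domain with Dirichlet ends.  Returns x, rho, m,
    rho_0, rho_a arrays; ``m = rho' / (Pe (1 - rho))`` from the zero-flux
    first integral and ``rho_0 = nu (1 - rho)``.
    """
    res = coex if coex is not None else binodal_at_nu(Pe, nu)
    if res.degenerate:
        raise ValueError("no interface at/below the critical point")
    t = res.terms
    gbar = float(t.g0(res.phi_v))

    # The profile equation kap*rho'' = g0 - gbar + Lam*(rho')**2 becomes,
    # with p(rho) = (rho')**2, the *linear* first-order ODE
    #     dp/drho = 2 (g0(rho) - gbar)/kap(rho) + (2 Lam(rho)/kap(rho)) p,
    # integrated from the vapor density (p = 0 there; the coexistence
    # construction guarantees p returns to 0 at the liquid density).
    from scipy.integrate import solve_ivp

    pv, pl = res.phi_v, res.phi_l
    eps = 1e-6 * (pl - pv)

    def dpdr(rho, p):
        return 2.0 * (t.g0(rho) - gbar) / t.kap(rho) + (
            2.0 * t.Lam(rho) / t.kap(rho)
        ) * p

    p0 = float(t.g0_deriv(pv) / t.kap(pv)) * eps**2  # quadratic start
    rho_grid = np.linspace(pv + eps, pl - eps, 6 * n)
    ivp = solve_ivp(
        dpdr, (rho_grid[0], rho_grid[-1]), [p0], t_eval=rho_grid,
        rtol=1e-11, atol=1e-14, method="LSODA",
    )
    if not ivp.success:
        raise RuntimeError(f"interface quadrature failed: {ivp.message}")
    p = np.clip(ivp.y[0], 0.0, None)
    if p[-1] > 1e-4 * p.max():
        raise RuntimeError(
            "interface profile does not close: (rho')^2 nonzero at the "
            f"liquid density (residual {p[-1]:.2e})"
        )
    # x(rho) by quadrature of 1/rho' (log tails clipped at the endpoints)
    interior = p > 1e-14
    rr = rho_grid[interior]
    drho_drr = np.sqrt(p[interior])
    dx = np.diff(rr) / (0.5 * (drho_drr[1:] + drho_drr[:-1]))
    x_of_rho = np.concatenate([[0.0], np.cumsum(dx)])
    mid = 0.5 * (pv + pl)
    x_of_rho -= np.interp(mid, rr, x_of_rho)  # gauge: rho(0) = midpoint
    xs = np.linspace(-half_width, half_width, n)
    rho = np.interp(xs, x_of_rho, rr, left=pv, right=pl)
    drho = np.interp(xs, x_of_rho, drho_drr, left=0.0, right=0.0)
    m = drho / (Pe * (1.0 - rho))
    rho0 = nu * (1.0 - rho)
    return {
        "x": xs,
        "rho": rho,
        "drho": drho,
        "m": m,
        "rho_0": rho0,
        "rho_a": rho - rho0,
        "result": res,
    }
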