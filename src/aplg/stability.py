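"""Linear stability of homogeneous states.

Perturbing the uniform state ``rho_+- = phi_a/2``, ``rho_0 = phi_p`` with
plane waves ``delta * A_sigma * exp(lambda*t + i*q*x)`` reduces the
linearized hydrodynamics to a 3x3 eigenvalue problem
``lambda A = M(q) A``.  At ``q = 0`` the spectrum is exactly
``{0, 0, -2}``: two conserved densities plus the magnetization relaxing
at twice the tumble rate.  The homogeneous state is unstable when any
branch has ``Re lambda > 0`` at some wavenumber; the spinodal is the
locus in the ``(phi_a, phi_p)`` plane where the supremum over continuous
``q`` of the dominant growth rate crosses zero.  Points where the
dominant eigenvalue at the fastest-growing wavenumber switches between
real and complex along the spinodal are codimension-two
(Bogdanov-Takens) points; a complex dominant eigenvalue signals an
oscillatory (Hopf-like) instability and heralds traveling or
counter-propagating patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coefficients import (
    CoefficientSet,
    DEFAULT_COEFFS,
)
from .params import ModelParams

__all__ = [
    "stability_matrix",
    "DispersionResult",
    "dispersion",
    "growth_rate_max",
    "most_unstable_mode",
    "spinodal",
    "bogdanov_takens_points",
]


def stability_matrix(
    q: float, params: ModelParams, coeffs: CoefficientSet = DEFAULT_COEFFS
) -> np.ndarray:
    """3x3 complex matrix of the linearization at wavenumber ``q``.

    Species order (+, -, 0).  Assembled from the analytic derivatives of
    the transport coefficients at the mean density ``phi``.
    """
    phi = params.phi
    pp = params.phi_a / 2.0
    pm = params.phi_a / 2.0
    p0 = params.phi_p
    ds = coeffs.d_s(phi)
    dsp = coeffs.d_s_deriv(phi)
    D = coeffs.D(phi)
    s = coeffs.s(phi)
    Pe = params.Pe
    q2 = q * q
    iqPe = 1j * q * Pe

    M = np.empty((3, 3), dtype=complex)
    # sigma = +1 row
    M[0, 0] = -q2 * (ds + pp * D) - iqPe * (pp * s + ds + dsp * pp) - 1.0
    M[0, 1] = -q2 * pp * D - iqPe * (-pp * s + dsp * pp) + 1.0
    M[0, 2] = -q2 * pp * D - iqPe * dsp * pp
    # sigma = -1 row
    M[1, 0] = -q2 * pm * D - iqPe * (pm * s - dsp * pm) + 1.0
    M[1, 1] = -q2 * (ds + pm * D) - iqPe * (-pm * s - ds - dsp * pm) - 1.0
    M[1, 2] = -q2 * pm * D + iqPe * dsp * pm
    # sigma = 0 row
    M[2, 0] = -q2 * p0 * D - iqPe * p0 * s
    M[2, 1] = -q2 * p0 * D + iqPe * p0 * s
    M[2, 2] = -q2 * (ds + p0 * D)
    return M


@dataclass
class DispersionResult:
    """Eigenvalue branches on a wavenumber grid, tracked by eigenvector overlap."""

    q: np.ndarray
    branches: np.ndarray        # (nq, 3) complex eigenvalues
    vectors: np.ndarray         # (nq, 3, 3) columns are eigenvectors
    dominant: np.ndarray        # (nq,) index of max-Re branch
    ambiguous: np.ndarray       # (nq,) flag: branch tracking was uncertain

    @property
    def dominant_lambda(self) -> np.ndarray:
        return self.branches[np.arange(len(self.q)), self.dominant]

    @property
    def is_complex_dominant(self) -> np.ndarray:
        return np.abs(self.dominant_lambda.imag) > 1e-10

    @property
    def max_growth(self) -> float:
        return float(self.dominant_lambda.real.max())


def dispersion(
    params: ModelParams,
    q_max: float = 12.0,
    nq: int = 241,
    coeffs: CoefficientSet = DEFAULT_COEFFS,
) -> DispersionResult:
    """Eigen-decomposition on a q-grid with continuous branch tracking.

    Branches are matched between adjacent wavenumbers by maximal
    eigenvector overlap (ties broken by eigenvalue proximity); points
    where the assignment is ambiguous (near-degenerate overlaps at
    exceptional points) are flagged, not fatal.
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    qs = np.linspace(0.0, q_max, nq)
    lams = np.empty((nq, 3), dtype=complex)
    vecs = np.empty((nq, 3, 3), dtype=complex)
    ambiguous = np.zeros(nq, dtype=bool)
    prev_v = None
    for i, q in enumerate(qs):
        w, v = np.linalg.eig(stability_matrix(q, params, coeffs))
        if prev_v is None:
            order = np.argsort(-w.real)
        else:
            overlap = np.abs(prev_v.conj().T @ v)  # (prev_branch, new_idx)
            order = np.full(3, -1)
            used = set()
            for k in range(3):
                cand = np.argsort(-overlap[k])
                cand = [c for c in cand if c not in used]
                if len(cand) > 1 and abs(
                    overlap[k, cand[0]] - overlap[k, cand[1]]
                ) < 1e-3:
                    # tie: break by eigenvalue proximity to previous branch
                    ambiguous[i] = True
                    d0 = abs(w[cand[0]] - lams[i - 1, k])
                    d1 = abs(w[cand[1]] - lams[i - 1, k])
                    best = cand[0] if d0 <= d1 else cand[1]
                else:
                    best = cand[0]
                order[k] = best
                used.add(best)
        lams[i] = w[order]
        vecs[i] = v[:, order]
        prev_v = vecs[i]
    dominant = np.argmax(lams.real, axis=1)
    return DispersionResult(qs, lams, vecs, dominant, ambiguous)


def growth_rate_max(
    params: ModelParams,
    q_max: float = 12.0,
    nq: int = 241,
    refine: bool = True,
    coeffs: CoefficientSet = DEFAULT_COEFFS,
) -> tuple[float, float]:
    """Supremum over continuous q of the dominant growth rate.

    Returns ``(max Re lambda, argmax q)``.  A coarse grid scan is refined
    by golden-section search around the grid maximum.  The trivial zero
    modes at ``q = 0`` are excluded (conserved densities are always
    marginal there).
    """
    disp = dispersion(params, q_max, nq, coeffs)
    rel = disp.dominant_lambda.real
    i = int(np.argmax(rel[1:])) + 1
    if not refine:
        return float(rel[i]), float(disp.q[i])
    lo = disp.q[max(i - 1, 1)]
    hi = disp.q[min(i + 1, len(disp.q) - 1)]

    def f(q):
        return -np.max(np.linalg.eigvals(stability_matrix(q, params, coeffs)).real)

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    if -res.fun > rel[i]:
        return float(-res.fun), float(res.x)
    return float(rel[i]), float(disp.q[i])


def most_unstable_mode(
    params: ModelParams,
    q_index: int | None = None,
    coeffs: CoefficientSet = DEFAULT_COEFFS,
) -> tuple[float, complex, np.ndarray]:
    """Most unstable admissible mode ``q = 2*pi*k/L`` on the finite domain.

    Returns ``(q, lambda, A)`` for the dominant branch, with the
    eigenvector chosen on the branch with ``Im(lambda) >= 0``
    (left-traveling for real instabilities this is the real mode itself).
    ``q_index`` forces the mode number ``k``.
    """
    dq = 2.0 * np.pi / params.L
    if q_index is not None:
        ks = [q_index]
    else:
        kmax = max(2, int(np.ceil(12.0 / dq)))
        ks = range(1, kmax + 1)
    best = None
    for k in ks:
        q = k * dq
        w, v = np.linalg.eig(stability_matrix(q, params, coeffs))
        i = int(np.argmax(w.real))
        # among the dominant (possibly conjugate-pair) eigenvalues pick Im >= 0
        close = np.where(np.abs(w.real - w[i].real) < 1e-12)[0]
        i = close[np.argmax(w[close].imag)]
        if best is None or w[i].real > best[1].real:
            vec = v[:, i] / v[:, i][np.argmax(np.abs(v[:, i]))]
            best = (q, w[i], vec)
    return best


def _unstable(params: ModelParams, q_max: float, coeffs: CoefficientSet) -> bool:
    g, _ = growth_rate_max(params, q_max=q_max, nq=121, refine=False, coeffs=coeffs)
    return g > 0


def spinodal(
    Pe: float,
    resolution: int = 72,
    q_max: float = 12.0,
    tol: float = 1e-8,
    coeffs: CoefficientSet = DEFAULT_COEFFS,
) -> np.ndarray:
    """Spinodal curve at fixed ``Pe``: ``(n, 2)`` array of ``(phi_a, phi_p)``.

    The curve is traced by bisection along rays from an interior point of
    the unstable region; the continuous-q supremum of the dominant growth
    rate defines (in)stability.  Returns an empty array when no unstable
    region exists (low Pe).
    """
    if Pe <= 0:
        raise ValueError("Pe must be positive")

    # coarse scan for the unstable region
    pts = []
    for pa in np.linspace(0.02, 0.98, 25):
        for pp in np.linspace(0.0, 0.98 - pa, 13):
            p = ModelParams(Pe=Pe, L=1.0, phi_a=pa, phi_p=pp)
            if _unstable(p, q_max, coeffs):
                pts.append((pa, pp))
    if not pts:
        return np.empty((0, 2))
    center = np.mean(np.array(pts), axis=0)

    def gmax(pa, pp):
        if pa < 0 or pp < 0 or pa + pp >= 1:
            return -1.0
        p = ModelParams(Pe=Pe, L=1.0, phi_a=pa, phi_p=pp)
        g, _ = growth_rate_max(p, q_max=q_max, nq=161, coeffs=coeffs)
        return g

    curve = []
    for th in np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False):
        d = np.array([np.cos(th), np.sin(th)])
        # bracket: step outward until stable (or boundary)
        r_lo, r_hi = 0.0, None
        r = 0.02
        while r < 1.6:
            pa, pp = center + r * d
            if pa < 0 or pp < 0 or pa + pp >= 1:
                break
            if gmax(pa, pp) > 0:
                r_lo = r
            else:
                r_hi = r
                break
            r += 0.04
        if r_hi is None:
            continue  # ray leaves the physical triangle while still unstable
        for _ in range(60):
            rm = 0.5 * (r_lo + r_hi)
            if gmax(*(center + rm * d)) > 0:
                r_lo = rm
            else:
                r_hi = rm
            if r_hi - r_lo < tol:
                break
        curve.append(center + 0.5 * (r_lo + r_hi) * d)
    return np.array(curve)


def bogdanov_takens_points(
    Pe: float,
    resolution: int = 72,
    q_max: float = 12.0,
    coeffs: CoefficientSet = DEFAULT_COEFFS,
) -> np.ndarray:
    """Codimension-two points on the spinodal where the dominant mode
    switches real <-> complex.  Returns ``(k, 2)`` array (possibly empty).
    """
    curve = spinodal(Pe, resolution=resolution, q_max=q_max, coeffs=coeffs)
    if len(curve) == 0:
        return np.empty((0, 2))

    def is_cx(pt):
        p = ModelParams(Pe=Pe, L=1.0, phi_a=pt[0], phi_p=pt[1])
        _, qstar = growth_rate_max(p, q_max=q_max, coeffs=coeffs)
        w = np.linalg.eigvals(stability_matrix(qstar, p, coeffs))
        i = int(np.argmax(w.real))
        return abs(w[i].imag) > 1e-9

    flags = [is_cx(pt) for pt in curve]
    out = []
    n = len(curve)
    for i in range(n):
        j = (i + 1) % n
        if flags[i] != flags[j]:
            a, b = curve[i].copy(), curve[j].copy()
            fa = flags[i]
            for _ in range(40):
                mid = 0.5 * (a + b)
                if is_cx(mid) == fa:
                    a = mid
                else:
                    b = mid
                if np.linalg.norm(b - a) < 1e-6:
                    break
            out.append(0.5 * (a + b))
    return np.array(out) if out else np.empty((0, 2))
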