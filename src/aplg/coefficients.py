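"""Transport coefficients of the exclusion-process hydrodynamics.

The hydrodynamic equations involve the self-diffusion coefficient
``d_s(rho)`` of a tagged particle in the symmetric simple exclusion
process, together with the derived cross-diffusion coefficients

    D(rho) = (1 - d_s(rho)) / rho,      s(rho) = D(rho) - 1.

``d_s`` has no closed form; the default here is the cubic Pade-type
approximation

    d_s(rho) = (1 - rho) * (1 - a*rho + a*(2a-1)/(2a+1) * rho**2),

with ``a = pi/2 - 1``, which matches the exact value and slope at
``rho = 0`` and ``rho = 1`` and is accurate to a fraction of a percent in
between.  The mean-field approximation would be ``d_s = 1 - rho``; the
correction term is what makes the lattice gas "non-gradient".

Because ``1 - d_s(rho)`` vanishes linearly at ``rho = 0``, the quotient
``D`` is itself a polynomial and needs no limiting procedure:

    D(rho) = (1 + a) - (a + b)*rho + b*rho**2,   b = a*(2a-1)/(2a+1).

All downstream constructions (linearization, effective free energy)
require smooth derivatives, so each coefficient carries its analytic
first derivative.  The coefficient set is pluggable: any positive,
decreasing ``d_s`` with a derivative can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

ALPHA = math.pi / 2.0 - 1.0
BETA = ALPHA * (2.0 * ALPHA - 1.0) / (2.0 * ALPHA + 1.0)

ArrayLike = float | np.ndarray


def _check_density(rho: ArrayLike) -> None:
    r = np.asarray(rho)
    if np.any(r < -1e-12) or np.any(r > 1.0 + 1e-12):
        raise ValueError("density outside [0, 1]")


def self_diffusion(rho: ArrayLike) -> ArrayLike:
    """Tagged-particle self-diffusion coefficient ``d_s(rho)``.

    Polynomial approximation matching the exact exclusion-process values
    at both endpoints: ``d_s(0) = 1`` and ``d_s(1) = 0``.
    """
    _check_density(rho)
    return (1.0 - rho) * (1.0 - ALPHA * rho + BETA * rho * rho)


def self_diffusion_deriv(rho: ArrayLike) -> ArrayLike:
    """Analytic derivative ``d_s'(rho)`` of the default approximation."""
    _check_density(rho)
    return -(1.0 - ALPHA * rho + BETA * rho * rho) + (1.0 - rho) * (
        -ALPHA + 2.0 * BETA * rho
    )


def cross_coefficients(rho: ArrayLike) -> tuple[ArrayLike, ArrayLike]:
    """Cross-diffusion pair ``(D, s)`` with ``D = (1 - d_s)/rho``, ``s = D - 1``.

    For the default ``d_s`` the quotient is evaluated in its exact
    polynomial form, so ``rho = 0`` returns the analytic limit
    ``D(0) = 1 + a = pi/2``.
    """
    _check_density(rho)
    D = (1.0 + ALPHA) - (ALPHA + BETA) * rho + BETA * rho * rho
    return D, D - 1.0


def cross_coefficients_deriv(rho: ArrayLike) -> ArrayLike:
    """Common derivative ``D'(rho) = s'(rho)`` of the polynomial pair."""
    _check_density(rho)
    return -(ALPHA + BETA) + 2.0 * BETA * rho


@dataclass(frozen=True)
class CoefficientSet:
    """Pluggable transport-coefficient bundle.

    ``d_s`` is the self-diffusion coefficient; ``D`` and ``s`` are always
    derived from it through ``D = (1 - d_s)/rho`` (with the analytic
    ``rho -> 0`` limit) so the identity ``rho*D + d_s = 1`` holds by
    construction for any plugged-in approximation.
    """

    d_s: Callable[[ArrayLike], ArrayLike] = field(default=self_diffusion)
    d_s_deriv: Callable[[ArrayLike], ArrayLike] = field(default=self_diffusion_deriv)
    _default: bool = True

    def D(self, rho: ArrayLike) -> ArrayLike:
        if self._default:
            return cross_coefficients(rho)[0]
        rho_arr = np.asarray(rho, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (1.0 - self.d_s(rho_arr)) / rho_arr
        # analytic limit from the series of d_s at 0: D(0) = -d_s'(0)
        limit = -self.d_s_deriv(0.0)
        if out.ndim == 0:
            return float(out) if rho_arr > 0 else float(limit)
        out[rho_arr == 0] = limit
        return out

    def s(self, rho: ArrayLike) -> ArrayLike:
        return self.D(rho) - 1.0

    def D_deriv(self, rho: ArrayLike) -> ArrayLike:
        if self._default:
            return cross_coefficients_deriv(rho)
        rho_arr = np.asarray(rho, dtype=float)
        eps = 1e-7
        lo = np.clip(rho_arr - eps, 0.0, 1.0)
        hi = np.clip(rho_arr + eps, 0.0, 1.0)
        return (self.D(hi) - self.D(lo)) / (hi - lo)


DEFAULT_COEFFS = CoefficientSet()
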