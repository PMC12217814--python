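"""Damped Newton iteration with a colored finite-difference sparse Jacobian.

The traveling-wave systems discretize to banded nonlinear systems (each
residual row couples a node to its nearest neighbours across all species
blocks) bordered by a handful of dense rows (mass/gauge constraints) and
one dense column (the wave speed).  The banded part of the Jacobian is
estimated by forward differences with structural coloring: columns of
the same species block separated by more than twice the bandwidth are
perturbed simultaneously, so a full Jacobian costs a handful of residual
evaluations.  Dense constraint rows are supplied analytically by the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve


def _cycle_coloring(N: int, bw: int, periodic: bool) -> list[np.ndarray]:
    """Greedy coloring of a (cyclic) path graph with conflicts within 2*bw."""
    colors = np.full(N, -1)
    ncol = 0
    for j in range(N):
        taken = set()
        for d in range(1, 2 * bw + 1):
            for nb in (j - d, j + d):
                if periodic:
                    nb %= N
                elif nb < 0 or nb >= N:
                    continue
                if colors[nb] >= 0:
                    taken.add(colors[nb])
        c = 0
        while c in taken:
            c += 1
        colors[j] = c
        ncol = max(ncol, c + 1)
    return [np.nonzero(colors == c)[0] for c in range(ncol)]


@dataclass
class BlockSystem:
    """Nonlinear system with banded block structure.

    ``residual(u)`` returns the banded rows; ``constraints(u)`` returns
    ``(values, dense_jacobian_rows)``.  The unknown vector is
    ``[block_0, ..., block_{k-1}, extra...]`` with each block of length
    ``N``; ``row_nodes[i]`` is the node index the i-th banded row is
    centered on.
    """

    residual: Callable[[np.ndarray], np.ndarray]
    constraints: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    n_blocks: int
    N: int
    n_extra: int
    row_nodes: np.ndarray
    bandwidth: int = 1
    periodic: bool = True
    _groups: list = field(default=None, repr=False)

    @property
    def n_unknowns(self) -> int:
        return self.n_blocks * self.N + self.n_extra

    def groups(self) -> list[np.ndarray]:
        if self._groups is None:
            self._groups = _cycle_coloring(self.N, self.bandwidth, self.periodic)
        return self._groups


def _fd_jacobian(system: BlockSystem, u: np.ndarray, f0: np.ndarray,
                 eps: float = 1e-7) -> sp.csr_matrix:
    N = system.N
    bw = system.bandwidth
    rows_l, cols_l, vals_l = [], [], []
    row_nodes = system.row_nodes
    for b in range(system.n_blocks):
        for grp in system.groups():
            member = np.zeros(N, dtype=bool)
            member[grp] = True
            du = np.zeros_like(u)
            du[b * N + grp] = eps
            df = (system.residual(u + du) - f0) / eps
            nz = df != 0.0
            for off in range(-bw, bw + 1):
                cand = row_nodes + off
                if system.periodic:
                    cand = cand % N
                else:
                    cand = np.clip(cand, 0, N - 1)
                hit = nz & member[cand] & (np.abs(row_nodes - cand) <= bw) if not system.periodic else nz & member[cand]
                rr = np.nonzero(hit)[0]
                if len(rr):
                    rows_l.append(rr)
                    cols_l.append(b * N + cand[rr])
                    vals_l.append(df[rr])
                    nz = nz & ~hit  # each row attributed once per group
    for k in range(system.n_extra):
        du = np.zeros_like(u)
        du[system.n_blocks * N + k] = eps
        df = (system.residual(u + du) - f0) / eps
        rr = np.nonzero(df)[0]
        rows_l.append(rr)
        cols_l.append(np.full(len(rr), system.n_blocks * N + k))
        vals_l.append(df[rr])
    rows = np.concatenate(rows_l) if rows_l else np.array([], dtype=int)
    cols = np.concatenate(cols_l) if cols_l else np.array([], dtype=int)
    vals = np.concatenate(vals_l) if vals_l else np.array([])
    return sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(f0), system.n_unknowns)
    ).tocsr()


def newton_solve(
    system: BlockSystem,
    u0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 60,
    verbose: bool = False,
) -> tuple[np.ndarray, float, bool]:
    """Damped Newton with halving line search.

    Returns ``(u, final_residual_norm, converged)``; the norm is the
    max-norm of the stacked residual and constraint values.
    """
    u = u0.copy()

    def full_res(uu):
        c_vals, _ = system.constraints(uu)
        return np.concatenate([system.residual(uu), c_vals])

    f = full_res(u)
    norm = np.linalg.norm(f, np.inf)
    for _it in range(max_iter):
        if norm < tol:
            return u, norm, True
        f_pde = system.residual(u)
        c_vals, c_jac = system.constraints(u)
        J_pde = _fd_jacobian(system, u, f_pde)
        J = sp.vstack([J_pde, sp.csr_matrix(c_jac)]).tocsc()
        rhs = -np.concatenate([f_pde, c_vals])
        if J.shape[0] != J.shape[1]:
            # overdetermined bordered system: normal equations
            JtJ = (J.T @ J).tocsc()
            try:
                du = spsolve(JtJ, J.T @ rhs)
            except Exception:
                return u, norm, False
        else:
            try:
                du = spsolve(J, rhs)
            except Exception:
                return u, norm, False
        if not np.all(np.isfinite(du)):
            return u, norm, False
        step = 1.0
        for _ in range(40):
            u_new = u + step * du
            f_new = full_res(u_new)
            n_new = np.linalg.norm(f_new, np.inf)
            if n_new < norm * (1.0 - 1e-4 * step) or n_new < tol:
                break
            step *= 0.5
        else:
            return u, norm, False
        u, norm = u_new, n_new
        if verbose:
            print(f"  newton it {_it}: |F| = {norm:.3e} (step {step})")
    return u, norm, norm < tol
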