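"""Exact continuous-time simulation of the active-passive lattice gas.

Particles of three species live on a periodic 2D square lattice with at
most one particle per site.  In rescaled units (tumble rate and
translational diffusivity both 1) the rates are

    passive:  jump to each of the 4 neighbours at rate 1/h^2;
    active :  horizontal jumps at rate 1/h^2 +- Pe/(2h) (along/against
              the orientation), vertical at 1/h^2; orientation flip at
              rate 1;
    exclusion: a jump into an occupied site is aborted.

The chain is sampled exactly with a rejection-style Gillespie scheme:
per-particle total rates are configuration-independent (blocked jumps
are kept as null events), so events are drawn in O(1): exponential
waiting time at the constant total rate, a uniformly chosen particle of
a rate-weighted species class, then a rate-weighted event that may
abort.  Species counts are conserved (flips exchange the two active
orientations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ModelParams

__all__ = ["LatticeState", "initialize_lattice", "site_rates", "gillespie_run",
           "mesoscopic_density"]

EMPTY = -1
RIGHT = 0   # sigma = +1
LEFT = 1    # sigma = -1
PASSIVE = 2


@dataclass
class LatticeState:
    """Occupancy grid plus particle bookkeeping.

    ``grid[i, j]`` holds a particle index or -1; ``species[k]`` in
    {RIGHT, LEFT, PASSIVE}; ``xs``, ``ys`` are particle coordinates.
    ``h`` is the lattice spacing in rescaled units.
    """

    grid: np.ndarray
    species: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    h: float
    time: float = 0.0

    @property
    def dims(self) -> tuple[int, int]:
        return self.grid.shape

    def counts(self) -> dict:
        return {
            "right": int((self.species == RIGHT).sum()),
            "left": int((self.species == LEFT).sum()),
            "passive": int((self.species == PASSIVE).sum()),
        }

    def occupancy(self) -> np.ndarray:
        """(nx, ny) int grid: -1 empty, else species code."""
        occ = np.full(self.grid.shape, EMPTY, dtype=np.int8)
        mask = self.grid >= 0
        occ[mask] = self.species[self.grid[mask]]
        return occ

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.species.copy(),
                            self.xs.copy(), self.ys.copy(), self.h, self.time)


def initialize_lattice(
    params: ModelParams,
    dims: tuple[int, int] | None = None,
    seed: int | None = None,
) -> LatticeState:
    """Independent per-site filling: right/left active with probability
    ``phi_a/2`` each, passive with ``phi_p``, else empty."""
    h = params.h if params.h is not None else 0.025
    if params.Pe > 0 and h > 2.0 / params.Pe:
        raise ValueError(
            f"lattice spacing h={h} too coarse: backward jump rate "
            f"1/h^2 - Pe/(2h) would be negative (need h <= 2/Pe)"
        )
    if dims is None:
        nx = int(round(params.L / h))
        ny = max(4, int(round(params.L * params.aspect / h)))
    else:
        nx, ny = dims
    rng = np.random.default_rng(seed)
    u = rng.random((nx, ny))
    occ = np.full((nx, ny), EMPTY, dtype=np.int8)
    occ[u < params.phi_a / 2.0] = RIGHT
    occ[(u >= params.phi_a / 2.0) & (u < params.phi_a)] = LEFT
    occ[(u >= params.phi_a) & (u < params.phi_a + params.phi_p)] = PASSIVE
    idx = np.argwhere(occ != EMPTY)
    n = len(idx)
    grid = np.full((nx, ny), -1, dtype=np.int64)
    grid[idx[:, 0], idx[:, 1]] = np.arange(n)
    return LatticeState(
        grid=grid,
        species=occ[idx[:, 0], idx[:, 1]].astype(np.int8),
        xs=idx[:, 0].astype(np.int64),
        ys=idx[:, 1].astype(np.int64),
        h=h,
        time=0.0,
    )


def site_rates(state: LatticeState, site: tuple[int, int],
               params: ModelParams) -> list[tuple[str, float]]:
    """Event list (event name, rate) for the particle at ``site``.

    Jump rates are listed regardless of target occupancy (blocked jumps
    are retained as aborted events with their full rate).
    """
    k = state.grid[site]
    if k < 0:
        raise ValueError(f"site {site} is empty")
    h = state.h
    base = 1.0 / h**2
    sp = state.species[k]
    events = []
    if sp == PASSIVE:
        for name in ("right", "left", "up", "down"):
            events.append((f"jump_{name}", base))
        return events
    sig = 1.0 if sp == RIGHT else -1.0
    drift = params.Pe / (2.0 * h)
    if base + sig * drift < 0 or base - sig * drift < 0:
        raise ValueError("negative jump rate: h too coarse for this Pe")
    events.append(("jump_right", base + sig * drift))
    events.append(("jump_left", base - sig * drift))
    events.append(("jump_up", base))
    events.append(("jump_down", base))
    events.append(("flip", 1.0))
    return events


@njit(cache=True)
def _run_kernel(grid, species, xs, ys, h, Pe, t, t_end, seed):  # pragma: no cover
    nx, ny = grid.shape
    n = len(species)
    np.random.seed(seed)
    base = 1.0 / (h * h)
    drift = Pe / (2.0 * h)
    n_act = 0
    for k in range(n):
        if species[k] != 2:
            n_act += 1
    # active particle list first, passives after (rates differ only by flip)
    act_rate = 4.0 * base + 1.0
    pas_rate = 4.0 * base
    act_idx = np.empty(n, dtype=np.int64)
    pas_idx = np.empty(n, dtype=np.int64)
    na = 0
    npas = 0
    for k in range(n):
        if species[k] != 2:
            act_idx[na] = k
            na += 1
        else:
            pas_idx[npas] = k
            npas += 1
    total = na * act_rate + npas * pas_rate
    if total <= 0.0:
        return t_end
    p_act = na * act_rate / total
    while t < t_end:
        t += -np.log(np.random.random()) / total
        if t >= t_end:
            break
        if np.random.random() < p_act:
            k = act_idx[np.int64(np.random.random() * na)]
            u = np.random.random() * act_rate
            sig = 1.0 if species[k] == 0 else -1.0
            if u < 1.0:
                species[k] = 1 - species[k]  # flip orientation
                continue
            u -= 1.0
            if u < base + sig * drift:
                dx_, dy_ = 1, 0
            elif u < 2.0 * base:
                dx_, dy_ = -1, 0
            elif u < 3.0 * base:
                dx_, dy_ = 0, 1
            else:
                dx_, dy_ = 0, -1
        else:
            k = pas_idx[np.int64(np.random.random() * npas)]
            u = np.random.random() * pas_rate
            if u < base:
                dx_, dy_ = 1, 0
            elif u < 2.0 * base:
                dx_, dy_ = -1, 0
            elif u < 3.0 * base:
                dx_, dy_ = 0, 1
            else:
                dx_, dy_ = 0, -1
        x0, y0 = xs[k], ys[k]
        x1 = (x0 + dx_) % nx
        y1 = (y0 + dy_) % ny
        if grid[x1, y1] >= 0:
            continue  # aborted jump (exclusion)
        grid[x0, y0] = -1
        grid[x1, y1] = k
        xs[k] = x1
        ys[k] = y1
    return t_end


def gillespie_run(
    state: LatticeState,
    t_end: float,
    params: ModelParams,
    seed: int = 0,
    observers=None,
    snap_dt: float | None = None,
) -> list:
    """Advance the chain exactly to ``t_end`` (in place).

    Returns the list of observer outputs collected every ``snap_dt``
    (plus the final time); each observer is called as ``obs(state)``.
    """
    if t_end <= state.time:
        raise ValueError("t_end must exceed current time")
    if params.Pe > 0 and state.h > 2.0 / params.Pe:
        raise ValueError("h too coarse: negative backward rate")
    times = (
        np.arange(state.time + snap_dt, t_end + 1e-12, snap_dt)
        if snap_dt
        else np.array([t_end])
    )
    if len(times) == 0 or times[-1] < t_end - 1e-12:
        times = np.append(times, t_end)
    rng = np.random.default_rng(seed)
    collected = []
    for i, tt in enumerate(times):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        state.time = _run_kernel(
            state.grid, state.species, state.xs, state.ys,
            state.h, params.Pe, state.time, float(tt), sub_seed,
        )
        if observers:
            collected.append([obs(state) for obs in observers])
    return collected


def mesoscopic_density(
    state: LatticeState,
    r: float = 0.1,
    kernel: str = "tophat",
) -> dict:
    """y-averaged mesoscopic densities per species as volume fractions.

    Counts particles within horizontal distance ``r`` of each column
    (top-hat window; a Gaussian window of standard deviation ``r`` is
    optional) and divides by the window's site count, giving local
    volume fractions in [0, 1].  Requires ``r >= h``.
    """
    h = state.h
    if r < h:
        raise ValueError(f"smoothing radius r={r} smaller than one site h={h}")
    nx, ny = state.dims
    occ = state.occupancy()
    cols = {
        "plus": (occ == RIGHT).sum(axis=1).astype(float),
        "minus": (occ == LEFT).sum(axis=1).astype(float),
        "zero": (occ == PASSIVE).sum(axis=1).astype(float),
    }
    if kernel == "tophat":
        w = int(np.floor(r / h))
        win = np.zeros(nx)
        for d in range(-w, w + 1):
            win[d % nx] += 1.0
    elif kernel == "gaussian":
        d = np.arange(nx)
        d = np.minimum(d, nx - d).astype(float) * h
        win = np.exp(-0.5 * (d / r) ** 2)
    else:
        raise ValueError("kernel must be 'tophat' or 'gaussian'")
    fw = np.fft.rfft(win)
    out = {}
    denom = win.sum() * ny
    for key, col in cols.items():
        smoothed = np.fft.irfft(np.fft.rfft(col) * fw, n=nx)
        out[key] = smoothed / denom
    out["x"] = (np.arange(nx) + 0.5) * h
    out["rho"] = out["plus"] + out["minus"] + out["zero"]
    return out
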