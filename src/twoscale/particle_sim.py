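"""Stochastic simulation of Brownian particles with two-scale crowding response.

Each of the N particles obeys the overdamped Langevin dynamics

    dr_i = sqrt(2 * D_i) dW_i,      D_i = D0 * g(a - b*rho_s_i + c*rho_l_i)

where ``rho_s_i`` and ``rho_l_i`` are the particle's local densities —
neighbour counts (including itself) over concentric disks of radius R_s
and R_l divided by the disk areas — and ``g`` is the sigmoid response
from :mod:`twoscale.model_core`.  The equation is interpreted in the Ito
sense: the stop-or-move decision uses the configuration at the beginning
of the step, so within an Euler--Maruyama step all densities are frozen
at the pre-step positions and every particle is displaced synchronously.

The domain is a periodic square of side L; distances use the
minimum-image convention.  Particle number is strictly conserved (the
model has no birth or death), and positions are re-wrapped into [0, L)
after every step.

Neighbour counting uses uniform cell lists (cell size >= R_l) compiled
with numba, giving O(N) cost per step at the scales studied here
(N ~ 1e4); a vectorized O(N^2) all-pairs routine is kept as an
independent oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_core import ModelParams

__all__ = [
    "ParticleState",
    "uniform_particles",
    "neighbor_counts",
    "neighbor_counts_bruteforce",
    "local_densities",
    "step",
    "run",
    "default_dt",
    "min_image_displacement",
]

log = logging.getLogger(__name__)


@dataclass
class ParticleState:
    """Positions (and diagnostics) of the particle population at one time.

    Attributes
    ----------
    positions : ndarray, shape (N, 2)
        Coordinates in [0, L)^2.
    L : float
        Periodic domain side.
    t : float
        Simulation time.
    seed : int or None
        Seed that initialized this trajectory's random stream (recorded
        in every output header).
    rng : numpy.random.Generator
        The trajectory's random stream; created from ``seed`` if absent.
    diffusivities : ndarray or None
        Per-particle D_i of the last executed step (diagnostic).
    """

    positions: np.ndarray
    L: float
    t: float = 0.0
    seed: int | None = None
    rng: np.random.Generator | None = field(default=None, repr=False, compare=False)
    diffusivities: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if np.any(self.positions < 0) or np.any(self.positions >= self.L):
            raise ValueError("positions must lie in [0, L)")
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleState":
        """Snapshot copy sharing no arrays (the rng stream is shared)."""
        d = None if self.diffusivities is None else self.diffusivities.copy()
        return ParticleState(
            self.positions.copy(), self.L, self.t, self.seed, rng=self.rng, diffusivities=d
        )


def uniform_particles(N: int, L: float, seed: int | None = None) -> ParticleState:
    """N particles placed uniformly at random in the periodic box."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, L, size=(N, 2))
    return ParticleState(pos, L, 0.0, seed=seed, rng=rng)


@njit(cache=False)
def _counts_brute_nb(pos, L, Rs, Rl):  # pragma: no cover - numba
    N = pos.shape[0]
    Ns = np.ones(N, np.int64)
    Nl = np.ones(N, np.int64)
    Rs2 = Rs * Rs
    Rl2 = Rl * Rl
    half = 0.5 * L
    for i in range(N):
        for j in range(i + 1, N):
            dx = pos[j, 0] - pos[i, 0]
            if dx > half:
                dx -= L
            elif dx < -half:
                dx += L
            dy = pos[j, 1] - pos[i, 1]
            if dy > half:
                dy -= L
            elif dy < -half:
                dy += L
            r2 = dx * dx + dy * dy
            if r2 <= Rl2:
                Nl[i] += 1
                Nl[j] += 1
                if r2 <= Rs2:
                    Ns[i] += 1
                    Ns[j] += 1
    return Ns, Nl


@njit(cache=False)
def _counts_cells_nb(pos, L, Rs, Rl):  # pragma: no cover - numba
    N = pos.shape[0]
    m = int(L / Rl)  # cells per side; cell size L/m >= Rl
    cs = L / m
    ncell = m * m

    cell = np.empty(N, np.int64)
    for i in range(N):
        cx = int(pos[i, 0] / cs)
        cy = int(pos[i, 1] / cs)
        if cx >= m:
            cx = m - 1
        if cy >= m:
            cy = m - 1
        cell[i] = cx * m + cy

    # counting sort into cell-contiguous order
    start = np.zeros(ncell + 1, np.int64)
    for i in range(N):
        start[cell[i] + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
    order = np.empty(N, np.int64)
    fill = start[:-1].copy()
    for i in range(N):
        order[fill[cell[i]]] = i
        fill[cell[i]] += 1

    Ns = np.ones(N, np.int64)
    Nl = np.ones(N, np.int64)
    Rs2 = Rs * Rs
    Rl2 = Rl * Rl
    half = 0.5 * L
    for i in range(N):
        xi = pos[i, 0]
        yi = pos[i, 1]
        cx = cell[i] // m
        cy = cell[i] % m
        for ox in range(-1, 2):
            ccx = cx + ox
            if ccx < 0:
                ccx += m
            elif ccx >= m:
                ccx -= m
            for oy in range(-1, 2):
                ccy = cy + oy
                if ccy < 0:
                    ccy += m
                elif ccy >= m:
                    ccy -= m
                cc = ccx * m + ccy
                for idx in range(start[cc], start[cc + 1]):
                    j = order[idx]
                    if j == i:
                        continue
                    dx = pos[j, 0] - xi
                    if dx > half:
                        dx -= L
                    elif dx < -half:
                        dx += L
                    dy = pos[j, 1] - yi
                    if dy > half:
                        dy -= L
                    elif dy < -half:
                        dy += L
                    r2 = dx * dx + dy * dy
                    if r2 <= Rl2:
                        Nl[i] += 1
                        if r2 <= Rs2:
                            Ns[i] += 1
    return Ns, Nl


def neighbor_counts(state: ParticleState, params: ModelParams):
    """Per-particle neighbour counts (N_s, N_l) within R_s and R_l.

    Counts include the focal particle itself (N_l >= N_s >= 1), matching
    the continuum limit where the smoothed density under the kernel
    includes the focal neighbourhood's own mass.  The long-range
    neighbourhood is the full disk of radius R_l, concentric with the
    short one.

    Uses cell lists when the box holds at least a 3x3 block of cells of
    size >= R_l; otherwise falls back to the all-pairs loop.
    """
    pos = state.positions
    if int(state.L / params.R_l) >= 3:
        return _counts_cells_nb(pos, state.L, params.R_s, params.R_l)
    return _counts_brute_nb(pos, state.L, params.R_s, params.R_l)


def neighbor_counts_bruteforce(state: ParticleState, params: ModelParams):
    """Vectorized O(N^2) all-pairs oracle for the neighbour counts."""
    pos = state.positions
    delta = pos[:, None, :] - pos[None, :, :]
    delta -= state.L * np.round(delta / state.L)
    r2 = (delta**2).sum(axis=2)
    Ns = (r2 <= params.R_s**2).sum(axis=1)
    Nl = (r2 <= params.R_l**2).sum(axis=1)
    return Ns.astype(np.int64), Nl.astype(np.int64)


def local_densities(state: ParticleState, params: ModelParams):
    """Per-particle mean densities (rho_s, rho_l) = N_mu / (pi R_mu^2)."""
    Ns, Nl = neighbor_counts(state, params)
    return Ns / (math.pi * params.R_s**2), Nl / (math.pi * params.R_l**2)


def default_dt(params: ModelParams) -> float:
    """Default step: rms free displacement sqrt(2 D0 dt) = R_s / 4."""
    return (params.R_s / 4.0) ** 2 / (2.0 * params.D0)


def max_dt(params: ModelParams) -> float:
    """Resolution guard: sqrt(2 D0 dt) must not exceed R_s / 2."""
    return (params.R_s / 2.0) ** 2 / (2.0 * params.D0)


def step(state: ParticleState, params: ModelParams, dt: float) -> ParticleState:
    """One synchronous Euler--Maruyama step (Ito convention).

    Diffusivities are evaluated at the pre-step configuration for every
    particle, then all particles move by ``sqrt(2 D_i dt) * xi`` with
    ``xi`` a standard Gaussian pair, and positions re-wrap periodically.

    Raises
    ------
    ValueError
        If ``dt`` exceeds the displacement-resolution guard
        ``sqrt(2 D0 dt) <= R_s / 2`` (steps longer than half the short
        interaction radius would jump over the neighbourhood structure).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if math.sqrt(2.0 * params.D0 * dt) > params.R_s / 2.0 * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} too large: rms free displacement sqrt(2 D0 dt)="
            f"{math.sqrt(2 * params.D0 * dt):.4g} exceeds R_s/2={params.R_s / 2:.4g}"
        )
    rho_s, rho_l = local_densities(state, params)
    D = params.D0 * np.asarray(params.g(params.a - params.b * rho_s + params.c * rho_l))
    xi = state.rng.standard_normal(size=(state.N, 2))
    pos = state.positions + np.sqrt(2.0 * D * dt)[:, None] * xi
    pos %= state.L
    return ParticleState(
        pos, state.L, state.t + dt, seed=state.seed, rng=state.rng, diffusivities=D
    )


def run(
    initial: ParticleState,
    params: ModelParams,
    t_end: float,
    dt: float | None = None,
    snapshot_every: float | None = None,
) -> list[ParticleState]:
    """Integrate the particle dynamics to ``t_end``, collecting snapshots.

    The trajectory is reproducible: the random stream is re-created from
    ``initial.seed``, so running twice from the same initial state gives
    identical positions.

    Parameters
    ----------
    initial : ParticleState
        Not modified.
    params : ModelParams
    t_end : float
        Final time relative to ``initial.t``; 0 returns only the initial
        snapshot.
    dt : float, optional
        Defaults to :func:`default_dt` (rms free step = R_s / 4).
    snapshot_every : float, optional
        Time between stored snapshots; the initial and final states are
        always included.

    Returns
    -------
    list of ParticleState
    """
    if dt is None:
        dt = default_dt(params)
    state = ParticleState(
        initial.positions.copy(),
        initial.L,
        initial.t,
        seed=initial.seed,
        rng=np.random.default_rng(initial.seed),
    )
    n_steps = int(np.ceil(t_end / dt - 1e-12)) if t_end > 0 else 0
    stride = max(1, int(round(snapshot_every / dt))) if snapshot_every is not None else n_steps + 1

    snaps = [state.copy()]
    for i in range(1, n_steps + 1):
        h = min(dt, initial.t + t_end - state.t)
        state = step(state, params, h)
        if i % stride == 0 and i != n_steps:
            snaps.append(state.copy())
        if i % max(1, n_steps // 10) == 0:
            log.debug("particle run: t=%.4g / %.4g", state.t, initial.t + t_end)
    if n_steps > 0:
        snaps.append(state.copy())
    return snaps


def min_image_displacement(a: ParticleState, b: ParticleState) -> np.ndarray:
    """Per-particle displacement b - a under the minimum-image convention.

    Valid as a true displacement only while particles move less than L/2
    between the two snapshots.
    """
    d = b.positions - a.positions
    d -= a.L * np.round(d / a.L)
    return d
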