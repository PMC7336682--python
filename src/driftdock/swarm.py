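"""Particle population state and per-iteration update rules.

Two update rules are provided on a shared :class:`SwarmState`:

* :func:`pso_step` — inertia-weight PSO (the LPSO baseline),
  ``V <- w*V + c1*r*(P-X) + c2*R*(G-X)``;
* :func:`rdpso_step` — random drift PSO, where each particle's velocity is the
  superposition of a thermal component ``alpha*|C-X|*phi`` (``phi ~ N(0,1)``,
  ``C`` the mean of all personal bests) and a drift component ``beta*(p-X)``
  toward the particle's local attractor ``p`` (a random convex combination of
  its personal best and the global best).

Velocities are clamped componentwise to ``±Vmax`` (half the per-dimension
range) and positions are repaired into the space after every move.  All random
draws come from a single ``numpy.random.Generator`` in a fixed particle-major,
dimension-minor order, so runs are reproducible from one seed.

Objectives are *batched*: a callable mapping an ``(M, N)`` position array to
``(M,)`` fitness values (minimization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .space import SearchSpace

__all__ = [
    "SwarmState",
    "clamp_velocity",
    "local_focus",
    "pso_step",
    "rdpso_step",
    "linear_schedule",
    "init_swarm",
]

Objective = Callable[[np.ndarray], np.ndarray]


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping of M particles.

    ``G``/``f_G`` track the running global best (never worsens); ``C`` is the
    mean-best position, the componentwise mean of all personal bests,
    refreshed after every pbest update.
    """

    X: np.ndarray          # (M, N) positions
    V: np.ndarray          # (M, N) velocities
    P: np.ndarray          # (M, N) personal best positions
    f_X: np.ndarray        # (M,) fitness of X
    f_P: np.ndarray        # (M,) fitness of P
    G: np.ndarray          # (N,) global best position
    f_G: float
    C: np.ndarray = field(default=None)  # (N,) mean best position
    n: int = 0             # iteration index
    evals: int = 0         # objective evaluations consumed

    def __post_init__(self) -> None:
        if self.C is None:
            self.C = self.P.mean(axis=0)

    @property
    def n_particles(self) -> int:
        return self.X.shape[0]

    def best_index(self) -> int:
        """Index of the particle with the lowest current fitness (ties: lowest index)."""
        return int(np.argmin(self.f_X))

    def update_bests(self) -> None:
        """Refresh pbest/gbest/mbest from current positions.

        Ties keep the incumbent pbest; the global best is a running minimum
        and never moves to an equal-or-worse point.
        """
        improved = self.f_X < self.f_P
        self.P[improved] = self.X[improved]
        self.f_P[improved] = self.f_X[improved]
        i = int(np.argmin(self.f_P))
        if self.f_P[i] < self.f_G:
            self.f_G = float(self.f_P[i])
            self.G = self.P[i].copy()
        self.C = self.P.mean(axis=0)


def init_swarm(
    objective: Objective, space: SearchSpace, m: int, rng: np.random.Generator
) -> SwarmState:
    """Uniform random positions within the bounds, zero velocities."""
    if m < 1:
        raise ValueError("swarm size must be at least 1")
    X = space.sample(rng, size=m)
    f_X = np.asarray(objective(X), dtype=float)
    if f_X.shape != (m,):
        raise ValueError("objective must return one fitness per particle")
    i = int(np.argmin(f_X))
    state = SwarmState(
        X=X,
        V=np.zeros_like(X),
        P=X.copy(),
        f_X=f_X,
        f_P=f_X.copy(),
        G=X[i].copy(),
        f_G=float(f_X[i]),
        evals=m,
    )
    return state


def clamp_velocity(v: np.ndarray, vmax: np.ndarray) -> np.ndarray:
    """Limit each velocity component to ``[-vmax[j], vmax[j]]``."""
    return np.clip(v, -vmax, vmax)


def local_focus(P: np.ndarray, G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-dimension random convex combination ``gamma*P + (1-gamma)*G``.

    ``P`` may be a single pbest vector or an ``(M, N)`` stack; a fresh
    ``gamma ~ U(0,1)`` is drawn for every entry.
    """
    gamma = rng.uniform(size=np.shape(P))
    return gamma * P + (1.0 - gamma) * G


def pso_step(
    state: SwarmState,
    objective: Objective,
    space: SearchSpace,
    w: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
) -> SwarmState:
    """One inertia-weight PSO iteration (in place)."""
    if c1 <= 0 or c2 <= 0:
        raise ValueError("acceleration coefficients must be positive")
    r = rng.uniform(size=state.X.shape)
    R = rng.uniform(size=state.X.shape)
    v = (
        w * state.V
        + c1 * r * (state.P - state.X)
        + c2 * R * (state.G - state.X)
    )
    state.V = clamp_velocity(v, space.vmax())
    state.X = space.repair(state.X + state.V)
    state.f_X = np.asarray(objective(state.X), dtype=float)
    state.evals += state.n_particles
    state.n += 1
    state.update_bests()
    return state


def rdpso_step(
    state: SwarmState,
    objective: Objective,
    space: SearchSpace,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
) -> SwarmState:
    """One random-drift PSO iteration (in place).

    Thermal component ``alpha*|C - X|*phi`` with ``phi ~ N(0,1)`` plus drift
    ``beta*(p - X)`` toward the local attractor ``p``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    p = local_focus(state.P, state.G, rng)
    phi = rng.standard_normal(size=state.X.shape)
    v = alpha * np.abs(state.C - state.X) * phi + beta * (p - state.X)
    state.V = clamp_velocity(v, space.vmax())
    state.X = space.repair(state.X + state.V)
    state.f_X = np.asarray(objective(state.X), dtype=float)
    state.evals += state.n_particles
    state.n += 1
    state.update_bests()
    return state


def linear_schedule(start: float, end: float, n: int, n_max: int) -> float:
    """Linear ramp from ``start`` at iteration 1 to ``end`` at ``n_max``."""
    if not 1 <= n <= n_max:
        raise ValueError(f"iteration {n} outside [1, {n_max}]")
    if n_max == 1:
        return start
    return start + (end - start) * (n - 1) / (n_max - 1)
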