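"""Two-phase diversity control (2PDC) for the random drift swarm.

Swarm diversity is the normalized average distance of the particles from their
centroid,

    D(X_n) = 1/(M*A) * sum_i ||X_i - mean(X)||,

with ``A`` the diagonal length of the search box.  The controller keeps
``D`` between a linearly decaying floor ``DL_n`` (from ``0.75*D(X_1)`` down to
``0.002*D(X_1)``) and a fixed ceiling ``DU = 0.95*D(X_1)``:

* CONVERGE — the swarm runs with the canonical schedule (``alpha`` ramping
  0.9→0.3, ``beta = 1.45``).  If diversity falls below the floor the
  controller flips to DIVERGE.
* DIVERGE — ``alpha`` and ``beta`` are inflated by the reciprocal of the
  diversity ratio ``Dr = D(X_n)/D(X_1)`` (``alpha = alpha0/Dr^c1``,
  ``beta = beta0/Dr^c2``), pushing particles away from their attractors until
  diversity recovers to the ceiling, whereupon the controller flips back.
* Acceleration — if a convergence phase fails to descend to the floor for
  more than ``accr * n_max`` iterations, every personal best is pulled to its
  local attractor, contracting the swarm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .space import SearchSpace
from .swarm import SwarmState, local_focus

__all__ = [
    "Phase",
    "PdcParams",
    "PdcState",
    "diversity",
    "lower_bound",
    "divergence_coeffs",
    "pdc_update",
    "accelerate_swarm",
    "jitter_degenerate",
]

#: floor on the diversity ratio when the swarm has fully collapsed (Dr = 0
#: makes the reciprocal coefficients divide by zero)
DR_EPS = 1e-6


class Phase(enum.Enum):
    CONVERGE = "converge"
    DIVERGE = "diverge"


@dataclass(frozen=True)
class PdcParams:
    """Tuning constants of the two-phase diversity controller."""

    dl1_factor: float = 0.75      # floor at iteration 1, as a fraction of D(X1)
    dlnmax_factor: float = 0.002  # floor at the final iteration
    du_factor: float = 0.95       # recovery ceiling, as a fraction of D(X1)
    alpha0: float = 9.0           # divergence thermal coefficient at Dr = 1
    beta0: float = 3.0            # divergence drift coefficient at Dr = 1
    c1: float = 1.0               # amplitude exponent for alpha
    c2: float = 0.7               # amplitude exponent for beta
    accr: float = 0.003           # acceleration clock threshold, fraction of n_max

    def __post_init__(self) -> None:
        if not 0 < self.dlnmax_factor < self.dl1_factor < self.du_factor <= 1:
            raise ValueError(
                "need 0 < dlnmax_factor < dl1_factor < du_factor <= 1"
            )
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("alpha0 and beta0 must be positive")
        if self.accr < 0.003:
            raise ValueError("accr must be at least 0.003")


@dataclass
class PdcState:
    """Mutable controller state threaded through a run."""

    D1: float                     # baseline diversity D(X_1)
    phase: Phase = Phase.CONVERGE
    conv_clock: int = 0           # iterations in this convergence phase spent above the floor
    accel_on: bool = False

    def __post_init__(self) -> None:
        if self.D1 <= 0:
            raise ValueError("baseline diversity D1 must be positive")


def diversity(positions: np.ndarray, A: float) -> float:
    """Normalized mean distance of the swarm from its centroid."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] == 0:
        raise ValueError("positions must be a non-empty (M, N) array")
    if A <= 0:
        raise ValueError("diagonal length A must be positive")
    centroid = positions.mean(axis=0)
    dist = np.linalg.norm(positions - centroid, axis=1)
    return float(dist.sum() / (positions.shape[0] * A))


def lower_bound(n: int, n_max: int, D1: float, params: PdcParams = PdcParams()) -> float:
    """Linearly decaying diversity floor DL_n.

    ``DL_n = (1 - n/n_max)*(DL_1 - DL_nmax) + DL_nmax`` with
    ``DL_1 = dl1_factor*D1`` and ``DL_nmax = dlnmax_factor*D1``.
    """
    if not 1 <= n <= n_max:
        raise ValueError(f"iteration {n} outside [1, {n_max}]")
    if D1 <= 0:
        raise ValueError("D1 must be positive")
    dl1 = params.dl1_factor * D1
    dln = params.dlnmax_factor * D1
    return (1.0 - n / n_max) * (dl1 - dln) + dln


def divergence_coeffs(
    Dn: float, D1: float, params: PdcParams = PdcParams()
) -> tuple[float, float]:
    """Inflated (alpha, beta) for the divergence phase.

    ``alpha = alpha0 / Dr^c1`` and ``beta = beta0 / Dr^c2`` with
    ``Dr = Dn/D1``; a fully collapsed swarm (``Dr = 0``) is capped at
    ``Dr = DR_EPS`` to keep the coefficients finite.
    """
    if D1 <= 0:
        raise ValueError("D1 must be positive")
    if Dn < 0:
        raise ValueError("diversity cannot be negative")
    dr = max(Dn / D1, DR_EPS)
    return params.alpha0 / dr**params.c1, params.beta0 / dr**params.c2


def pdc_update(
    state: PdcState,
    Dn: float,
    n: int,
    n_max: int,
    params: PdcParams = PdcParams(),
) -> tuple[Phase, tuple[float, float] | None, bool]:
    """Advance the phase machine for iteration ``n`` given diversity ``Dn``.

    Returns ``(phase, coeffs, accelerate)``: ``coeffs`` is the inflated
    ``(alpha, beta)`` pair during DIVERGE and ``None`` during CONVERGE (the
    caller then uses the canonical schedule); ``accelerate`` flags that the
    convergence phase has idled above the floor for more than
    ``accr * n_max`` iterations and the swarm should be contracted.
    """
    dl = lower_bound(n, n_max, state.D1, params)
    du = params.du_factor * state.D1

    if state.phase is Phase.CONVERGE and Dn < dl:
        state.phase = Phase.DIVERGE
    elif state.phase is Phase.DIVERGE and Dn >= du:
        state.phase = Phase.CONVERGE
        state.conv_clock = 0

    accelerate = False
    if state.phase is Phase.DIVERGE:
        state.accel_on = False
        return state.phase, divergence_coeffs(Dn, state.D1, params), False

    if Dn >= dl:
        state.conv_clock += 1
        accelerate = state.conv_clock > params.accr * n_max
    state.accel_on = accelerate
    return state.phase, None, accelerate


def accelerate_swarm(
    state: SwarmState,
    objective: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
) -> SwarmState:
    """Contract the swarm: every pbest moves to its local attractor.

    Each personal best is replaced by ``gamma*P + (1-gamma)*G`` and re-scored
    with one objective evaluation per particle; the stored global best
    position/fitness is kept as a running minimum.
    """
    state.P = local_focus(state.P, state.G, rng)
    state.f_P = np.asarray(objective(state.P), dtype=float)
    state.evals += state.n_particles
    i = int(np.argmin(state.f_P))
    if state.f_P[i] < state.f_G:
        state.f_G = float(state.f_P[i])
        state.G = state.P[i].copy()
    state.C = state.P.mean(axis=0)
    return state


def jitter_degenerate(
    state: SwarmState, space: SearchSpace, rng: np.random.Generator
) -> SwarmState:
    """Tiny uniform position jitter for a fully collapsed swarm.

    With all particles identical the thermal term ``|C - X|`` is zero and a
    divergence step cannot move anything; a perturbation of ``1e-6`` of each
    dimension's range restores a nonzero spread.
    """
    scale = 1e-6 * space.range
    state.X = space.repair(state.X + rng.uniform(-scale, scale, size=state.X.shape))
    return state
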