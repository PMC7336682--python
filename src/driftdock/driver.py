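"""Run orchestration for DGLRDPSO and its LRDPSO / LPSO baselines.

A run initializes the swarm uniformly at random within the bounds, then, per
iteration: measures swarm diversity; (DGLRDPSO only) lets the two-phase
diversity controller pick the phase and coefficients; performs one swarm
update (RDPSO, or inertia-weight PSO for LPSO); optionally contracts the
swarm (acceleration); and finally applies Solis–Wets local search to the best
particle of the iteration with Lamarckian write-back — the refined position
replaces the particle's current position, its personal best if better, and
the global best if better still.

The evaluation budget counts every objective call: swarm sweeps, acceleration
re-scores, and local-search trials.  The iteration horizon ``n_max`` used by
the linear schedules (coefficient annealing and the diversity floor) is
``ceil(eval_budget / (M + 100))`` when local search is enabled: the 100 is a
nominal per-iteration local-search consumption, so that the schedules finish
roughly when the budget runs out instead of stalling at their early values.
A run always terminates on budget exhaustion; if it outlasts ``n_max`` the
schedules simply hold their final values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .diversity import (
    PdcParams,
    PdcState,
    Phase,
    accelerate_swarm,
    diversity,
    jitter_degenerate,
    pdc_update,
)
from .solis_wets import SolisWetsParams, solis_wets
from .space import SearchSpace
from .swarm import init_swarm, linear_schedule, pso_step, rdpso_step

__all__ = ["ALGORITHMS", "RunConfig", "RunRecord", "run", "SW_NOMINAL_EVALS"]

ALGORITHMS = ("DGLRDPSO", "LRDPSO", "LPSO")

#: nominal objective evaluations consumed by one local-search call, used only
#: to size the iteration horizon of the linear schedules
SW_NOMINAL_EVALS = 100


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one optimization run.

    The production defaults follow the study protocol (swarm of 150,
    2.5e6-evaluation budget); tests and the shipped examples use far smaller
    budgets via explicit overrides.
    """

    algorithm: str = "DGLRDPSO"
    m: int = 150
    eval_budget: int = 2_500_000
    seed: int = 0
    pdc: PdcParams = field(default_factory=PdcParams)
    sw: SolisWetsParams = field(default_factory=SolisWetsParams)
    alpha_schedule: tuple[float, float] = (0.9, 0.3)
    beta: float = 1.45
    lpso_w: tuple[float, float] = (0.9, 0.4)
    lpso_c: tuple[float, float] = (2.05, 2.05)
    local_search: bool = True
    pdc_enabled: bool | None = None  # None: controller active iff algorithm is DGLRDPSO

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose one of {ALGORITHMS}"
            )
        if self.m < 1:
            raise ValueError("swarm size must be at least 1")
        if self.eval_budget < self.m:
            raise ValueError("eval_budget must allow at least one full sweep")

    @property
    def n_max(self) -> int:
        """Iteration horizon for the linear schedules."""
        per_iter = self.m + (SW_NOMINAL_EVALS if self.local_search else 0)
        return math.ceil(self.eval_budget / per_iter)


@dataclass
class RunRecord:
    """Per-iteration trace and final outcome of a run."""

    trace: list[dict]
    best_x: np.ndarray
    best_f: float
    evals_total: int
    iterations: int
    seed: int
    algorithm: str

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)

    def write_trace(self, path) -> None:
        self.trace_frame().to_csv(path, sep="\t", index=False)


def run(
    objective: Callable[[np.ndarray], np.ndarray],
    space: SearchSpace,
    config: RunConfig,
) -> RunRecord:
    """Execute one full optimization run; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    state = init_swarm(objective, space, config.m, rng)
    n_max = config.n_max
    A = space.diagonal

    use_pdc = (
        config.pdc_enabled
        if config.pdc_enabled is not None
        else config.algorithm == "DGLRDPSO"
    )
    pdc_state: PdcState | None = None
    trace: list[dict] = []

    n = 0
    while state.evals < config.eval_budget:
        n += 1
        n_sched = min(n, n_max)  # schedules hold their final value past the horizon
        d_n = diversity(state.X, A)

        phase = Phase.CONVERGE
        accelerate = False
        if use_pdc:
            if pdc_state is None:
                # the first measured diversity is the baseline D(X_1); a fully
                # degenerate init (D = 0) cannot happen under uniform sampling
                pdc_state = PdcState(D1=d_n)
            phase, coeffs, accelerate = pdc_update(
                pdc_state, d_n, n_sched, n_max, config.pdc
            )
        else:
            coeffs = None

        if coeffs is not None:
            alpha, beta = coeffs
            if d_n == 0.0:
                jitter_degenerate(state, space, rng)
        else:
            alpha = linear_schedule(*config.alpha_schedule, n=n_sched, n_max=n_max)
            beta = config.beta

        if config.algorithm == "LPSO":
            w = linear_schedule(*config.lpso_w, n=n_sched, n_max=n_max)
            pso_step(state, objective, space, w, *config.lpso_c, rng)
        else:
            rdpso_step(state, objective, space, alpha, beta, rng)

        if accelerate:
            accelerate_swarm(state, objective, rng)

        if config.local_search:
            i = state.best_index()
            res = solis_wets(
                state.X[i], objective, space, config.sw, rng, f0=state.f_X[i]
            )
            state.evals += res.nfev
            if res.fun < state.f_X[i]:
                state.X[i] = res.x
                state.f_X[i] = res.fun
                if res.fun < state.f_P[i]:
                    state.P[i] = res.x.copy()
                    state.f_P[i] = res.fun
                    state.C = state.P.mean(axis=0)
                    if res.fun < state.f_G:
                        state.G = res.x.copy()
                        state.f_G = res.fun

        trace.append(
            {
                "n": n,
                "f_G": state.f_G,
                "diversity": d_n,
                "phase": phase.value,
                "alpha": alpha,
                "beta": beta,
                "accelerate": accelerate,
                "evals": state.evals,
            }
        )

    return RunRecord(
        trace=trace,
        best_x=state.G.copy(),
        best_f=state.f_G,
        evals_total=state.evals,
        iterations=n,
        seed=config.seed,
        algorithm=config.algorithm,
    )
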