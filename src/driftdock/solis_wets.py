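"""Solis–Wets stochastic local search with Lamarckian write-back.

The classical variant: at each iteration a Gaussian deviate ``delta`` with
componentwise mean ``bias`` and standard deviation ``rho`` is tried on both
sides of the current point.  A success updates the bias toward the accepted
direction (``0.2*bias + 0.4*delta`` forward, ``bias - 0.4*delta`` backward); a
failure halves the bias.  Four consecutive successes double ``rho``, four
consecutive failures halve it; the search stops when ``rho`` drops below 0.01
(native genotype units) or after 300 iterations.  Trial points are repaired
into the search space before scoring, and only improvements are ever accepted,
so the returned fitness never exceeds the input fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .space import SearchSpace

__all__ = ["SolisWetsParams", "SolisWetsResult", "solis_wets"]


@dataclass(frozen=True)
class SolisWetsParams:
    """Step-size adaptation constants (rho in native units: Å / radians)."""

    max_iter: int = 300
    consec_limit: int = 4
    rho0: float = 1.0
    rho_min: float = 0.01
    expansion: float = 2.0
    contraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.rho_min < self.rho0:
            raise ValueError("rho_min must be smaller than rho0")
        if self.expansion <= 1 or not 0 < self.contraction < 1:
            raise ValueError("need expansion > 1 and 0 < contraction < 1")
        if self.consec_limit < 1 or self.max_iter < 1:
            raise ValueError("consec_limit and max_iter must be at least 1")


@dataclass
class SolisWetsResult:
    x: np.ndarray
    fun: float
    nfev: int                          # objective evaluations consumed
    n_iter: int
    rho_trace: list[float] = field(default_factory=list)  # rho at each iteration start


def solis_wets(
    x0: np.ndarray,
    objective: Callable[[np.ndarray], np.ndarray],
    space: SearchSpace,
    params: SolisWetsParams,
    rng: np.random.Generator,
    f0: float | None = None,
) -> SolisWetsResult:
    """Local minimization from ``x0``; ``objective`` is batched ``(B,N)->(B,)``.

    Pass ``f0`` when the fitness of ``x0`` is already known to avoid spending
    one evaluation on the start point.
    """
    x = space.repair(np.asarray(x0, dtype=float))
    nfev = 0
    if f0 is None:
        f_x = float(objective(x[None, :])[0])
        nfev += 1
    else:
        f_x = float(f0)

    bias = np.zeros_like(x)
    rho = params.rho0
    successes = failures = 0
    rho_trace: list[float] = []

    n_iter = 0
    while rho >= params.rho_min and n_iter < params.max_iter:
        rho_trace.append(rho)
        n_iter += 1
        delta = rng.normal(loc=bias, scale=rho)
        x_fwd = space.repair(x + delta)
        f_fwd = float(objective(x_fwd[None, :])[0])
        nfev += 1
        if f_fwd < f_x:
            x, f_x = x_fwd, f_fwd
            bias = 0.2 * bias + 0.4 * delta
            successes += 1
            failures = 0
        else:
            x_bwd = space.repair(x - delta)
            f_bwd = float(objective(x_bwd[None, :])[0])
            nfev += 1
            if f_bwd < f_x:
                x, f_x = x_bwd, f_bwd
                bias = bias - 0.4 * delta
                successes += 1
                failures = 0
            else:
                bias = 0.5 * bias
                failures += 1
                successes = 0
        if successes >= params.consec_limit:
            rho *= params.expansion
            successes = 0
        elif failures >= params.consec_limit:
            rho *= params.contraction
            failures = 0

    return SolisWetsResult(x=x, fun=f_x, nfev=nfev, n_iter=n_iter, rho_trace=rho_trace)
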