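"""Docking evaluation indexes: RMSD, Dref, and per-case multi-run summaries.

Conventions follow standard re-docking reports: a run is *successful* when
the final pose lies within 2.0 Å RMSD of the reference pose (no
superposition, identity atom mapping); ``Dref`` is the plain difference
between an algorithm's indicator value and the per-case reference (best)
algorithm's value, so the reference algorithm scores 0; the rank of the
lowest-binding-score successful conformation among all R conformations is
recorded as ``R + 1`` when no run succeeded (31 for the standard 30-repeat
protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RunOutcome", "CaseResult", "CaseSummary", "rmsd", "dref", "summarize_case"]

SUCCESS_THRESHOLD = 2.0  # Å


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared deviation over matched atom pairs (Å).

    No superposition and no symmetry correction: coordinates are compared
    pairwise in the given order.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3) with equal N")
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def dref(value_test: float, value_ref: float) -> float:
    """Difference between a tested and a reference indicator value."""
    if not (np.isfinite(value_test) and np.isfinite(value_ref)):
        raise ValueError("both values must be finite")
    return float(value_test - value_ref)


@dataclass(frozen=True)
class RunOutcome:
    """Final conformation of one docking run."""

    docked_energy: float
    binding_score: float
    rmsd: float

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd cannot be negative")


@dataclass(frozen=True)
class CaseResult:
    """R repeated runs of one algorithm on one case."""

    runs: tuple[RunOutcome, ...]
    success_threshold: float = SUCCESS_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.runs) < 1:
            raise ValueError("at least one run is required")


@dataclass(frozen=True)
class CaseSummary:
    """Per-case statistics in the standard report columns.

    ``ns`` — number of successful runs; ``me`` — mean binding score;
    ``le`` — lowest binding score among successful runs (None if ``ns`` is 0);
    ``rank`` — position of the LE conformation when all R conformations are
    sorted ascending by binding score (ties broken by run index), ``R + 1``
    when no run succeeded.
    """

    n_runs: int
    ns: int
    mean_docked_energy: float
    best_docked_energy: float
    me: float
    le: float | None
    rank: int


def summarize_case(res: CaseResult) -> CaseSummary:
    runs = res.runs
    r = len(runs)
    rmsds = np.array([o.rmsd for o in runs])
    docked = np.array([o.docked_energy for o in runs])
    binding = np.array([o.binding_score for o in runs])
    success = rmsds <= res.success_threshold
    ns = int(success.sum())

    # ascending binding score, ties by run index (lexsort: last key primary)
    order = np.lexsort((np.arange(r), binding))
    if ns == 0:
        le = None
        rank = r + 1
    else:
        le_idx = min(
            (i for i in range(r) if success[i]), key=lambda i: (binding[i], i)
        )
        le = float(binding[le_idx])
        rank = int(np.where(order == le_idx)[0][0]) + 1

    return CaseSummary(
        n_runs=r,
        ns=ns,
        mean_docked_energy=float(docked.mean()),
        best_docked_energy=float(docked.min()),
        me=float(binding.mean()),
        le=le,
        rank=rank,
    )
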