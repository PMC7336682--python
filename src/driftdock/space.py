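"""Optimization domains: box-bounded real vectors and the docking genotype.

A flexible-ligand pose is encoded as a flat real vector of length ``7 + Ntor``:
three Cartesian translation components (Å), four quaternion components
(unitless, scipy ``(x, y, z, w)`` order), and one dihedral angle per rotatable
bond (radians, periodic on ``[-pi, pi)``).  Swarm updates treat every dimension
as an ordinary bounded real; :func:`repair` restores the representation
invariants (wrap, clip, unit quaternion) after each move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SearchSpace", "DockingGenotype", "make_docking_space"]

#: identity rotation in (x, y, z, w) component order
IDENTITY_QUAT = np.array([0.0, 0.0, 0.0, 1.0])


@dataclass(frozen=True)
class SearchSpace:
    """Per-dimension box bounds with optional periodic (angular) dimensions.

    Parameters
    ----------
    lower, upper
        Per-dimension bounds; ``lower[j] < upper[j]`` for every ``j``.
    periodic
        Per-dimension flag; periodic dimensions must span exactly ``2*pi``
        and are wrapped (not clipped) by :meth:`repair`.
    quat_slice
        Optional slice marking four contiguous dimensions that hold a unit
        quaternion; ``repair`` renormalizes that block.  ``None`` for generic
        spaces.
    """

    lower: np.ndarray
    upper: np.ndarray
    periodic: np.ndarray
    quat_slice: slice | None = field(default=None)

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        periodic = np.asarray(self.periodic, dtype=bool)
        if lower.shape != upper.shape or lower.shape != periodic.shape:
            raise ValueError("lower, upper and periodic must have equal length")
        if lower.ndim != 1 or lower.size == 0:
            raise ValueError("bounds must be non-empty 1-D arrays")
        if not np.all(lower < upper):
            raise ValueError("every dimension needs lower < upper")
        if periodic.any():
            span = upper[periodic] - lower[periodic]
            if not np.allclose(span, 2.0 * np.pi):
                raise ValueError("periodic dimensions must span exactly 2*pi")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "periodic", periodic)

    @property
    def n_dim(self) -> int:
        return self.lower.size

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def diagonal(self) -> float:
        """Diagonal length A of the search box, sqrt(sum of squared ranges)."""
        return float(np.sqrt(np.sum(self.range**2)))

    def vmax(self) -> np.ndarray:
        """Per-dimension velocity cap, half the admissible range."""
        return self.range / 2.0

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        """Uniform random point(s) in the box, repaired."""
        shape = (self.n_dim,) if size is None else (size, self.n_dim)
        return self.repair(rng.uniform(self.lower, self.upper, size=shape))

    def repair(self, x: np.ndarray) -> np.ndarray:
        """Map arbitrary vectors back into the feasible representation.

        Periodic dimensions are wrapped into their range, all others are
        clipped to the box, and the quaternion block (if any) is renormalized
        to unit length; an all-zero quaternion resets to the identity.
        Accepts a single vector or a ``(batch, N)`` array.  Idempotent.
        """
        x = np.array(x, dtype=float, copy=True)
        if x.shape[-1] != self.n_dim:
            raise ValueError(
                f"vector length {x.shape[-1]} does not match space dimension {self.n_dim}"
            )
        per = self.periodic
        if per.any():
            lo, rng_ = self.lower[per], self.range[per]
            x[..., per] = (x[..., per] - lo) % rng_ + lo
        x[..., ~per] = np.clip(x[..., ~per], self.lower[~per], self.upper[~per])
        if self.quat_slice is not None:
            q = x[..., self.quat_slice]
            norm = np.linalg.norm(q, axis=-1, keepdims=True)
            zero = (norm == 0.0)[..., 0]
            if np.any(zero):
                q[zero] = IDENTITY_QUAT
                norm = np.linalg.norm(q, axis=-1, keepdims=True)
            # skip division on already-unit blocks so repair is an exact fixed point
            off = (np.abs(norm - 1.0) > 1e-12)[..., 0]
            if np.any(off):
                q[off] = q[off] / norm[off]
            x[..., self.quat_slice] = q
        return x


@dataclass(frozen=True)
class DockingGenotype:
    """Structured view of a docking decision vector.

    ``translation`` in Å, ``orientation`` a unit quaternion ``(x, y, z, w)``,
    ``torsions`` in radians wrapped to ``[-pi, pi)``.
    """

    translation: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float)
        q = np.asarray(self.orientation, dtype=float)
        tor = np.atleast_1d(np.asarray(self.torsions, dtype=float))
        if t.shape != (3,):
            raise ValueError("translation must have 3 components")
        if q.shape != (4,):
            raise ValueError("orientation must have 4 components")
        norm = np.linalg.norm(q)
        q = IDENTITY_QUAT.copy() if norm == 0.0 else q / norm
        tor = (tor + np.pi) % (2.0 * np.pi) - np.pi
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "orientation", q)
        object.__setattr__(self, "torsions", tor)

    @property
    def n_torsions(self) -> int:
        return self.torsions.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.orientation, self.torsions])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "DockingGenotype":
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.size < 7:
            raise ValueError("genotype vector must be 1-D with at least 7 entries")
        return cls(x[:3], x[3:7], x[7:])


def make_docking_space(
    box_center: np.ndarray, box_edge: float, n_torsions: int
) -> SearchSpace:
    """Search space for a ligand in a cubic box (default study box: 22.5 Å edge).

    Translation bounds are ``center ± edge/2`` per axis, quaternion components
    range over ``[-1, 1]``, and each torsion is periodic on ``[-pi, pi)``.
    """
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    if n_torsions < 0:
        raise ValueError("n_torsions must be non-negative")
    center = np.asarray(box_center, dtype=float)
    if center.shape != (3,):
        raise ValueError("box_center must have 3 components")
    half = box_edge / 2.0
    lower = np.concatenate(
        [center - half, -np.ones(4), np.full(n_torsions, -np.pi)]
    )
    upper = np.concatenate(
        [center + half, np.ones(4), np.full(n_torsions, np.pi)]
    )
    periodic = np.concatenate(
        [np.zeros(7, dtype=bool), np.ones(n_torsions, dtype=bool)]
    )
    return SearchSpace(lower, upper, periodic, quat_slice=slice(3, 7))
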