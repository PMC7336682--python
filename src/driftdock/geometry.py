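"""Vectorized rigid-body rotation primitives.

Hand-written (rather than routed through ``scipy.spatial.transform``) because
the docking objective evaluates millions of batch-of-one poses inside the
local search, where per-call wrapper overhead dominates.  Conventions match
scipy: quaternions are ``(x, y, z, w)`` and need not be pre-normalized.
"""

from __future__ import annotations

import numpy as np

__all__ = ["quat_to_matrix", "axis_angle_matrices"]


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices for a ``(..., 4)`` array of ``(x, y, z, w)`` quaternions."""
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q, axis=-1, keepdims=True)
    x, y, z, w = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    out = np.empty(q.shape[:-1] + (3, 3))
    out[..., 0, 0] = 1 - 2 * (y * y + z * z)
    out[..., 0, 1] = 2 * (x * y - z * w)
    out[..., 0, 2] = 2 * (x * z + y * w)
    out[..., 1, 0] = 2 * (x * y + z * w)
    out[..., 1, 1] = 1 - 2 * (x * x + z * z)
    out[..., 1, 2] = 2 * (y * z - x * w)
    out[..., 2, 0] = 2 * (x * z - y * w)
    out[..., 2, 1] = 2 * (y * z + x * w)
    out[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return out


def axis_angle_matrices(axis: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices about one fixed unit ``axis`` for ``(B,)`` angles."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    c = np.cos(angles)[:, None, None]
    s = np.sin(angles)[:, None, None]
    K = np.array(
        [
            [0.0, -u[2], u[1]],
            [u[2], 0.0, -u[0]],
            [-u[1], u[0], 0.0],
        ]
    )
    outer = np.outer(u, u)
    return c * np.eye(3) + s * K + (1.0 - c[:, 0, 0])[:, None, None] * outer
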