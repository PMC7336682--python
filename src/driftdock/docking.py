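"""Simplified flexible-ligand docking objective.

The receptor is a rigid atom cloud turned into precomputed grid maps (one
van der Waals affinity map per ligand atom type plus one electrostatic
potential map) sampled by trilinear interpolation, as in classical grid-based
docking codes.  The ligand is a torsion-tree model: a rigid root fragment with
nested rotatable branches.  The optimized *docked energy* is

    E_total = E_inter + E_internal

where ``E_inter`` sums, per ligand atom, the type-matched affinity map value
plus charge times the electrostatic map value, and ``E_internal`` sums
Lennard-Jones 12-6 and distance-dependent-dielectric Coulomb terms over
ligand atom pairs at least three bonds apart.  The *binding score* used for
ranking final poses is ``E_inter + w_tor * n_torsions``.

This is a surrogate energy model: a small closed atom-type alphabet with
tabulated well parameters, dielectric ``eps(r) = 4r``, no directional
hydrogen-bond or desolvation terms.  It supplies a realistic search landscape
for the optimizer, not chemical accuracy.
"""

from __future__ import annotations

import io
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .geometry import axis_angle_matrices, quat_to_matrix
from .space import DockingGenotype

__all__ = [
    "TYPE_PARAMS",
    "OUT_OF_GRID_PENALTY",
    "CLASH_CEILING",
    "Branch",
    "LigandModel",
    "GridMaps",
    "Pose",
    "apply_pose",
    "trilinear",
    "build_maps",
    "score_pose",
    "DockingObjective",
    "parse_pdbqt",
    "write_pdbqt",
    "parse_receptor_pdbqt",
    "write_receptor_pdbqt",
    "write_maps",
    "read_maps",
    "PdbqtError",
]

#: per-type Lennard-Jones parameters (well depth eps in energy units,
#: equilibrium pair distance r_eq in Å); combined by eps=sqrt(ei*ej),
#: r_eq=(ri+rj)/2 (Lorentz-Berthelot).  "X" is the generic fallback type.
TYPE_PARAMS: dict[str, tuple[float, float]] = {
    "C": (0.15, 4.00),
    "N": (0.16, 3.50),
    "O": (0.20, 3.20),
    "H": (0.02, 2.00),
    "X": (0.15, 3.50),
}

OUT_OF_GRID_PENALTY = 1.0e5   # per atom outside the grid box
CLASH_CEILING = 1.0e5         # cap on affinity map node values and internal pair terms
ELEC_CEILING = 1.0e3          # cap on electrostatic map magnitude; kept well below
                              # CLASH_CEILING so capped attraction can never cancel
                              # a capped clash at the same node
BOND_INFER_CUTOFF = 1.9       # Å, distance-based bond inference for parsed files
W_TOR_DEFAULT = 0.3           # binding-score torsional penalty per rotatable bond


class PdbqtError(ValueError):
    """Malformed ligand/receptor structure text."""


# ---------------------------------------------------------------------------
# ligand model and kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Branch:
    """One rotatable bond: axis ``parent_atom -> child_atom`` (0-based indices),
    ``moved`` = every atom distal to the axis (child included), ``parent_branch``
    = index of the enclosing branch in DFS order, −1 if attached to the root."""

    parent_atom: int
    child_atom: int
    moved: tuple[int, ...]
    parent_branch: int = -1


@dataclass(frozen=True)
class LigandModel:
    names: tuple[str, ...]
    types: tuple[str, ...]
    charges: np.ndarray
    ref_coords: np.ndarray            # (n_atoms, 3) Å
    bonds: tuple[tuple[int, int], ...]
    root: tuple[int, ...]             # atom indices of the rigid root fragment
    branches: tuple[Branch, ...]      # DFS order (outer before nested)

    def __post_init__(self) -> None:
        charges = np.asarray(self.charges, dtype=float)
        coords = np.asarray(self.ref_coords, dtype=float)
        n = len(self.names)
        if len(self.types) != n or charges.shape != (n,) or coords.shape != (n, 3):
            raise ValueError("inconsistent atom table")
        covered = set(self.root)
        for br in self.branches:
            covered.update(br.moved)
        if covered != set(range(n)):
            raise ValueError("root and branch moved-sets must cover all atoms")
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "ref_coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_torsions(self) -> int:
        return len(self.branches)

    def bond_separation(self) -> np.ndarray:
        """All-pairs bond-graph distances (BFS; ligands are small)."""
        n = self.n_atoms
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        sep = np.full((n, n), np.inf)
        for s in range(n):
            sep[s, s] = 0
            q = deque([s])
            while q:
                u = q.popleft()
                for v in adj[u]:
                    if sep[s, v] == np.inf:
                        sep[s, v] = sep[s, u] + 1
                        q.append(v)
        return sep

    def internal_pairs(self) -> np.ndarray:
        """Index pairs (i < j) separated by >= 3 bonds (1-4 and beyond)."""
        sep = self.bond_separation()
        ii, jj = np.triu_indices(self.n_atoms, k=1)
        keep = sep[ii, jj] >= 3
        return np.stack([ii[keep], jj[keep]], axis=1)

    def root_anchor(self) -> np.ndarray:
        """Centroid of the root fragment at reference coordinates; the rigid
        rotation pivot."""
        return self.ref_coords[list(self.root)].mean(axis=0)


def apply_pose_batch(ligand: LigandModel, X: np.ndarray) -> np.ndarray:
    """Atom coordinates for a ``(B, 7 + n_torsions)`` batch of genotype vectors.

    Torsions are applied innermost-branch-first about each branch axis at
    reference geometry, then the whole ligand is rotated by the quaternion
    about the root-fragment centroid, then translated.  The translation genes
    are a displacement of the ligand frame: the all-zero genotype (identity
    quaternion) reproduces the reference coordinates exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    expected = 7 + ligand.n_torsions
    if X.shape[1] != expected:
        raise ValueError(f"genotype length {X.shape[1]}, expected {expected}")
    B = X.shape[0]
    coords = np.broadcast_to(ligand.ref_coords, (B,) + ligand.ref_coords.shape).copy()

    # innermost first: nested moved-sets are subsets, and a branch's axis atoms
    # are never inside a deeper branch, so axes stay at reference until applied
    for k in range(ligand.n_torsions - 1, -1, -1):
        br = ligand.branches[k]
        a = ligand.ref_coords[br.parent_atom]
        b = ligand.ref_coords[br.child_atom]
        R = axis_angle_matrices(b - a, X[:, 7 + k])
        idx = list(br.moved)
        coords[:, idx] = np.einsum("bij,bkj->bki", R, coords[:, idx] - a) + a

    anchor = ligand.root_anchor()
    Rq = quat_to_matrix(X[:, 3:7])
    coords = np.einsum("bij,bkj->bki", Rq, coords - anchor) + anchor
    coords += X[:, None, 0:3]
    return coords


def apply_pose(ligand: LigandModel, genotype: DockingGenotype) -> np.ndarray:
    """Atom coordinates (n_atoms, 3) for one structured genotype."""
    return apply_pose_batch(ligand, genotype.to_vector()[None, :])[0]


# ---------------------------------------------------------------------------
# grid maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridMaps:
    """Precomputed receptor fields on a shared lattice.

    ``npts`` counts grid *intervals* per axis (the lattice has ``npts + 1``
    points per axis), matching the convention of the host docking software,
    so the default 60 × 60 × 60 at 0.375 Å spans a 22.5 Å cube.
    """

    origin: np.ndarray                  # lattice corner, Å
    spacing: float
    npts: tuple[int, int, int]
    affinity: dict[str, np.ndarray]     # per ligand atom type, (nx, ny, nz) points
    electrostatic: np.ndarray

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        shape = tuple(n + 1 for n in self.npts)
        for name, grid in self.affinity.items():
            if grid.shape != shape:
                raise ValueError(f"affinity map {name!r} has shape {grid.shape}, expected {shape}")
        if self.electrostatic.shape != shape:
            raise ValueError("electrostatic map shape mismatch")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def interpolate(self, type_label: str, points: np.ndarray) -> np.ndarray:
        return trilinear(self.affinity[type_label], self.origin, self.spacing, points)


def trilinear(
    grid: np.ndarray,
    origin: np.ndarray,
    spacing: float,
    points: np.ndarray,
    out_of_grid: float = OUT_OF_GRID_PENALTY,
) -> np.ndarray:
    """Trilinear interpolation of ``grid`` at Cartesian ``points``.

    Points outside the lattice return ``out_of_grid`` instead of raising, so
    the value is always finite during scoring.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = (pts - origin) / spacing
    nx, ny, nz = grid.shape
    hi = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
    inside = np.all((u >= 0.0) & (u <= hi), axis=1)

    uc = np.clip(u, 0.0, hi - 1e-12)
    i0 = np.minimum(uc.astype(int), np.array([nx - 2, ny - 2, nz - 2]))
    f = uc - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]

    c000 = grid[ix, iy, iz]
    c100 = grid[ix + 1, iy, iz]
    c010 = grid[ix, iy + 1, iz]
    c110 = grid[ix + 1, iy + 1, iz]
    c001 = grid[ix, iy, iz + 1]
    c101 = grid[ix + 1, iy, iz + 1]
    c011 = grid[ix, iy + 1, iz + 1]
    c111 = grid[ix + 1, iy + 1, iz + 1]

    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    values = c0 * (1 - fz) + c1 * fz
    return np.where(inside, values, out_of_grid)


def _combined_lj(type_a: str, type_b: str) -> tuple[float, float]:
    ea, ra = TYPE_PARAMS.get(type_a, TYPE_PARAMS["X"])
    eb, rb = TYPE_PARAMS.get(type_b, TYPE_PARAMS["X"])
    return float(np.sqrt(ea * eb)), (ra + rb) / 2.0


def build_maps(
    receptor_atoms: list[tuple[str, float, np.ndarray]],
    center: np.ndarray,
    spacing: float = 0.375,
    npts: int | tuple[int, int, int] = 60,
    ligand_types: tuple[str, ...] = tuple(TYPE_PARAMS),
    ceiling: float = CLASH_CEILING,
) -> GridMaps:
    """Precompute affinity and electrostatic maps on a lattice around ``center``.

    Each affinity node stores the summed 12-6 term over receptor atoms for
    that ligand type; the electrostatic node stores the summed receptor
    potential ``q / (4 r^2)`` (dielectric ``eps(r) = 4r``), so a ligand atom's
    electrostatic energy is its charge times the interpolated value.  Node
    values are capped at ``±ceiling`` so clashes stay finite.
    """
    if not receptor_atoms:
        raise ValueError("at least one receptor atom is required")
    if isinstance(npts, int):
        npts = (npts, npts, npts)
    center = np.asarray(center, dtype=float)
    origin = center - np.array(npts) * spacing / 2.0
    axes = [origin[d] + spacing * np.arange(npts[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    shape = tuple(n + 1 for n in npts)

    rec_xyz = np.array([np.asarray(a[2], dtype=float) for a in receptor_atoms])
    rec_types = [a[0] for a in receptor_atoms]
    rec_q = np.array([a[1] for a in receptor_atoms], dtype=float)

    affinity = {t: np.zeros(len(nodes)) for t in ligand_types}
    elec = np.zeros(len(nodes))
    chunk = 20000  # bound peak memory on the 227k-node default lattice
    for s in range(0, len(nodes), chunk):
        d2 = np.sum(
            (nodes[s : s + chunk, None, :] - rec_xyz[None, :, :]) ** 2, axis=-1
        )
        d2 = np.maximum(d2, 1e-12)
        elec[s : s + chunk] = np.sum(rec_q / (4.0 * d2), axis=1)
        inv_r6 = d2**-3
        for t in ligand_types:
            eps = np.empty(len(rec_types))
            req6 = np.empty(len(rec_types))
            for k, rt in enumerate(rec_types):
                e, r = _combined_lj(t, rt)
                eps[k] = e
                req6[k] = r**6
            a6 = req6 * inv_r6
            affinity[t][s : s + chunk] = np.sum(eps * (a6**2 - 2.0 * a6), axis=1)

    affinity = {
        t: np.clip(v, -ceiling, ceiling).reshape(shape) for t, v in affinity.items()
    }
    elec = np.clip(elec, -ELEC_CEILING, ELEC_CEILING).reshape(shape)
    return GridMaps(origin, spacing, npts, affinity, elec)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pose:
    genotype: DockingGenotype
    coordinates: np.ndarray
    docked_energy: float
    binding_score: float


class DockingObjective:
    """Batched docked-energy function over genotype vectors.

    Callable on a ``(B, 7 + n_torsions)`` array, returning ``(B,)`` docked
    energies; precomputes per-atom map lookups and internal-pair parameters
    once so per-call cost stays low inside the local search.
    """

    def __init__(
        self,
        ligand: LigandModel,
        maps: GridMaps,
        w_tor: float = W_TOR_DEFAULT,
        penalty: float = OUT_OF_GRID_PENALTY,
    ) -> None:
        self.ligand = ligand
        self.maps = maps
        self.w_tor = w_tor
        self.penalty = penalty
        types = sorted(set(ligand.types))
        for t in types:
            if t not in maps.affinity:
                raise ValueError(f"maps lack an affinity grid for atom type {t!r}")
        self._type_stack = np.stack(
            [maps.affinity[t] for t in types] + [maps.electrostatic]
        )
        self._atom_map = np.array([types.index(t) for t in ligand.types])
        self._charges = ligand.charges
        pairs = ligand.internal_pairs()
        self._pairs = pairs
        eps = np.empty(len(pairs))
        req = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            eps[k], req[k] = _combined_lj(ligand.types[i], ligand.types[j])
        self._pair_eps = eps
        self._pair_req6 = req**6
        self._pair_qq = (
            self._charges[pairs[:, 0]] * self._charges[pairs[:, 1]]
            if len(pairs)
            else np.zeros(0)
        )
        # flattened kinematics tables for the compiled kernel
        self._anchor = ligand.root_anchor()
        self._branch_axis = np.array(
            [(br.parent_atom, br.child_atom) for br in ligand.branches], dtype=np.int64
        ).reshape(ligand.n_torsions, 2)
        moved_lists = [list(br.moved) for br in ligand.branches]
        self._moved_flat = np.array(
            [i for lst in moved_lists for i in lst] or [0], dtype=np.int64
        )
        self._moved_ptr = np.cumsum([0] + [len(lst) for lst in moved_lists]).astype(np.int64)
        self._pairs_arr = pairs.astype(np.int64).reshape(len(pairs), 2)

    def intermolecular(self, coords: np.ndarray) -> np.ndarray:
        """Grid part of the energy for ``(B, n_atoms, 3)`` coordinates."""
        B, nat, _ = coords.shape
        flat = coords.reshape(-1, 3)
        m = self.maps
        u = (flat - m.origin) / m.spacing
        shape = self._type_stack.shape[1:]
        hi = np.array(shape, dtype=float) - 1.0
        inside = np.all((u >= 0.0) & (u <= hi), axis=1)
        uc = np.clip(u, 0.0, hi - 1e-12)
        i0 = np.minimum(uc.astype(int), np.array(shape) - 2)
        f = uc - i0
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]

        tmap = np.tile(self._atom_map, B)         # affinity grid per point
        emap = np.full(len(flat), self._type_stack.shape[0] - 1)
        stack = self._type_stack
        aff = _interp_stack(stack, tmap, ix, iy, iz, fx, fy, fz)
        ele = _interp_stack(stack, emap, ix, iy, iz, fx, fy, fz)
        q = np.tile(self._charges, B)
        per_atom = np.where(inside, aff + q * ele, self.penalty)
        return per_atom.reshape(B, nat).sum(axis=1)

    def internal(self, coords: np.ndarray) -> np.ndarray:
        """Ligand internal energy for ``(B, n_atoms, 3)`` coordinates."""
        if len(self._pairs) == 0:
            return np.zeros(coords.shape[0])
        d = coords[:, self._pairs[:, 0]] - coords[:, self._pairs[:, 1]]
        r2 = np.maximum(np.sum(d * d, axis=-1), 1e-12)
        a6 = self._pair_req6 * r2**-3
        lj = self._pair_eps * (a6**2 - 2.0 * a6)
        coul = self._pair_qq / (4.0 * r2)
        return np.sum(np.minimum(lj + coul, CLASH_CEILING), axis=1)

    def energies(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Docked-energy components via the compiled kernel."""
        from ._kernels import score_kernel

        X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
        if X.shape[1] != 7 + self.ligand.n_torsions:
            raise ValueError(
                f"genotype length {X.shape[1]}, expected {7 + self.ligand.n_torsions}"
            )
        return score_kernel(
            X,
            self.ligand.ref_coords,
            self._anchor,
            self._branch_axis,
            self._moved_flat,
            self._moved_ptr,
            self._type_stack,
            self._atom_map,
            self._charges,
            self.maps.origin,
            self.maps.spacing,
            self.penalty,
            self._pairs_arr,
            self._pair_eps,
            self._pair_req6,
            self._pair_qq,
            CLASH_CEILING,
        )

    def energies_reference(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pure-numpy route (kinematics + map interpolation); the kernel is
        cross-checked against this in the tests."""
        coords = apply_pose_batch(self.ligand, np.atleast_2d(X))
        return self.intermolecular(coords), self.internal(coords)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        e_inter, e_internal = self.energies(np.atleast_2d(X))
        return e_inter + e_internal

    def score(self, genotype: DockingGenotype) -> Pose:
        x = genotype.to_vector()[None, :]
        e_inter, e_internal = self.energies(x)
        coords = apply_pose_batch(self.ligand, x)[0]
        return Pose(
            genotype=genotype,
            coordinates=coords,
            docked_energy=float(e_inter[0] + e_internal[0]),
            binding_score=float(e_inter[0] + self.w_tor * self.ligand.n_torsions),
        )


def _interp_stack(stack, gsel, ix, iy, iz, fx, fy, fz):
    c00 = stack[gsel, ix, iy, iz] * (1 - fx) + stack[gsel, ix + 1, iy, iz] * fx
    c10 = stack[gsel, ix, iy + 1, iz] * (1 - fx) + stack[gsel, ix + 1, iy + 1, iz] * fx
    c01 = stack[gsel, ix, iy, iz + 1] * (1 - fx) + stack[gsel, ix + 1, iy, iz + 1] * fx
    c11 = (
        stack[gsel, ix, iy + 1, iz + 1] * (1 - fx)
        + stack[gsel, ix + 1, iy + 1, iz + 1] * fx
    )
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


def score_pose(
    ligand: LigandModel,
    maps: GridMaps,
    genotype: DockingGenotype,
    w_tor: float = W_TOR_DEFAULT,
) -> Pose:
    """Score one structured genotype (convenience over :class:`DockingObjective`)."""
    return DockingObjective(ligand, maps, w_tor=w_tor).score(genotype)


# ---------------------------------------------------------------------------
# PDBQT-subset I/O
# ---------------------------------------------------------------------------


def _format_atom(serial: int, name: str, xyz: np.ndarray, charge: float, t: str) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s} LIG A   1    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"    {charge:6.3f} {t:<2s}"
    )


def _parse_atom_line(line: str, lineno: int) -> tuple[int, str, np.ndarray, float, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        charge = float(line[66:76])
        t = line[77:79].strip() or "X"
    except (ValueError, IndexError) as exc:
        raise PdbqtError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    return serial, name, xyz, charge, t


def write_pdbqt(
    ligand: LigandModel, genotype: DockingGenotype | None = None
) -> str:
    """Serialize a ligand (optionally at a posed conformation) to PDBQT text.

    Bonds are recorded as ``REMARK BOND i j`` lines (serial numbers) so that
    :func:`parse_pdbqt` round-trips the model exactly; downstream PDBQT
    readers ignore REMARK records.
    """
    coords = ligand.ref_coords if genotype is None else apply_pose(ligand, genotype)
    out = io.StringIO()
    for i, j in ligand.bonds:
        out.write(f"REMARK BOND {i + 1:4d} {j + 1:4d}\n")

    children: dict[int, list[int]] = {-1: []}
    for k, br in enumerate(ligand.branches):
        children.setdefault(br.parent_branch, []).append(k)
        children.setdefault(k, [])
    own: dict[int, set[int]] = {}
    for k, br in enumerate(ligand.branches):
        nested: set[int] = set()
        for c in children[k]:
            nested.update(ligand.branches[c].moved)
        own[k] = set(br.moved) - nested

    def atom_line(i: int) -> str:
        return _format_atom(i + 1, ligand.names[i], coords[i], ligand.charges[i], ligand.types[i])

    out.write("ROOT\n")
    for i in sorted(ligand.root):
        out.write(atom_line(i) + "\n")
    out.write("ENDROOT\n")

    def emit(k: int) -> None:
        br = ligand.branches[k]
        out.write(f"BRANCH {br.parent_atom + 1:4d} {br.child_atom + 1:4d}\n")
        for i in sorted(own[k]):
            out.write(atom_line(i) + "\n")
        for c in children[k]:
            emit(c)
        out.write(f"ENDBRANCH {br.parent_atom + 1:4d} {br.child_atom + 1:4d}\n")

    for k in children[-1]:
        emit(k)
    out.write(f"TORSDOF {ligand.n_torsions}\n")
    return out.getvalue()


def parse_pdbqt(text: str) -> LigandModel:
    """Parse the PDBQT subset (ROOT/BRANCH/TORSDOF + ATOM/HETATM records).

    Bonds come from ``REMARK BOND`` lines when present; otherwise they are
    inferred from branch axes plus interatomic distances below 1.9 Å at the
    recorded coordinates.
    """
    serials: list[int] = []
    names: list[str] = []
    types: list[str] = []
    charges: list[float] = []
    coords: list[np.ndarray] = []
    remark_bonds: list[tuple[int, int]] = []

    root_atoms: list[int] = []
    in_root = False
    seen_root = False
    # open branches: (parent_serial, child_serial, moved_atom_indices, parent_branch)
    open_stack: list[list] = []
    done_branches: list[tuple[int, int, list[int], int]] = []
    branch_order: list[int] = []  # DFS open order -> index into done list at close
    torsdof: int | None = None

    def atom_index(serial: int, lineno: int) -> int:
        try:
            return serials.index(serial)
        except ValueError:
            raise PdbqtError(f"unknown atom serial {serial} at line {lineno}") from None

    dfs_open: list[dict] = []   # records in open order with moved lists
    all_branches: list[dict] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        rec = line[:6].strip().upper()
        if not line.strip():
            continue
        if rec == "REMARK":
            parts = line.split()
            if len(parts) == 4 and parts[1] == "BOND":
                remark_bonds.append((int(parts[2]) - 1, int(parts[3]) - 1))
            continue
        if rec == "ROOT":
            in_root = True
            seen_root = True
            continue
        if rec == "ENDROO":
            in_root = False
            continue
        if rec == "BRANCH":
            parts = line.split()
            if len(parts) != 3:
                raise PdbqtError(f"malformed BRANCH record at line {lineno}")
            entry = {
                "parent_serial": int(parts[1]),
                "child_serial": int(parts[2]),
                "moved": [],
                "parent_branch": dfs_open[-1]["order"] if dfs_open else -1,
                "order": len(all_branches),
            }
            all_branches.append(entry)
            dfs_open.append(entry)
            continue
        if rec == "ENDBRA":
            parts = line.split()
            if not dfs_open:
                raise PdbqtError(f"ENDBRANCH without open BRANCH at line {lineno}")
            top = dfs_open.pop()
            if len(parts) == 3 and (
                int(parts[1]) != top["parent_serial"] or int(parts[2]) != top["child_serial"]
            ):
                raise PdbqtError(
                    f"ENDBRANCH {parts[1]} {parts[2]} at line {lineno} does not close "
                    f"open BRANCH {top['parent_serial']} {top['child_serial']}"
                )
            continue
        if rec == "TORSDO":
            torsdof = int(line.split()[1])
            continue
        if rec in ("ATOM", "HETATM"):
            serial, name, xyz, charge, t = _parse_atom_line(line, lineno)
            idx = len(serials)
            serials.append(serial)
            names.append(name)
            types.append(t)
            charges.append(charge)
            coords.append(xyz)
            if dfs_open:
                for entry in dfs_open:
                    entry["moved"].append(idx)
            elif in_root or not seen_root:
                root_atoms.append(idx)
            else:
                root_atoms.append(idx)  # stray trailing atom: treat as rigid
            continue
        raise PdbqtError(f"unrecognized record {rec!r} at line {lineno}")

    if dfs_open:
        top = dfs_open[-1]
        raise PdbqtError(
            f"unclosed BRANCH {top['parent_serial']} {top['child_serial']} at end of file"
        )
    if not serials:
        raise PdbqtError("no ATOM/HETATM records found")

    serial_to_idx = {s: i for i, s in enumerate(serials)}
    branches = []
    for entry in all_branches:
        for key in ("parent_serial", "child_serial"):
            if entry[key] not in serial_to_idx:
                raise PdbqtError(f"BRANCH references unknown atom serial {entry[key]}")
        branches.append(
            Branch(
                parent_atom=serial_to_idx[entry["parent_serial"]],
                child_atom=serial_to_idx[entry["child_serial"]],
                moved=tuple(entry["moved"]),
                parent_branch=entry["parent_branch"],
            )
        )

    if torsdof is not None and torsdof != len(branches):
        warnings.warn(
            f"TORSDOF {torsdof} does not match branch count {len(branches)}",
            stacklevel=2,
        )

    xyz = np.array(coords)
    if remark_bonds:
        bonds = sorted(set(tuple(sorted(b)) for b in remark_bonds))
    else:
        bonds_set = {
            tuple(sorted((br.parent_atom, br.child_atom))) for br in branches
        }
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        ii, jj = np.where((d < BOND_INFER_CUTOFF) & (d > 0))
        for i, j in zip(ii, jj):
            if i < j:
                bonds_set.add((int(i), int(j)))
        bonds = sorted(bonds_set)

    return LigandModel(
        names=tuple(names),
        types=tuple(types),
        charges=np.array(charges),
        ref_coords=xyz,
        bonds=tuple(bonds),
        root=tuple(root_atoms),
        branches=tuple(branches),
    )


def write_receptor_pdbqt(atoms: list[tuple[str, float, np.ndarray]]) -> str:
    lines = []
    for k, (t, q, xyz) in enumerate(atoms, start=1):
        lines.append(_format_atom(k, t, np.asarray(xyz, dtype=float), q, t))
    return "\n".join(lines) + "\n"


def parse_receptor_pdbqt(text: str) -> list[tuple[str, float, np.ndarray]]:
    atoms = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip().upper()
        if rec in ("ATOM", "HETATM"):
            _, _, xyz, charge, t = _parse_atom_line(line, lineno)
            atoms.append((t, charge, xyz))
    if not atoms:
        raise PdbqtError("no ATOM/HETATM records found in receptor text")
    return atoms


# ---------------------------------------------------------------------------
# map file I/O (plain text, one node value per line, x fastest / z slowest)
# ---------------------------------------------------------------------------


def write_maps(maps: GridMaps) -> str:
    out = io.StringIO()
    out.write(f"spacing {maps.spacing:.6f}\n")
    out.write(f"npts {maps.npts[0]} {maps.npts[1]} {maps.npts[2]}\n")
    out.write(
        f"origin {maps.origin[0]:.6f} {maps.origin[1]:.6f} {maps.origin[2]:.6f}\n"
    )
    for name in sorted(maps.affinity):
        out.write(f"map {name}\n")
        np.savetxt(out, maps.affinity[name].flatten(order="F"), fmt="%.8g")
    out.write("map e\n")
    np.savetxt(out, maps.electrostatic.flatten(order="F"), fmt="%.8g")
    return out.getvalue()


def read_maps(text: str) -> GridMaps:
    lines = text.splitlines()
    if len(lines) < 3:
        raise ValueError("truncated map text")
    spacing = float(lines[0].split()[1])
    npts = tuple(int(v) for v in lines[1].split()[1:4])
    origin = np.array([float(v) for v in lines[2].split()[1:4]])
    shape = tuple(n + 1 for n in npts)
    n_nodes = shape[0] * shape[1] * shape[2]

    affinity: dict[str, np.ndarray] = {}
    elec = None
    k = 3
    while k < len(lines):
        header = lines[k].split()
        if header[0] != "map":
            raise ValueError(f"expected 'map' header at line {k + 1}")
        name = header[1]
        vals = np.array([float(v) for v in lines[k + 1 : k + 1 + n_nodes]])
        grid = vals.reshape(shape, order="F")
        if name == "e":
            elec = grid
        else:
            affinity[name] = grid
        k += 1 + n_nodes
    if elec is None:
        raise ValueError("map text lacks the electrostatic map 'e'")
    return GridMaps(origin, spacing, npts, affinity, elec)
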