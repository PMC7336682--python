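# Methods

## Search model

A docking pose is a real vector of length `7 + Ntor`: translation (Å),
orientation as four quaternion components, and one dihedral per rotatable
bond (radians, periodic on `[-π, π)`). All swarm updates treat every
dimension as an ordinary bounded real; after each move a `repair` step wraps
the torsions, clips the non-periodic dimensions to the box, and renormalizes
the quaternion block (an all-zero block resets to the identity rotation).
The translation genes *displace* the ligand frame: the all-zero genotype
reproduces the ligand's reference coordinates, which places generated
fixtures' search boxes at the origin. Swarm diversity and the search-space
diagonal `A` are computed over all dimensions with equal weight, quaternion
components included; the quaternion dimensions span `[-1, 1]` and the
torsions exactly `2π`, so no block dominates `A`.

Velocities are clamped componentwise to half the per-dimension range.
Boundary handling after a step: clip non-periodic dimensions, wrap torsions.
Clipping (rather than bouncing) keeps the swarm inside the box so the
diversity ceiling remains meaningful.

## The optimizer

One shared `numpy.random.Generator`, seeded from the run configuration,
drives initialization, swarm updates (particle-major, dimension-minor draw
order), acceleration and the local search, so a run is bit-reproducible from
its seed.

* **RDPSO update** — thermal term `α|C − X|φ` (`φ ~ N(0,1)`) plus drift
  `β(p − X)` toward the local attractor `p = γP + (1−γ)G` with a fresh
  `γ ~ U(0,1)` per dimension. Canonical coefficients: `α` annealed linearly
  0.9 → 0.3, `β = 1.45`.
* **LPSO baseline** — inertia-weight update `wV + c1 r(P−X) + c2 R(G−X)`
  with `w` 0.9 → 0.4 and `c1 = c2 = 2.05`. The inertia weight applies to
  LPSO only.
* **Global-best topology** for all algorithms; personal-best ties keep the
  incumbent; the stored global best is a running minimum and never worsens.

### Two-phase diversity control

The controller measures `D(X_n) = 1/(M·A) Σ‖X_i − X̄‖` each iteration and
keeps it between a linearly decaying floor (`0.75·D(X_1)` → `0.002·D(X_1)`)
and a fixed ceiling `0.95·D(X_1)`. Crossing the floor flips the swarm into a
divergence phase with `α = α₀/Dr^c1`, `β = β₀/Dr^c2` (`α₀ = 9, β₀ = 3,
c1 = 1, c2 = 0.7`); reaching the ceiling flips it back and resets the
convergence clock. If a convergence phase stays above the floor for more
than `accr·n_max` iterations (`accr = 0.003`), every personal best is
replaced by its local attractor and re-scored once per particle — applied on
every iteration for which the condition holds, and also in the very first
convergence phase. Bookkeeping (personal/global bests, budget) continues
during divergence. Two degenerate-input guards: a fully collapsed swarm
(`Dr = 0`) caps the ratio at `10⁻⁶` instead of dividing by zero, and its
positions receive a uniform jitter of `10⁻⁶` of each range so the thermal
term `|C − X|` is not identically zero.

### Solis–Wets local search

The classical variant: a Gaussian deviate with componentwise mean `bias` and
scalar standard deviation `ρ` (native genotype units) is tried forward, then
backward; a success moves the point and adapts the bias (`0.2·bias + 0.4·Δ`
forward, `bias − 0.4·Δ` backward), a failure halves the bias. Four
consecutive successes double `ρ`, four consecutive failures halve it;
termination at `ρ < 0.01` or 300 iterations. `ρ₀ = 1.0` by default
(configurable). It is applied once per iteration to the particle with the
lowest current fitness (ties → lowest index), and the improved point
overwrites that particle's position, its personal best if better, and the
global best if better still (Lamarckian write-back). Every trial evaluation
counts against the run budget.

### Budget and schedule horizon

The run terminates when the evaluation budget is exhausted (the last local
search may overrun by at most `2 × 300` evaluations). The linear schedules
(`α`, `w`, the diversity floor) need an iteration horizon `n_max`; we use
`n_max = ceil(budget / (M + 100))`, where 100 is a nominal per-iteration
local-search consumption. A horizon of `budget/M` would leave the schedules
less than half-finished at budget exhaustion — the floor would still sit
near `0.5·D(X_1)` and the swarm would be forced to keep exploring when it
should be refining. If a run outlasts `n_max` (cheap local searches), the
schedules simply hold their final values.

## The docking surrogate

The objective is a grid surrogate of a docking force field, not a calibrated
one: per-ligand-atom-type Lennard-Jones affinity maps and one electrostatic
map precomputed on a lattice (default 60×60×60 intervals at 0.375 Å — a
22.5 Å cube) and read by trilinear interpolation; plus the ligand internal
energy, `ε[(r_eq/r)¹² − 2(r_eq/r)⁶] + q_iq_j/(4r²)`, over atom pairs three
or more bonds apart (1-2 and 1-3 excluded, 1-4 and beyond unscaled). The
atom-type alphabet is closed — C, N, O, H plus a generic X — with tabulated
`(ε, r_eq)` combined by Lorentz–Berthelot rules. The dielectric is the
simple distance-dependent `ε(r) = 4r`. Directional hydrogen bonding,
desolvation and calibrated term weights are deliberately absent; no
literature binding-energy value should be compared against these numbers.

Numerical guards: affinity nodes are capped at `10⁵` energy units,
electrostatic nodes at `10³` (strictly below the clash cap, so capped
attraction can never cancel a capped clash), atoms outside the lattice score
a `10⁵` penalty each, and internal pair terms are capped at `10⁵`. The
binding score used for ranking adds `0.3` energy units per rotatable bond to
the intermolecular part and omits the internal energy.

Pose kinematics: torsions are applied innermost-branch-first about each
rotatable bond's axis at reference geometry, then the rigid rotation about
the root fragment's centroid, then the translation. Single-pose scoring runs
in a compiled (numba) kernel; a pure-numpy route is kept and cross-checked
in the tests, and hand-written rotation matrices are cross-checked against
`scipy.spatial.transform`.

## Synthetic fixtures

The generator emulates a re-docking experiment: a known reference pose of a
flexible ligand inside a complementary rigid receptor. The ligand is a
zig-zag chain (1.5 Å bonds, tetrahedral angles) of `4 + 2·Ntor` atoms with
one out-of-plane side atom in the rigid root and one nested branch per
rotatable bond. The side atom exists because a plain chain is almost
palindromic: with it absent, the head-to-tail-reversed pose is an
energetically competitive minimum and re-docking becomes ill-posed.

Charges are core-weighted: the root and first branch pair draw `+1.2…1.8 e`,
distal atoms `+0.15…0.35 e`; receptor contacts carry the opposite charge
scaled ×10 (core) or ×4 (distal). The resulting net monopole makes the
`1/r²` Coulomb field a smooth funnel across the whole box, while the
contacts define the specific registry: two per core atom at the pairwise LJ
optimum, one per distal atom at 1.25× the optimum — far enough out that a
wrongly folded branch meets no repulsive wall on its way in. Contacts prefer
one side of the ligand (a groove rather than a closed cage; a closed cage
proved much harder to enter within a desk-scale budget). Reference torsions
are drawn gently first (|τ| 0.25–0.6 rad) and escalate only until the
conformation fits the grid box — a fully extended high-torsion chain cannot.
The drawn pose is settled into its exact local minimum by a deep Solis–Wets
relaxation before acceptance.

The generator *certifies* each fixture and retries with a fresh internal
sub-seed otherwise:

1. **Funnel** — the reference must score below the 5th percentile of 200
   uniformly random genotypes, and below zero.
2. **Re-dockability** (for `Ntor ≤ 8`) — two independent probe runs at the
   desk-scale protocol (M = 50, 5×10⁴ evaluations) must re-find the
   reference within 2 Å RMSD. Beyond 8 torsions only the funnel is
   certified: re-docking reliability genuinely collapses with flexibility,
   in this surrogate as in real benchmarks.

What the fixtures do **not** emulate: real chemistry (idealized geometry, no
hydrogens-as-chemistry, toy charges), receptor flexibility, solvent, or
symmetric ligands (RMSD uses the identity atom mapping, which is exact here
because every atom is uniquely labeled). Passing the re-docking suite shows
the search machinery works on a realistic-*shaped* landscape; it says
nothing about chemical accuracy on real complexes.

## Evaluation conventions

RMSD is the plain root-mean-square of per-atom displacements, no
superposition, no symmetry correction; success means RMSD ≤ 2.0 Å
(inclusive). A case summary over R repeats reports NS (successful runs),
mean/best docked energy, ME (mean binding score), LE (lowest binding score
among successful runs; undefined when NS = 0), and the rank of the LE
conformation among all R sorted ascending by binding score (ties broken by
run index), recorded as R+1 when NS = 0 — 31 under the standard 30-repeat
protocol. `Dref = Value_test − Value_ref` against the per-case best
algorithm, which therefore scores exactly 0.

## Problem sizes in the shipped suite

The production protocol (swarm 150, 2.5×10⁶ evaluations, 30 repeats per
case) is the package default but far beyond a desk run. The test suite uses
deliberately scaled-down versions: sphere/Rastrigin checks at M = 20–30 and
10⁴–6×10⁴ evaluations; re-docking on 2- and 6-torsion fixtures at M = 50,
5×10⁴ evaluations, 30 repeats; funnel regression on a sample of generator
seeds across 2, 6 and 12 torsions. These sizes are the package's chosen
regression scale; the full protocol is reproduced by raising `m`,
`eval_budget` and `repeats` in `RunConfig`/the CLI.

## Known limitations

* The surrogate's absolute energies are meaningless outside this package.
* The acceleration mechanism is applied persistently while its trigger
  holds; at small `n_max` (desk budgets) it fires after very few iterations
  and produces frequent converge/diverge cycling. This is the literal
  scaled-down behaviour of the rule, and the hybrid still dominates the
  plain LRDPSO baseline at that scale.
* Grid discretization error grows steeply inside the LJ wall; comparisons
  against continuous-space sums are only meaningful outside contact range.
* `load_fixture` trusts its metadata; it rebuilds maps only when the map
  file is absent.
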