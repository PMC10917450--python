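# Methods

This note documents the models, estimators and numerical choices behind
`dendrofix`, in the spirit of the model documentation of simulation
packages: what is computed, under which assumptions, and what the tests do
and do not establish.

## Morphology representation

A morphology is a rooted tree of 3D nodes with radii, read and written as
7-column SWC (`id type x y z radius parent`; structure codes 1 soma,
2 axon, 3 basal, 4 apical, others custom). Nodes are kept in
parent-before-child order; ids on disk are 1-based and renumbered on every
write. Known-incomplete ("cut") terminals have no standard SWC field and
are persisted as a `# cut: <ids>` header comment — a dialect local to this
package; files without the header carry no flags. Multi-root files are
rejected rather than auto-stitched.

Before any growth the tree is resampled to an inter-node spacing of 1 µm.
The growth rule attaches targets node-to-node, so it needs dense, uniform
attachment candidates; with 1 µm spacing the error of not attaching
mid-edge is bounded by half the spacing. Resampling only subdivides edges
(with linear interpolation of radii); original nodes — in particular
branch points and terminations — survive bit-exactly and total cable
length is preserved exactly. Nodes closer than the spacing are left alone:
merging them would alter the piecewise-linear geometry.

## The growth rule

Targets are connected greedily, each step appending the (target, node)
pair minimising `d + bf·(PL(node) + d)`, i.e. the path length the *new*
point would have, subject to `d ≤ G_thr`. The alternative of costing only
`PL(node)` was rejected: at `bf = 1` the optimised quantity must be the
new point's conduction path. Ties are broken lexicographically on
(cost, node id, target index), which makes growth deterministic across
platforms. Newly appended nodes are always attachable (they are
descendants of whatever mask seeded the growth); the growth mode only
controls the initial mask — every seed node in biological mode (restricted
to nodes within `G_thr` of the volume), flagged cut terminals in conserved
mode. Unreachable targets are reported, never silently dropped.

With `bf = 0` and unbounded threshold the rule *is* Prim's algorithm; the
test suite checks exact equality of total cable with a classical MST
oracle to 1e−9 over 100 random instances.

## Growth volumes

A volume is defined by a 2D/3D point set and a tightness parameter
`alpha ∈ [0, 1]` on the circumradius scale of its Delaunay complex:
`alpha = 0` keeps every simplex (the convex hull), `alpha = 1` keeps the
tightest complex that still touches every defining point; the kept-simplex
threshold interpolates linearly between those two radii, so the enclosed
measure is non-increasing in `alpha`. Coplanar point sets (by SVD rank
tolerance) are handled natively as planar areas; containment then also
requires the query to lie in the plane (tolerance `plane_tol`, default
1e-6 µm). Uniform sampling draws a kept simplex with probability
proportional to its measure and a Dirichlet-distributed barycentric point
inside — exact, with rejection used only for the density weight and the
exclusion margin. The distance of an outside point to the volume is
approximated by its distance to the nearest kept vertex; this upper bound
is only used in proximity heuristics where simplex-scale slack is
irrelevant.

`G_thr` is the total chord length of the line through the root `R` and
`Q = (V_mean + V_far)/2` inside the volume, computed by clipping the line
against every kept simplex and merging the parameter intervals. For small
volumes far from the soma this chord is a conservative cap on connection
span; growth then proceeds chain-wise through the distributed targets.

## Parameter estimation

**Balancing factor.** The root-angle distribution — the angle at each node
between the local edge direction and the away-from-root direction — is a
monotone readout of `bf`: cable-optimised trees meander (large angles),
path-optimised trees grow radially (angles near 0). The estimator computes
the input's mean root angle after 1 µm resampling and inverts it through a
calibration curve: mean root angles of reference trees grown at
`bf = 0, 0.1, …, 1` (150 targets in a 100 µm sphere, three fixed seeds per
grid point, forced monotone). Inputs with fewer than 20 nodes fall back to
`bf = 0.5` with a warning. Parameter-recovery tests show a worst-case mean
error below ±0.1 across the grid for sphere-grown arbours; the calibration
is geometry-dependent, so strongly anisotropic arbours may be estimated
less accurately.

**Target count.** `Npts = round(2 · ρ · |V|)`, floored at 1, with ρ the
density of branch plus termination points over the input's spanning-field
hull (area for planar volumes, volume otherwise). The factor of 2 targets
per expected topological point only sets a starting level — branch-point
matching corrects it.

**Target placement.** Targets are thinned against a Gaussian kernel
density built from the input's branch and termination points, evaluated in
the volume's local coordinates. The weight is used only when the input has
topological points *inside* the volume: a lesioned region is empty of
surviving branch points, and extrapolating the KDE into it only piles
targets against the rim, so such repairs sample uniformly. An exclusion
margin `R_d` keeps targets away from every point of the existing neuron
(default 0 for plain repair; 2 µm — twice the resampling spacing — in the
lesion experiment, so that neither regeneration nor invasion is favoured
by targets hugging either origin).

**Branch-point matching.** With a reference (or explicit target `NBr`),
growth is iterated by bisection on the number of targets (at most 12
iterations), using *nested* target sets — one pool is sampled and prefixes
of it are grown — so the branch-point count is near-monotone in the count
and the bisection is well behaved; ties go to fewer points. When a target
`NBr` is given, the starting estimate is raised to 3× the branch-point
deficit so the 1…4×initial bisection range brackets the target even for
small seed trees.

**Taper.** A least-squares fit of `d(p) = scale·(1 − p/P)² + offset` over
the input's dendritic nodes (p: path length to root; P: maximum path
length within the node's structure label), with the tip floor `d_min`
taken as the 5th percentile of terminal diameters — the floor is
data-driven because tip diameters level off at species-dependent values
that cannot be assumed. New-node diameters follow the fitted quadratic,
floored at `d_min` and forced non-increasing toward the tips along new
material.

**Jitter.** Grown branches are straight between targets; to match the
appearance of biological cable, per-branch 3D Gaussian noise (s.d. =
amplitude) is low-pass filtered by a centred moving average (window 5
nodes) and added to new-node coordinates, with branch points and
attachment junctions pinned at zero displacement. The default amplitude is
0.3× the input's mean per-edge tortuosity excess (segment path length
minus chord length per edge), so perfectly straight synthetic inputs get
zero jitter and tortuous biological inputs get proportionate roughness.
Jitter is isotropic in 3D.

**Pruning.** Optional trimming to a total cable length: the shortest
terminal segment composed entirely of new nodes is removed repeatedly;
input nodes are never removed.

## Lesion experiment

A lesion severs the subtree of a uniformly chosen qualifying branch-point
child with cable length in (50, 1000) µm; the branch point (stem) is
flagged as a cut terminal. The growth volume for regrowth is the convex
hull of the severed nodes (alpha = 0), targets are excluded within `R_d`
of the lesioned neuron, and repair runs in biological mode with `bf`
estimated once per input morphology. Regeneration is the percentage of new
cable whose path to the soma passes through the stem; material invading
from neighbouring branches counts as invasion. Severing removes the edge
between the stem and the severed subtree root, so the severed length
includes that edge while the two returned trees' cable sums fall short of
the original by exactly it.

## Passive electrotonics

The functional check is the steady-state input resistance of a passive
compartmental model: each parent–child edge is a frustum with axial
resistance `Ra·l/(π·r0·r1)`, each node carries the leak of half its
adjacent frustum lateral surfaces over `Rm`, and a single-node soma is a
sphere of area 4πr². Defaults `Rm = 28 kΩ·cm²`, `Ra = 150 Ω·cm` (typical
pyramidal passive values); since all comparisons are relative, these only
scale the numbers. The sparse linear system is solved directly; against
the sealed-end cable closed form `R_∞·coth(L)` the 1 µm discretisation is
accurate to ~1e-5 %. Cutting dendrites removes shunt, raising `R_in`
(the hyperexcitability proxy); a successful repair moves `R_in` back
toward the reference.

## Synthetic study morphologies

All experiments run on generator-built arbours: uniform targets in a
disc / sphere / cone / slab grown from a central soma with the package's
own rule, resampled and tapered. The class-IV-like fixture (800 targets,
200 µm disc, `bf = 0.2`) reproduces the flat, dense, space-filling regime
in which dendriotomy regrowth has been characterised experimentally; the
pyramidal-like fixture combines a basal sphere, a straight apical trunk
and oblique growth in a cone. These are stand-ins tuned to qualitative
regimes, not statistical clones of any specimen: they share the growth
rule with the repair itself, so cut-and-repair tests demonstrate
*self-consistency* of the method (recovery of trees the model can
express), not fidelity to any particular biological dataset; real
reconstructions additionally carry reconstruction noise, non-homogeneous
statistics and anatomical boundary effects that the generators do not
emulate. Validation protocols use the planar space-filling regime (400
targets, 150 µm disc, cuts of 300–1000 µm, conserved mode with
branch-point matching and pruning to the reference length), mirroring the
system in which regrowth is biologically characterised.

## Problem sizes and determinism

The shipped experiments use 100 MST instances (≤ 50 points), 20-seed
suites for trade-off, determinism, ancestry, branch-point matching and
restoration, 20 seeds × 9 grid points for balancing-factor recovery, and
200 lesion trials on the class-IV-like arbour; these sizes give stable
statistics while keeping the full suite in the low minutes on one core.
Every stochastic step threads a `numpy` `Generator` derived from an
explicit seed; identical inputs and seed give byte-identical SWC output.

## Known limitations

- The growth threshold derived from the root–Q chord can be conservative
  for small volumes far off the soma axis; conserved repairs whose
  terminals sit farther from the first target than the chord will not
  start — setting `g_thr` manually is the intended escape hatch.
- The `bf` estimator assumes roughly isotropic arbours around the root;
  heavily polarised cells (one long trunk) push the mean root angle down
  and bias the estimate upward.
- Repairs assume the remaining tree's statistics are homogeneous and
  extend them into the volume; vastly incomplete inputs give unreliable
  estimates of `bf`, taper and density.
- The electrotonic check is passive and steady-state only; active
  channels, synapses and frequency-dependent behaviour are out of scope.
- The alpha-shape containment test classifies points in dropped simplices
  as outside even when they touch a kept face from the other side; at the
  1 µm node spacing used throughout this affects at most sliver regions.
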