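# Methods

`ramify` simulates the growth of spatial biological networks — neurites,
osteocyte canaliculi, vessel sprouts, fungal hyphae — as a population of
stochastic agents ("growth cones") moving through a 3D tissue environment.
This note records the model, its tunable parameters, the numerical choices,
and what the synthetic fixtures do and do not establish.

## Growth model

Each cone performs a biased, correlated random walk with constant step
length. Every influence on the step direction is a 3D Gaussian *cue kernel*
N(μ, Σ): the mean μ is the directional bias, the covariance Σ the
anisotropic mobility. Independent cues combine exactly by convolution,

    μ_conv = Σᵢ μᵢ,   Σ_conv = Σᵢ Σᵢ ,

and the step direction is drawn from the angular marginal of the combined
Gaussian — the projected-normal (angular Gaussian) distribution on the unit
sphere,

    f(y) = (2π)^(-1) |Σ|^(-1/2) (yᵀSy)^(-3/2)
           · exp(½(α² − μᵀSμ)) · M₂(α),
    S = Σ⁻¹,  α = yᵀSμ / √(yᵀSy),
    M₂(a) = (1 + a²)Φ(a) + a·φ(a),

which reduces to the uniform density 1/(4π) for μ = 0, Σ = I. Separating
the radial and angular parts leaves the step length as an independent
distribution (constant by default, optionally Gaussian truncated at zero).

Cue families and their kernels:

| cue | μ | Σ |
|---|---|---|
| drift field | field vector | ε·I (delta-like) |
| soluble factor | ±β·∇c | γ·I |
| random motion | 0 | diag(σ²) |
| persistence | sum of last *m* step directions | σ_P²·I |
| tissue structure | g·∇p | α·Rᵀ·diag(dual λ)·R / tr |

For the structural cue, R diagonalizes the local structure tensor and the
eigenvalues are mapped to their *dual*, λᵢ → λ_min + λ_max − λᵢ, then
trace-normalized. The tensor's strong eigenvectors point across structures
(along image gradients); the dual map places the largest sampling variance
along the *weakest* gradient direction, so growth aligns with walls, planes
and fibres rather than crossing them.

### Sampling and the aperture

The angular density is evaluated on a Fibonacci lattice of (default) 2000
sphere nodes with equal solid-angle weights 4π/n and sampled by discrete
inversion — bounded cost and exact reproducibility, avoiding the rejection
sampling that projected distributions otherwise require. Before sampling,
the density is zeroed outside a cone of half-angle Ω (default 25°) around
the persistence axis μ_P (the sum of the last *m* directions, falling back
to the last direction) and renormalized over the cap. The aperture is the
maximum curvature per step; together with the persistence drift it makes
trajectories locally self-avoiding (the walk cannot reverse onto itself
within the memory length).

Directional persistence is quantified by the Kuhn length
δl·Σ_Δ⟨cos θ(Δ)⟩ (lag-averaged direction correlations, lag-0 term
included); an exponential fit of ⟨cos θ(Δ)⟩ gives the decay persistence
length. A memory-free unrestricted walk has Kuhn length ≈ one step; the
estimate grows monotonically with the memory *m*.

## Events

Before moving, each cone decides on at most one event, evaluated in fixed
precedence **merge → bifurcate → branch → terminate** (physical contact
dominates; splitting precedes stochastic death). Branching spawns a daughter
at a fixed angle θ_bran (uniform azimuth) while the mother keeps its
direction; bifurcation replaces the mother by two daughters at mutual angle
θ_bif in a uniformly random plane through the mother direction; daughters
inherit parameters and the mother's direction memory. Termination freezes
the cone (it may reactivate with p_reac); leaving the volume freezes it
permanently, keeping the partial edge.

Merging implements the shortest-distance contact rule: among all sample
points of edges found in the search field, the nearest one within the
contact range 2·R_c (inclusive) becomes a new network node; the target edge
is split there and the merging cone stops. Two exclusions prevent
degenerate self-contact:

* the cone's own recent trail — its last max(m, 2)+1 sample points, tracked
  across edge splits — is never a candidate (with step length ≤ 2·R_c the
  segment just laid down is unavoidably in contact range); merging with the
  cone's *older* trajectory stays legal, so loops are legitimate network
  features;
* a newborn cone may not merge before a refractory age (default m steps), so
  branches do not instantly re-fuse with their mother edge and sibling cones
  do not fuse at the shared cell body.

Candidates are pre-filtered to the contact range before the nearest is
chosen. This is what makes cluster-parallel execution exact: edges laid
down by another cluster can transiently appear in the search cube just
outside contact range, and taking a global minimum first would let them
shadow an acceptable candidate.

## Environment

The environment is a multilayer grid of scalar volumes indexed [x, y, z]
with voxel centers at integer coordinates; agents move in continuous
coordinates in the box [0, shape−1] and all derived fields are interpolated
trilinearly. Gradients are Gaussian-derivative filters (reflect boundaries)
at scale σ_grad (default 1 voxel); structure tensors are window-smoothed
outer products of gradients at σ_window (default 2 voxels — the window must
exceed the gradient scale to capture orientation). Channels may be swapped
at runtime; derived fields are recomputed lazily.

Every edge segment is imprinted into an integer occupancy layer (voxels
within max(R_c, √3/2) of the segment, plus the containing voxels of both
endpoints, which guarantees that every sample point's voxel is labeled).
Overlapping imprints keep the earlier label; latecomers go to a spillover
map so all overlapping edges stay findable. The search cube half-width is
derived from R_c so that any sample within the contact range of a cone is
guaranteed to lie inside the cube.

## Engine and reproducibility

A run is `i` global updates of `s` growth steps (defaults 10 × 25). At each
update, active cones are partitioned by cutting Delaunay edges longer than
l_d; since the Euclidean MST is a Delaunay subgraph this equals single
linkage at threshold l_d. With l_d ≥ 2·s·l + 2·R_c (the default), two cones
in different clusters cannot come into contact within one update, so
clusters are updated independently. Every cone owns a counter-based random
stream keyed by (master seed, cone id); event decisions always consume
exactly four uniforms. Consequence: serial and cluster-parallel execution
produce bit-identical network dictionaries, which the test suite asserts.

Within a cluster, cones step in ascending id order; daughter ids are derived
from (mother id, birth step, child index), so id assignment is independent
of cluster iteration order.

## Network analysis

Nodes are typed (seed, branch, bifurcation, merge, terminal); edges carry
their full polylines and collapse to single graph edges with arc-length
attributes. Closely spaced nodes are consolidated by single linkage at a
resolution r (default 2 voxels, mimicking finite imaging resolution);
groups collapse to their centroid, parallel edges keep the minimum length,
self-loops shorter than r vanish. Metrics: mean degree 2E/N, mean local
clustering, average shortest path in unweighted hops on the largest
connected component, edge density, mean normalized betweenness, mean
current-flow (information) centrality on the largest component, mean
harmonic centrality normalized by N−1, and the giant-component fraction.
Path-type metrics are restricted to the largest component because they are
undefined on disconnected graphs; the giant fraction is always reported
alongside.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| Ω | 25° | aperture half-angle (max curvature/step) |
| l | 1 voxel | step length |
| θ_bran, θ_bif | 75° | splitting angles |
| p_bran, p_bif | 2 % /step | splitting probabilities |
| p_term, p_reac | 0.1 % /step | termination / reactivation |
| m | 5 steps | direction memory |
| search field | 3×3×3 | environment interaction range |
| R_c | 0.5 voxel | merge radius (contact at 2·R_c) |
| σ_RW, σ_P | 0.5 | random-walk / persistence kernel scale |
| structure α | 4.0 | structural covariance weight |
| structure gain | 5.0 | structural mean (gradient) weight |
| i × s | 10 × 25 | global updates × steps per update |

Event probabilities are per-step Bernoulli rates at the configured step
length; rescale them when changing l. The cue weights (σ_RW, σ_P, α, gain)
are not physical constants: they were set once so that each enabled cue
contributes a bias of order one step — the persistence drift has norm ≈ m,
so a structural gradient of ≈ 0.2–0.4 (typical for the normalized synthetic
volumes) needs a gain of ≈ 5 to contribute an O(1) mean — and are exposed
as configuration.

## Synthetic fixtures

Tissue anisotropy is modeled as a blend a·sin(2π n·x/λ) + (1−a)·smoothed
noise, both components normalized to unit variance: a single scalar `a`
interpolates from isotropic noise to perfect lamellae whose structure
tensor is dominated by the lamella normal. Cell bodies are placed by
Poisson-disk sampling (or on grids/shells) with a boundary margin, each
emitting several cones in random directions; all cones of a cell share one
seed node. The default multicellular experiment uses a 64³ volume, 12
cells at ≥ 12 voxels spacing with a 10-voxel boundary margin, 10 cones per
cell — a scaled-down stand-in for the tens of processes per cell typical of
osteocytes and neurons; with many fewer processes per cell, full network
percolation becomes a coin flip rather than the robust phenomenon the
experiment emulates. The margin keeps cell bodies clear of the volume faces so that no
cell loses most of its processes to the boundary — the emulated experiment
is network formation *inside* a tissue, and the frozen out-of-bounds state
is a simulation artifact, not biology.

What the generator does **not** emulate: real image noise and imaging
anisotropy, curved or branching tissue structures, reaction–diffusion of
soluble cues, mechanical feedback, or cell-body growth. A green test on
these fixtures establishes that the growth rules respond to idealized
structural/soluble signals as designed — not that any particular biological
tissue is quantitatively reproduced.

## Numerical choices and degenerate inputs

* Covariances are regularized by ε·I (ε = 1e−8) before inversion, so
  delta-like drift kernels are legal. The projected-normal exponent is
  ≤ 0 by Cauchy–Schwarz; for extremely peaked kernels the density can
  underflow on every grid node, in which case all mass is placed on the
  node nearest the mean direction (the correct δ-limit).
* If the aperture cap contains no node or no mass, the node nearest the
  axis carries all mass. A degenerate persistence axis (‖μ_P‖ = 0) falls
  back to the last direction, else to an unrestricted draw.
* Merge ties (equal squared distance) break toward the lowest
  (edge id, sample index); cluster iteration and finalization orders are
  sorted — there is no dependence on dict ordering anywhere.
* Delaunay clustering falls back to the pairwise-distance graph for < 5
  points or degenerate (coplanar/collinear) geometry.
* Edges whose cone never moved (single-sample stubs) are dropped at
  finalization instead of producing zero-length self-edges.
* Merges landing exactly on an existing node (sample index 0 or the last
  sample of a closed edge) reuse that node instead of duplicating it; they
  are counted separately (`merge_reused_node`).

## Known limitations

* Probabilities are not renormalized per unit length: changing the step
  length changes the per-length event rates.
* The hop-based average shortest path grows with network size; arc-length
  weighted path statistics are not currently reported.
* Inherited direction memory means daughter cones partially realign with
  the mother direction over the first ~m steps, so effective branch angles
  are smaller than θ_bran.
* Cluster-parallel execution is sequential in this implementation (the
  contract — bit-identical results — is what is tested); no
  multi-process or GPU path.
* Event probabilities are spatially constant; coupling them to environment
  channels (e.g. making termination depend on local anisotropy) is left as
  configuration surface for future work.
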