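# Methods

## Model

Modularity of a hard partition σ of a weighted undirected network compares
within-community edge weight to a configuration-model expectation,

    Q(γ) = (1/2m) Σ_ij (A_ij − γ k_i k_j / 2m) δ(c_i, c_j),

with node strengths k_i, total edge weight m, and resolution parameter γ.
For a *fixed* partition the only γ-dependence is linear: dropping the
constant 1/(2m) prefactor and writing Â = Σ_ij A_ij δ and
P̂ = Σ_ij (k_i k_j / 2m) δ over ordered pairs,

    Q_σ(γ) = Â_σ − γ P̂_σ,

a line in (γ, Q).  Multilayer modularity adds the interlayer coupling term
ω Ĉ_σ (within-community sum of the interlayer coupling matrix), with the
null model applied per layer (k_i k_j / 2m_l within layer l, zero across
layers), making each partition a plane in (γ, ω, Q).

Given any finite ensemble of partitions — however they were produced — the
pointwise maximum of these lines/planes is the best modularity achievable
*within the ensemble* at each parameter point.  The package prunes the
ensemble to the admissible subset (partitions attaining that maximum
somewhere) and maps each survivor's domain of optimality: an interval in γ,
or a convex polygon in (γ, ω).  All optimality statements are relative to
the input set; the method is a post-processor, not a community detector.

## Summation and self-loop conventions

All coefficient sums run over ordered pairs (i, j) including i = j, so Â
equals twice the within-community edge weight plus diagonal terms, and the
one-community partition of a connected network has Â = P̂ = 2m exactly.  A
stored self-loop of weight w enters the adjacency diagonal as A_ii = 2w and
adds 2w to k_i, keeping 2m = Σ k_i.  Self-loops are summed as stored;
zeroing them (common when diagonal entries encode trivial self-similarity)
is a read-time flag, not a default.  `normalized_modularity` restores the
1/(2m) prefactor for reporting; everything internal stays unnormalized.
Only the configuration null (and its per-layer block-diagonal multilayer
form) is implemented; directed, signed and bipartite variants are out of
scope.

## 1-D envelope construction

The iterative algorithm starts from the partition optimal at `gamma_start`
and repeatedly finds the smallest pairwise crossing
γ_x = (Â_1 − Â_2)/(P̂_1 − P̂_2) beyond the current transition, handing
optimality to the crossing line until no crossing remains in range.
Choices:

- **Start rule.** The optimum at `gamma_start` is argmax Q(gamma_start),
  ties broken by smaller P̂ then lower partition id.  At the default
  `gamma_start = 0` this is exactly "maximum Â"; for a nonzero start the
  argmax form is what keeps the envelope equal to the brute-force maximum.
- **Ties at a crossing.** When several lines pass through the same
  transition point, the one with smallest P̂ (shallowest slope) takes over;
  exact P̂ ties go to the lowest id.  Domains are half-open [γ_p, γ_{p+1}):
  at a transition the incoming (larger-γ) partition is the optimal one.
- **Duplicates.** Records with identical (Â, P̂, Ĉ) are partitions of equal
  merit at every parameter value; they are collapsed onto the lowest id and
  reported as `co_optimal` rather than silently dropped.
- **Tolerances.** Crossings are compared at 1e-12 absolute in γ and domains
  narrower than that are treated as empty.  Coefficients are exact sums of
  input weights, so the crossings are well-conditioned and nothing finer is
  needed.
- Negative γ is not explored by default, but `gamma_start` is a free
  parameter, so a caller can shift the range below zero.

## 2-D domain maps

Each plane contributes the halfspace above it; the parameter box contributes
four vertical halfspaces and a horizontal cap one unit above the maximum of
all planes over the box corners (affine functions attain their box maximum
at a corner, so the cap clears the envelope everywhere).  The bounded
polyhedron is resolved with Qhull's halfspace intersection (scipy), seeded
with the interior point (box center, midway between envelope and cap).  The
vertices incident to each plane's facet, projected to (γ, ω), are its
domain polygon; vertices are merged and snapped to the box at 1e-9, and
polygons with area below 1e-9 are dropped.  By construction the domains
tile the box up to boundary measure zero.

Planes admissible only outside the user box are detected by re-running the
hull on a 10×-enlarged box anchored at the origin and reporting planes
admissible there but not in the user box.  The enlargement factor is a
pragmatic bound on the searched region, not an attempt at the unbounded
problem.

Border lengths between adjacent domains are shapely intersection lengths of
the domain polygons (which share exact vertex coordinates, coming from one
hull computation); pairs meeting only at a point are not adjacent.  Point
queries resolve border ties toward the smaller partition id.  Only two
parameter dimensions are supported.

## Adjusted mutual information

AMI(X, Y) = (MI − E[MI]) / (max(H(X), H(Y)) − E[MI]) in natural log, with
E[MI] computed by the exact closed-form sum over hypergeometric joint
counts with both marginals fixed — no sampling.  Identical partitions (up
to relabeling) return exactly 1, which also settles the degenerate
two-single-community case; when exactly one partition is single-community,
MI = E[MI] = 0 while max(H) > 0, so the score is ≤ 0 as the formula
dictates.  Only the "max" normalization is provided.  The neighbor-averaged
summary weights each neighboring domain's AMI by the shared border length;
the layer-averaged summary restricts a multilayer partition and a metadata
label vector to each layer and averages per-layer AMI with equal weight per
layer (so small layers count as much as large ones).

## Ensemble generation

The sweep driver runs a pluggable heuristic `(network, γ[, ω], seed) → raw
membership` at every point of a uniform, endpoint-inclusive grid,
`runs_per_point` times.  Node indices are freshly permuted for each run
before the heuristic sees the network (so order-sensitive heuristics can
reach different local optima at identical parameters), and results are
mapped back, canonicalized and deduplicated across the whole sweep.
Per-run seeds derive from (master seed, grid index, run index) via numpy
`SeedSequence` spawn keys, so sweeps are reproducible and safely
parallelizable.

The built-in heuristic is a minimal Louvain-style greedy optimizer of the
unnormalized quality Â − γP̂ + ωĈ: passes of strictly improving single-node
moves (so quality never decreases during local moves), followed by
community aggregation into supernodes carrying per-layer strength vectors,
repeated until a local phase makes no move.  It exists so that every test
and example runs with no external detection package; it makes no optimality
or parity claim against production Louvain/GenLouvain implementations,
which plug in through the callable contract in one line.

## Synthetic benchmarks

The planted-partition generator splits n nodes into near-equal contiguous
blocks and draws each within-block (between-block) pair as an edge with
probability p_in (p_out).  The multilayer generator repeats this per layer,
letting block labels persist between consecutive layers with probability
`persistence` (resampling uniformly otherwise) and joining consecutive
appearances of each node with identity interlayer edges of configurable
weight — emulating temporal community structure with nearest-neighbor-layer
coupling.

The default study conditions are a 4-block, 80-node graph with p_in = 0.9,
p_out = 0.05 (blocks dense enough that the planted partition is the
modularity optimum near γ = 1 with high probability) and, for the
multilayer case, 30 nodes × 4 layers, 3 blocks, persistence 0.9, coupling
weight 1 — persistent enough that communities span layers, with enough
label churn to make the (γ, ω) map non-trivial.  These generators produce
Bernoulli edges with homogeneous degrees inside blocks; they do not emulate
degree heterogeneity, overlapping communities, or weighted empirical
networks, so passing recovery tests demonstrate correctness of the
pipeline's bookkeeping and geometry, not detection performance on real
data.

## Problem sizes in the shipped checks

The test suite exercises the 1-D envelope against a dense-grid argmax
oracle on 200 random instances of 5–500 lines at 10,000 γ points, the 2-D
maps against a 200×200 grid argmax on 50 instances of 10–200 planes,
E[MI] against exhaustive node-permutation averaging for all partition pairs
at n = 4–5 and sampled pairs at n = 6–7, and AMI against an independent
reference implementation at n = 50.  The acceptance script reruns the full
pipeline on the default planted conditions above (400 single-layer and 90
multilayer heuristic runs).  These sizes were chosen so the whole pipeline
re-verifies in a few seconds on one core while still covering the regimes
where envelope geometry is combinatorially non-trivial.

## Known limitations

- Optimality is always relative to the input ensemble; partitions never
  admitted to the hull may still be near-optimal over wide ranges.
- Only hard partitions; no overlapping communities or background nodes.
- One interlayer coupling parameter; no per-layer ω or >2-dimensional
  parameter spaces (the linear-subspace formulation generalizes, but the
  geometry here is implemented for lines and planes only).
- The out-of-box report depends on the 10× search region; a plane optimal
  only beyond it is reported as pruned.
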