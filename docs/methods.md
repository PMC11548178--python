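# Methods

## Model and assumptions

The pipeline registers a skinned articulated template to a deformed target
surface through sparse correspondences. Its core assumption is
*near-isometry*: an articulated deformation of a body surface changes
geodesic (on-surface) distances between corresponding points only slightly,
while Euclidean distances between the same points can change by the full
range of limb motion. Compatibility of two candidate correspondences is
therefore measured by how well their geodesic separations agree across the
two surfaces. The assumption degrades where surfaces self-contact (an arm
pressed against the torso creates shortcuts on one surface only) and under
strong soft-tissue or clothing deformation; nothing in the pipeline detects
those regimes — they surface as reduced compatibility among true pairs.

## Geodesic measurement

Distances are computed only between the vertices named by the
correspondence set (one single-source problem per endpoint), never as an
all-pairs matrix. Two solvers:

- **`edge_dijkstra`** — shortest paths on the mesh edge graph. Exact graph
  metric, but it overestimates surface geodesics by a factor set by the
  triangulation's direction set: up to ~41 % on a grid whose diagonals all
  run one way, ~8 % after one midpoint-subdivision round (`refine=1`),
  which adds edge-midpoint and vertex-to-opposite-midpoint (median)
  directions. These are the documented planar tolerances; on isotropic
  triangulations like a subdivided icosphere the refined error is below
  1 %. This is the only solver available for point clouds, which route
  through a symmetric k-NN proxy graph (default k = 8).
- **`heat`** — the heat-method approximation (cotangent Laplacian, one
  short-time heat solve, normalized-gradient Poisson solve; diffusion time
  t = mean edge length squared). Within ~2 % of closed-form great-circle
  distances on a subdivided icosphere, weaker near open boundaries (up to
  ~20 % on small bordered patches). Its decisive property here is noise
  robustness: on a 2 mm-noise surface, graph shortest paths inflate with
  every noisy edge they traverse (the inflation grows with path length and
  shrinking edge length), while the diffusion solution averages the noise
  out. Measured on default scenes, the median inlier geodesic-difference
  drops roughly from 6 mm (Dijkstra) to 3 mm (heat).

The pipeline default is `auto`: heat on meshed surfaces, Dijkstra on k-NN
substrates. Because compatibility compares distance *differences* computed
identically on both surfaces, a consistent bias largely cancels; what
matters is the scatter.

## Compatibility graph

First-order compatibility uses the negative-exponential kernel
`SC1 = exp(-S^2 / d^2)` with `d = 0.05 m` by default — chosen to match the
5 cm scale at which a correspondence is counted correct, so the kernel
starts suppressing pairs whose geodesic story disagrees by more than the
error we are willing to call "correct" anyway. Binarization is strict
(`> tau_cmp`), `tau_cmp = 0.99` by default and `0.999` recommended when
slight motions produce very many matches; with these defaults an edge
requires geodesic agreement within about 5 mm. The second-order measure
`SC2 = C ⊙ (C·C)` counts joint supporters per compatible pair; on a planted
block of m mutual inliers every inlier–inlier entry is at least m − 2
(verified exactly in tests), while independent outliers almost never
accumulate support. All diagonals are fixed to zero — a correspondence is
not compared with itself, and a nonzero diagonal would double-count clique
endpoints downstream. No Euclidean prefilter is applied before the O(N²)
geodesic comparison: a Euclidean bound does not dominate a geodesic
difference, so pruning on it would be unsound; N is instead capped upstream
by the matcher.

## Clique search and selection

Maximal cliques of the binarized graph are enumerated with Bron–Kerbosch
with pivoting, the outer level following a degeneracy ordering. Vertex sets
are Python integer bitmasks; ties (pivot choice, ordering) break toward the
lowest index, making enumeration deterministic and equivariant under vertex
permutation. Defaults: `min_size = 3` (a 2-clique cannot constrain an
articulation) and a 10,000-clique cap with an explicit truncation flag —
noisy near-complete inlier blocks can have combinatorially many maximal
cliques that differ in a few members, and the cap bounds work without
hurting selection, since those cliques are near-duplicates. Selection is
node-guided: for each node only its highest-total-weight containing clique
survives, where total weight is the sum of SC2 over the clique's internal
pairs (the natural reading of clique weight); survivors are deduplicated,
ranked by weight, and truncated to `top_k = 5` hypotheses.

## Articulated fit

The body model is any (template, joint tree, convex skinning weights, part
labels) bundle; posing is forward kinematics (axis-angle per joint, rotation
about the rest joint center, composed root to leaf) followed by linear blend
skinning and a global rigid transform. The zero pose reproduces the
template exactly.

Per hypothesis, the global motion is first estimated in closed form
(Kabsch/SVD with determinant correction to +1) from the hypothesis'
torso-labeled pairs — the torso moves most rigidly — over all such pairs;
with fewer than three torso pairs, or a rank-deficient configuration, the
estimate falls back to all pairs of the hypothesis and the result is
flagged.

The pose objective is `E(θ) = Σ ρ(||M_i − p_i||) + λ ||θ||²` with the
Geman–McClure penalty `ρ(s) = s²/(s² + σ)`, `σ = 1e-3 m²` (soft residual
threshold near 3 cm) and `λ = 1e-3`. The isotropic Gaussian angle prior
stands where a learned pose prior would plug in; the interface accepts any
external callable, and the quadratic default is strong enough to park
unconstrained joints at rest without visibly biasing constrained ones.
Optimization is L-BFGS with analytic gradients: a joint perturbation
rotates its subtree about the posed joint center, and the world-frame
angular gradient maps to rotation-vector coordinates through the SO(3) left
Jacobian (verified against finite differences to ~1e-7 relative; a
finite-difference mode is retained and passes the same recovery tests).
Because the bounded loss is flat far from the optimum, fitting anneals the
scale over `(400, 20, 1) × σ` — graduated non-convexity; the final stage
uses the configured σ exactly, and all reported loss terms are evaluated
there. The root joint angle is locked at zero by default: it is redundant
with the global rotation, and locking keeps recovered joint angles
identifiable.

Hypotheses are ranked by `D_knn`, the summed squared distance from data
points to their nearest deformed-model vertex, with data subsampled to
2,000 points under a recorded seed (ranking is stable under this on the
scales used; the direction data→model is adopted and fixed here). The
winner is then refined in two stages:

1. **Consensus expansion.** The correspondence set grows to everything
   binarized-compatible with at least 10 % of the winning clique's members.
   The clique acts as a consensus seed: planted outliers are compatible
   with essentially none of it, so the expanded set recovers inliers the
   clique itself dropped (noise fragments long-range compatibility edges)
   at almost no outlier cost. A robust sparse fit runs on this set.
2. **Dense nearest-neighbor coupling.** Two rounds in which every model
   vertex pairs with its nearest target point and is fitted jointly with
   the consensus pairs (annealing `(20, 4, 1) × σ`). The dense term pins
   body parts the sparse set under-determines — a distal segment with one
   or two pairs has rotation components the data cannot see, and the prior
   would otherwise drag it — while the sparse pairs carry vertex-level
   identification the dense term is blind to (a tube surface looks
   identical under twist). Ordering matters: the dense term only enters
   after the consensus fit has placed every limb near its basin, because
   nearest-neighbor assignments from a badly posed limb lock onto the wrong
   surface region and the bounded loss cannot tell.

## Synthetic scenes and what they show

The fixture body is a tube-limb humanoid: 16 joints, one tube per bone
(rings of 8 vertices at ~5 cm spacing, ~860 vertices), a hub vertex at each
joint welded to its own tube's start ring and the parent tube's nearest
ring, hard (one-hot) skinning. With hubs exactly at the rotation centers,
every mesh edge joins points that move rigidly together or a bone to its
own rotation's fixed point — articulation is an **exact isometry** of the
edge graph. The ring spacing keeps graph-metric scatter and noise-induced
path inflation small relative to the 5 mm compatibility gate at the default
noise level. Soft weights are supported by the skinning code and tested,
but the fixture stays hard so closed-form oracles exist.

`make_scene` poses the body at per-joint angles uniform in ±0.6 rad by
default (capped at 1.2 rad against self-intersection), adds isotropic
Gaussian vertex noise (default 2 mm, the scale of a consumer depth sensor),
and plants 200 correspondences of which 30 % are outliers — uniform random
mismatches by default, or a coherent part-to-part block (`clustered`)
mimicking symmetric-limb confusion. Everything is reproducible from the
seed.

What passing on these scenes does **not** show: robustness to clothing and
soft tissue, scanner artifacts (holes, quantization, anisotropic noise),
descriptor ambiguity on symmetric bodies (the planted correspondences
bypass feature matching), partial overlap, or geodesic shortcuts from
self-contact. The generator validates the machinery under conditions where
the core assumption holds exactly up to noise; real-scan performance rests
on how nearly that assumption holds there.

Evaluation: a correspondence is *correct* iff its target endpoint lies
within 5 cm of the ground-truth position of its source vertex; precision is
the correct fraction of the reported (winning-clique) set. Surface error is
RMSE over all model vertices against the noiseless ground-truth pose.
Default problem sizes throughout (200 correspondences, ~860-vertex body, 10
scene seeds, 300-pair recovery fits) are the package's standard
configuration and keep a full validation run in the low minutes on one
core.

## Descriptors

The bundled descriptor is an FPFH-style 33-bin histogram of Darboux-frame
angles inside a support radius, with neighbor histograms blended in at
inverse-distance weight; it is rigid-invariant by construction (only dot
and cross products of relative geometry enter). Normals come from
area-weighted face averaging on meshes and PCA plane fits (centroid-outward
sign) on point clouds. Matching is nearest-neighbor or mutual
nearest-neighbor on descriptor distance, ties broken toward the lowest
target index. The descriptor only seeds the pipeline — the compatibility
stages carry all outlier rejection — and the interface accepts any
fixed-length descriptor table in its place.

## Known limitations

- Mirror-symmetric poses can produce a coherent wrong-side clique that the
  geodesic criterion cannot distinguish; D_knn ranking usually, not always,
  breaks the tie toward the correct side.
- `d` and `tau_cmp` jointly set a hard geodesic-agreement gate (≈5 mm at
  defaults); data whose noise pushes true pairs past the gate fragments the
  inlier clique, which the consensus expansion mitigates but cannot fully
  undo.
- The clique cap bounds worst-case enumeration on dense graphs; on inputs
  with several genuinely disjoint large consistent sets plus heavy noise,
  truncation could hide a competing hypothesis (the flag reports it).
- Shape parameters are not optimized; the template's proportions are taken
  as given.
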