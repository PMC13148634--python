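# Methods

## Scope and model

The package estimates, for a set of specimens, how closely the jaw joint
reaction force (JRF) aligns with the structural axis of the quadrate, and
whether that alignment evolves in a correlated way across a clade. Four
stages are chained: muscle force reconstruction, rigid-body reaction
statics, unit-vector similarity statistics, and phylogenetic regression.

### Muscle forces

Muscles are modeled as frusta whose faces are the origin and insertion
attachment areas measured from triangulated surface meshes. Site area is the
sum of half cross-product magnitudes; the site centroid is the area-weighted
mean of face centroids (a lamina centroid — a plain vertex mean is available
as `site_centroid(..., method="vertex")` for comparison with node-averaging
workflows, and the two differ on unevenly triangulated patches). Fascicle
length enters twice — once as the frustum height and once as the PCSA
denominator — and is taken as an *absolute* length: the origin–insertion
centroid chord multiplied by a relative fascicle-length fraction. This keeps
the frustum volume dimensionally consistent; the relative fraction is the
quantity a dissection actually yields. PCSA uses the multiplicative
pennation convention, PCSA = (V/l_f)·cos θ, so pennation can only reduce
the effective cross-section. The frustum formula includes the geometric-mean
term, V = (l_f/3)(A_or + A_ins + √(A_or·A_ins)), which reduces to a prism
for equal faces and a cone when one face vanishes.

Parameters and defaults:

| parameter | units | default | rationale |
|---|---|---|---|
| specific tension | N/cm² | 30 | standard vertebrate skeletal-muscle value |
| relative fascicle length | – | 0.40–0.60 per muscle | placeholder table; override per specimen |
| pennation | deg | 10–25 per muscle | placeholder table; override per specimen |
| null sample size | – | 1350 | fills the sphere densely at negligible cost |
| resamples | – | 10,000 | gives a 1/10,001 ≈ 0.0001 p-value floor |
| gape | deg | 5 | geometry is supplied already posed; never re-posed |

The shipped fascicle/pennation table is an order-of-magnitude placeholder
(flagged as such in the code): these are dissection quantities that must be
supplied per specimen for real analyses.

Each muscle's scalar force is spread over its attachment vertices in
proportion to nodal area weights (one third of each incident face's area),
with every nodal load directed at the opposite attachment's centroid. Scalar
force is conserved exactly; the net vector converges to the single-point
force as the target recedes, and is shorter for close targets (the wrap of
directions is the point of distributing the load). By default the
cranium-side (origin) site is loaded toward the mandible-side centroid;
`load_side: insertion` flips this for mandible-loading workflows. The
depressor (mDM) is included in the maximal-activation load set by default
(`include_mDM: false` excludes it), consistent with co-contraction during
crushing bites.

### Reaction statics

The cranium is treated as a rigid body on three point supports: the two jaw
joints and the bite point, each providing a reaction force but no moment.
Static equilibrium gives 6 equations in 9 unknowns; the package returns the
minimum-norm solution (Moore–Penrose pseudoinverse of the 6×9 equilibrium
matrix, assembled about the support centroid for conditioning). The
minimum-norm rule is the package's resolution of the 3-fold indeterminacy: a
stiff, quasi-rigid skull distributes load close to the equilibrium-optimal
pattern, no muscle-activation or elasticity model is needed, and the choice
is transparent and pluggable — an elastic or finite-element backend could
replace `solve_reactions` without touching the rest of the pipeline. Note
one behavioral consequence: a load applied exactly at a support is *not*
simply opposed there if sharing it lowers the summed squared reactions.

Sign convention: reactions act on the cranium, so with muscles pulling the
cranium toward the mandible the joint reactions point dorsally, and pure
axial compression of the quadrate yields a dot product of +1 with the
ventral→dorsal structural axis. Reactions below 1e-9 of the total applied
load are flagged orientation-unstable rather than normalized. Bite-force
direction is not pre-constrained; it emerges from equilibrium.

### Similarity statistics

Correspondence is cos θ = v̂_Q · v̂_JRF. Null directions are normalized iid
standard Gaussian triples — uniform on the sphere by rotational symmetry —
seeded and of size 1350 by default. Three tests:

- **Per individual:** the fraction of null directions whose dot with the
  quadrate axis is ≥ the observed dot (ties count against the hypothesis).
- **Per sample:** draw `m` random vector *pairs* (sample size matched to the
  data) 10,000 times from the null population; the empirical p is
  (k+1)/(N+1) with k = number of resample means ≥ the observed mean. The
  add-one estimator never returns 0 and floors at 0.0001 for N = 10,000.
- **Across bite positions:** a two-sided F-test on dot-product sample
  variances, larger variance in the numerator and its group labeled. Sides
  (working + balancing) are pooled within a bite position by default;
  `pool_sides_in_variance_test: false` tests each side separately.

### Phylogenetic regression

Under Brownian motion the trait covariance of two tips is their shared
root-to-MRCA path length. Each JRF unit-vector component is regressed on the
matching quadrate-axis component by GLS with that covariance (Cholesky
whitening), independently per component × side × bite position, with
slope t-tests on n−2 df and no multiple-testing correction. With C ∝ I this
reduces to OLS to machine precision. On ultrametric trees the estimates,
standard errors, t and p match R's `nlme::gls` with a Brownian correlation
structure to 12 digits (frozen cross-check in the test suite); on
non-ultrametric trees the package uses the full covariance, whereas a
correlation-structure parameterization would equalize tip variances — the
covariance form is the Brownian model. Only σ² differs by the tree-depth
scale factor. Pagel's λ and other transforms are out of scope (the solver is
an extension point).

Ancestral states are maximum-likelihood Brownian estimates, computed by
solving the branch-conductance (1/length) Laplacian system — weighted
squared-change parsimony, whose optimum coincides with the ML states for a
Gaussian process. Values match `phytools::fastAnc` (frozen cross-check).
Zero-length branches are guarded with a 1e-12 floor. Pearson correlations of
internal-node states summarize coordinated evolution.

## Synthetic data: what it emulates, and what it does not

`make_specimen` builds a skull from a flattening parameter φ ∈ [0, 1]:
the quadrate axis starts dorsoventral (0, 1, 0) and, as φ grows, tilts up to
50° rostrally in the sagittal plane and 25° medially in the transverse
plane (both smooth, monotone maps); the rostral bite point migrates slightly
forward. Joints sit at ±half the jaw width; bite points at the tooth row,
rostral ≈ 0.65–0.75 and caudal ≈ 0.18 of skull length ahead of the joints.
Default scale (skull length 300 mm, jaw width 160 mm, quadrate 45 mm) is an
adult-alligator-sized skull. Attachment patches are small planar quads, so
areas and centroids are closed-form; per-muscle areas (90–300 mm², the
pterygoideus complex largest) and insertion positions are fixed fractions of
skull size. All 16 muscle-sides share one pull direction per side: the
quadrate axis rotated by exactly δ (default 20°, chosen so rostral-bite dot
products land near 0.94 ≈ cos 20°) within the plane spanned by the axis and
the rostrocaudal direction. This makes the muscle-resultant-vs-axis angle
exactly δ by construction — a deliberate simplification that gives every
downstream stage a known truth to recover.

`make_clade` draws a pure-birth tree (dendropy), ages it by one extra
waiting time so the youngest terminal branches are not zero-length (which
would make the Brownian covariance singular), rescales it to unit depth, and
evolves φ by Brownian motion (sd 0.35 per unit depth, reflected into
[0, 1], root 0.15 — an early-suchian-like tall-skulled ancestor radiating
toward flatter forms). Default clade size is 11 taxa. All randomness flows
from one integer seed through spawned substreams; written specimens are
byte-identical under the same seed.

What the generator does **not** emulate: real attachment sites are curved,
irregular, and partly overlapping; real muscles differ in direction (the
pterygoideus complex is much more oblique than the external adductors); the
depressor opposes the adductors rather than joining them; skulls are not
bilaterally exact; and landmark placement carries measurement error. Passing
tests therefore demonstrate that the machinery is correct and that the
expected qualitative mechanics (caudal bites: higher bite force, weaker and
more variable working-side JRF) emerge from the geometry — not that any
particular empirical effect size in real suchians is reproduced. Tree shape
and branch-length calibration strongly affect PGLS p-values, so results on
real data require the user's own time-calibrated tree.

## Numerical choices

- Equilibrium is assembled about the support centroid; residuals are
  reported and verified ≤ 1e-9 of the applied load (and load × lever scale).
- Collinear supports raise a singular-configuration error (cross-product
  test at 1e-12 relative).
- acos inputs are clamped at ±1 with a 1e-12 overshoot tolerance.
- Unit-vector contracts are enforced at 1e-6; normalization itself is exact
  to 1e-12.
- CSV floats are written at 12 significant digits, making reruns
  byte-identical on a platform.
- Duplicate mesh vertices are *not* merged on load (STL triangle soup keeps
  its per-face vertices), preserving node counts for load distribution; an
  explicit tolerance-based merge is available.

## Problem sizes used in the checks

The shipped test suite and `scripts/acceptance.py` run on an 11-taxon
synthetic clade (16 muscle-sides × 8 vertices of distributed load per
specimen), a 1350-direction null, 1000–10,000 resamples, and 200-replicate
PGLS recovery at 32 tips — sizes chosen so the full suite completes in a few
seconds while leaving the statistical assertions comfortable margins.

## Known limitations

- Rigid-body minimum-norm statics ignores elasticity, sutures, and joint
  cartilage; absolute reaction magnitudes on compliant skulls will differ
  from finite-element estimates, though resultant directions are dominated
  by equilibrium.
- Reactions are point forces; no reaction moments, no articular surface
  pressure distribution.
- PGLS assumes Brownian residuals with a user-supplied tree; no λ/OU
  transforms, no multivariate (vector-response) regression.
- The similarity tests treat each specimen-side-bite as one observation;
  working and balancing sides of one bite share a solution and are not
  independent — the per-sample resampling test matches the sample size but
  not this dependence structure.
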