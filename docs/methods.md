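# Methods

## Data model and conventions

All coordinates are continuous nanometres with the origin at the image
top-left corner and y increasing downward; pixel index *i* maps to nm
coordinate (*i* + 0.5) × scale. Distances are Euclidean between particle
centres; the nominal 5/10 nm gold diameter is a categorical label and
never enters distance computation. A particle whose centre lies exactly
on the region-of-interest boundary counts as inside (point-in-polygon
with closed boundary); profile areas are shoelace areas of the polygon.
Membrane profiles carry a compartment label (soma, apical dendrite,
oblique dendrite, spine, axon terminal, active zone, extrasynaptic,
E-face background) because inference is summarised per compartment.

Particles belonging to clusters that are later discarded (fewer than 3
members) remain in every NND and density analysis; the discard rule
applies to clusters, not particles.

## Detection

Detection is two-stage. Stage 1 runs a circular Hough transform
(scikit-image, on a Canny edge map, σ = 1 px) over integer radii within
±20% of the nominal particle radius, followed by non-maximum suppression
at one radius (ties broken by score, then lower y, then lower x).
Automated detection refuses targets spanning < 4 px diameter, where the
Hough accumulator is unreliable; such particles (5 nm gold at coarse
scales) are imported from clicked coordinates instead, with only the
refinement step applied.

Stage 2 scores each candidate with a Gaussian Naive Bayes classifier
over six features: interior mean intensity, interior SD, ring contrast
(annulus mean − interior mean, annulus from r to 2r), mean radial
intensity step across the boundary, circularity (4πA/P²) of the blob
thresholded at the interior/annulus midpoint, and annulus SD. The
feature set is this package's choice; the model class (Naive Bayes) is
the method's stated default, and a differently trained model can be
loaded from JSON. Per-feature variances are floored at 10⁻⁶ × the
feature's variance over all training data to avoid degenerate
likelihoods. Candidates with particle posterior ≥ 0.5 are kept,
carrying the posterior as their confidence.

Accepted detections are refined to the intensity-weighted centroid of a
disk of radius r + 2 px, with intensities inverted about the local
maximum so dark particle pixels dominate and flat regions produce no
motion; displacement is capped at one radius. A final suppression pass
guarantees no two emitted particles are closer than the 10 nm physical
hard core (higher confidence wins).

## Spatial statistics

Intra-type NND excludes the particle itself; inter-type NND is
directional (from each particle of one class to the nearest of the
other). Estimators are deliberately uncorrected for edge effects — the
workflow's convention; toroidal variants exist for
self-tests only, where CSR closed forms hold (mean NND → 1/(2√λ),
K(r) → πr²).

The clustering threshold is mean + 2 × sample SD (n − 1 denominator) of
the intra-type NNDs, computed **per image and per size class** — the
only scope computable at analysis time, and the one consistent with the
per-image simulation design. The alternative rules (mean, mean + 1 SD,
fixed global threshold) are selectable. Single-linkage clusters are the
connected components of the graph joining particle pairs at distance ≤
threshold (implemented by cutting a SciPy single-linkage dendrogram,
verified against brute-force connected components); components with
fewer than 3 members are discarded. Cluster area is the convex-hull
area (0 for collinear members); inter-cluster distance defaults to
minimum member-to-member distance — consistent with single-linkage
geometry — with a centroid-to-centroid option, since no single convention
exists for a cluster-pair distance.

## Null models

**Random simulation** removes all particles of one size class and
redistributes the same number uniformly over the ROI (rejection sampling
from the bounding box, giving every interior location equal
probability), rejecting any position closer than the hard core
(10 nm, centre-to-centre) to any fixed real particle of the other class
or any already-placed simulated particle. The hard core is read centre-to-centre; an edge-to-edge reading would
depend on particle radii, which the exclusion rule does not invoke. Placement failure after 10⁶ proposals is a
packing-infeasibility error, never silent.

**Fitted simulation** starts from a random simulation and repeatedly
picks a uniformly random simulated particle, proposes a fresh valid
location, and keeps the move iff the two-sample KS p-value between all
real–real and all sim–sim intra-type pairwise distances does not
decrease (ties kept), stopping when p ≥ 0.1. The pairwise distance sets
are not i.i.d. samples; the KS p here is a similarity score, used
exactly as the procedure defines it, with the plain asymptotic
two-sample formula p = K(√(mn/(m+n))·D). Since that p is monotone in D
for fixed sample sizes, the inner loop compares D directly and the
sorted sim-distance array is maintained incrementally (a move changes
only the k − 1 distances involving the moved particle), which is what
makes ensembles of hundreds of fitted simulations per image practical.
The iteration cap (default 10⁴ proposed moves) and the explicit
non-convergence error carrying the best p reached are this package's
policy: convergence failure is loud, never a silent fallback.
Ensembles retry a non-convergent simulation up to 3 times with fresh
sub-seeds before excluding (and counting) the image.

Ensembles are pure functions of (image, parameters, seed); per-sim
seeds are seed + sim index. For inter-type analyses only the 5 nm class
is resimulated and the NND is measured from simulated 5 nm to real
10 nm particles: the inter-type question is where the resimulated
molecule sits relative to the fixed one.

## Inference

Per image: rank p-values with the (k+1)/(n+1) convention, ties counted
on both sides (conservative). Association iff p_low ≤ α/2, dissociation
iff p_high ≤ α/2 (α = 0.05); ensembles of < 40 simulations are rejected
because the 2.5% tail is unresolvable. Per compartment: two-sided
paired t test on (real mean NND, mean of that image's simulated mean
NNDs) pairs — the pairs are only approximately independent, a known
caveat of this design that is documented here rather than "fixed" —
followed by step-down Holm–Bonferroni over the set of
compartment tests performed in one run. Zero-variance differences are
reported as p = 1 with a degeneracy flag. Density gradients use
Kruskal–Wallis, pairwise Mann–Whitney U (exact null for groups ≤ 8,
normal approximation above) and Dunn's rank-based z tests; pairing the
two is a matter of convention, so both pairwise columns
are reported side by side, each Holm-adjusted across the pairwise
family.

## Synthetic data

The generator emulates the labelling regimes the analyses assume, not
replica physics. Point patterns live in a 1000 × 1000 nm (1 μm²)
rectangular profile by default — typical of the analysed membrane
profiles — with a 10 nm hard core enforced by rejection everywhere.

- *csr / bivariate_independent*: per class, Poisson(intensity × area)
  particles, default intensity 50 μm⁻² per class (mid-range of reported
  compartment densities, tens to a few hundred per μm²).
- *clustered*: Thomas-style process — parents uniform (default 8),
  children Poisson(6) truncated ≥ 1 per parent, isotropic Gaussian
  dispersion SD 15 nm. These defaults put roughly three quarters of
  recovered clusters in the 3–8-particle range, the regime reported
  for receptor clusters in replica labelling.
- *bivariate_coclustered*: both classes share parents; the second
  class's cluster centres can be displaced by a fixed offset (default
  0 nm) in a random direction.
- *bivariate_segregated*: disjoint parent sets, with class-2 parents
  excluded from within `segregation_inhibition_nm` of every class-1
  parent. The floor 4 × dispersion only prevents cluster overlap; at
  that distance cross-class cluster centres are no closer than under
  random placement (typical nearest cross-parent distance
  ≈ 0.5/√(n/A) ≈ 180 nm at the defaults), i.e. the pattern is not
  operationally segregated. The default is therefore 150 nm, chosen so
  the exclusion bites against random placement while leaving the
  rejection sampler feasible (~57% of the profile excluded).

The Thomas process is a test harness, not a biological claim: it
reproduces aggregation, co-aggregation and segregation with known
ground truth, but not anisotropy, membrane curvature effects, antibody
labelling efficiency, or replica shadowing artefacts — so passing tests
demonstrate correctness of the estimators and inference under the
stated point-process conditions, not performance on any particular
tissue.

The renderer draws dark sigmoid-edged disks (depth 0.45, edge softness
0.8 px) on a mid-grey background (0.6) with smooth correlated texture
(SD 0.05, ≈3 px correlation) plus per-pixel noise (SD 0.03) — the
reference noise level of the detection fixtures — and adds elongated
dark Gaussian blobs as classifier negatives. Fidelity beyond what
detection tests need is a non-goal.

## Validation problem sizes

The acceptance checks run the pipeline at these sizes: 400 independent
bivariate images × 199 random simulations for null calibration (199
gives an exactly calibrated (k+1)/(n+1) test at α = 0.05); 30
co-clustered and 30 segregated images × 99 fitted simulations for the
power checks (the per-image tail remains resolvable at 99); 1000 random
instances for the clustering oracle; 50 clustered patterns for the
fitted-simulation contract; 200/100 seeds for the CSR closed forms; and
a 12-image rendered suite for detection. Production defaults remain 500
simulations per image.

## Known limitations

- The shipped classifier instantiation is trained on rendered
  fixtures; for real replicas it should be retrained on candidates
  labelled from that imaging setup (the JSON model format supports
  this).
- Naive (uncorrected) NND and K estimators are biased near profile
  boundaries; this mirrors the reproduced procedure.
- The fitted-simulation KS criterion treats dependent pairwise
  distances as a sample; its p-values are scores, not calibrated tail
  probabilities.
- The clustering threshold is data-driven per image by default; a
  global fixed threshold is available when cross-image comparability
  of cluster definitions matters more than per-image adaptivity.
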