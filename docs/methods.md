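# Methods

`smlmfuse` fuses many sparsely labeled copies of one macromolecular
structure, imaged by 3D single-molecule localization microscopy (SMLM), into
a single high-signal "super-particle", detects the structure's rotational
symmetry group from the registration residuals, and quantifies the result.
This note records the model, the algorithmic choices, and their limits.

## Problem setting and model

Each particle is a cloud of localizations `x = R(s + ε) + t`, where `s` is
one of K ground-truth binding-site positions, `ε` is anisotropic Gaussian
localization noise with per-localization covariance
diag(σ_lat², σ_lat², σ_ax²) (axial precision 2–4× worse than lateral;
default factor 3), and (R, t) is the particle's unknown rigid pose.
Underlabeling is the dominant nuisance: each site carries a fluorophore only
with probability DOL (degree of labeling), so two particles share only a
random subset of sites.

Conventions used throughout: right-handed axes, z along the optical axis,
transforms act as x' = Rx + t, lengths in nm. The pose `M_i` maps the common
(template) frame onto particle i, so relative transforms recompose as
`M_ij = M_j ∘ M_i⁻¹` and alignment into the common frame applies `M_i⁻¹`.
Absolute poses are defined up to one global rigid motion (gauge); the
averaging stage fixes the gauge to particle 0, and the final pipeline
re-gauges the common frame so that the structure's symmetry axis lies on z
and its centroid at the origin. The axis itself is not taken from the
moment analysis (for the NPC the axial and in-plane covariance eigenvalues
differ by only ~10%, so the principal axes are unstable); instead it is read
exactly off the consistency records: a symmetry-branch mismatch gives
S_ij = R̂_j G R̂_j⁻¹, so back-rotating each record's rotation axis by the
second particle's pose maps it onto the common-frame symmetry axis, whose
spherical density maximum is used.

## Pairwise registration

Each cloud is an isotropic Gaussian mixture with one component per
localization and a common width (the "scale"). Registration minimizes the
L2 distance between the two mixtures, which reduces to maximizing the
Gaussian cross-correlation Σ_pq exp(−‖Ra_p + t − b_q‖²/4σ²); this objective
has closed-form gradients on the (rotation-vector, translation) chart and is
robust to non-matching points. Multi-start optimization covers SO(3) with a
deterministic super-Fibonacci quaternion grid (default n = 576 for
standalone use; the pipeline default is n = 48, which recovers exact
transforms on all built-in models); every start is first optimized at a
coarse scale (1/8 of the joint extent, so each start reaches its basin
across the whole structure) and the best few candidates are refined at the
fine scale. Scale selection is automatic: the median nearest-neighbor
distance pooled over both clouds, clamped to [2, 30] nm — shape-driven, as
the scale should be.

Candidates are ranked by an anisotropic Bhattacharyya overlap score: every
localization is a Gaussian with its own covariance (rotated with its
particle), and the score sums the pairwise Bhattacharyya coefficients of all
cross-cloud component pairs. This is where the 3× axial/lateral anisotropy
enters. A Bhattacharyya-refinement stage (continuing the optimization on the
Bhattacharyya objective itself) is deliberately not performed: it is
computationally demanding for little gain.

The GMM kernel is JIT-compiled with numba when available, with an identical
NumPy fallback.

## Robust pose averaging on SE(3)

The N(N−1)/2 relative poses are averaged into N absolute poses in the Lie
algebra se(3): residuals `log(M_j⁻¹ M_ij M_i)` are driven to zero by
iteratively re-weighted least squares with Weiszfeld (1/‖r‖) weights,
approximating an L1 objective that tolerates erroneous registrations.
Initialization is a maximum-score spanning tree; translations (nm) and
rotations (rad) are balanced by a length scale defaulting to the median
relative-translation magnitude (floored at 1 nm). Pairs whose residual
rotation reaches the π cut locus are excluded from each update (log-branch
ambiguity). Plain least squares (`l2_average`) is kept as the non-robust
comparator.

Consistency checking compares measured and recomputed rotations through
S_ij = R_ij (R̂_ij)⁻¹ with trace(S) = 1 + 2cos ψ; pairs with 3 − trace > ε
(empirical ε = 0.5) are pruned, and if pruning disconnects the registration
graph the lowest-deviation masked edges are restored per component. The
threshold acts on the trace deviation ("distance from the peak at 3"); an
angle threshold would be equivalent through ψ = arccos((trace−1)/2). Two
alternating rounds of averaging/pruning produce the data-driven template
poses and the consistency records used for symmetry detection.

## Symmetry detection

For an n-fold symmetric structure any branch `S̄_k` of the cyclic group is a
valid registration, so the S_ij cluster near group elements and their traces
pile up at 1 + 2cos(2πk/n). Detection builds a KDE of the traces (Silverman
bandwidth clamped to [0.05, 0.12] — the trace distribution is strongly
multimodal, where Silverman's unimodal rule oversmooths), finds its peaks,
and scores each candidate fold n ∈ {2..12} by a symmetric set mismatch:
mean distance from expected to nearest detected peak (weighted double — a
missing expected peak is strong negative evidence) plus mean distance from
detected to nearest expected peak. Folds are selected greedily until every
non-identity peak is explained, so compound groups (a tetrahedron's C2 ∪ C3)
are reported as multiple folds. Axes come from the antisymmetric part of
S_ij (with a half-turn fallback to the +1 eigenvector), pooled on the
projective sphere with a Watson kernel whose concentration is chosen by
leave-one-out likelihood from a small ladder; density maxima are refined to
the principal axis of their supporting points.

Symmetry promotion folds each measured pose onto the identity branch by
dividing out the nearest group element (conjugated into the particle's frame
about the structure center when pose estimates are available), which turns
branch-scattered pairs into consistent ones and can only increase the kept
count.

## The pseudo-mirror failure mode and overlap-driven refinement

A two-ring structure like the NPC is *nearly* dihedral: an upside-down
registration of a sparsely labeled particle often scores almost as well as
the correct one, and because two flips compose to an in-group rotation these
errors are mutually coherent — robust averaging can settle into two
internally consistent camps of mutually flipped particles, a state that
pairwise registration scores alone genuinely support (it explains the
pairwise evidence at least as well as the correct state). The NPC model
places the two Nup107 copies of each spoke on concentric circles (49.7 and
42.7 nm, the stacked Y-complex arrangement); with a single circle the model
would be exactly dihedral and up/down recovery impossible in principle.
Even so, labeling fluctuations at DOL ≈ 0.5 leave a substantial per-pair
flip rate.

What does arbitrate is the total Bhattacharyya overlap between *aligned
particles*: a particle flipped relative to the majority overlaps the
majority poorly, so the mixed state scores strictly lower than the
single-camp state on this objective even though their pairwise registration
scores are comparable. After averaging, the pipeline therefore runs a
greedy overlap-driven refinement: each particle in turn is re-registered
against the template of all others (full rotation grid, plus its current
pose composed with locally polished half turns about a fan of in-plane
axes, so the opposite-orientation hypothesis is always on the table), and a
candidate pose is accepted only if the particle's summed overlap with the
rest increases. A 50/50 camp split is unstable under this dynamics — any
accepted move grows one camp and the gain snowballs — so the refinement
converges to a single-camp solution. Bootstrapping additionally keeps
half-turn warm starts so a residual upside-down particle can still cross
back later. A deferral-based progressive template builder
(`progressive_alignment`) is available as an alternative robust
initializer.

At DOL 0.5 a few particles per dataset can remain genuinely ambiguous:
their localizations overlap the fused structure better upside down than
upright, under any data-driven criterion. Such particles either stay
flipped (raising the site-correspondence error) or are caught by the
outlier stage; this is an information limit of underlabeled near-dihedral
data, not an optimization failure.

## Bootstrapping and the hotspot fix

Five (default; 3–5 sensible) rounds: build the super-particle from current
poses, uniformly subsample it to at most the resample target (default 5000;
density-equalizing subsampling is available behind a flag), and re-register
every particle to this template, warm-started from its pose with a local
rotation grid (32 rotations within 30°), plus all symmetry-group elements
and the in-plane half turns, all acting about the aligned particle's
centroid. A failing re-registration keeps the previous pose. With a known
or detected C_n group, each round first adds a uniform random multiple of
2π/n about the symmetry axis to every particle's alignment: over rounds this
balances the localization load over the n sectors and removes the
self-reinforcing hotspot artifact of under-labeled symmetric structures
(the final reconstruction is not symmetrized — the group is only used to
randomize branch choice). The whole bootstrap is reproducible from one seed.

## Outlier particles

After bootstrapping, the N×N matrix of pairwise Bhattacharyya overlaps
between aligned particles is summed along rows to one quality score per
particle; particles more than 3 scaled MADs (×1.4826, with a tiny floor
against the all-equal degeneracy) *below* the median are flagged. The rule
is one-sided: bad particles form the extended low tail, and unusually high
overlap is not a defect. The super-particle is rebuilt without flagged
particles; poses are not re-estimated (single pass).

## Evaluation

* **Registration error** (simulation only): mean over particle pairs of the
  minimum RMS distance between ground-truth sites mapped through the
  estimated poses, minimized over cyclic site correspondences — per ring
  with a common shift for the NPC's two rings (a C8 rotation is an index
  shift of 2 in each 16-site ring), identity plus supplied permutations for
  non-cyclic models. Sites, not localizations, so localization noise does
  not contaminate the measure. Success means error < 25 nm (the NPC
  subunit spacing); a high-quality reconstruction is < 10 nm.
* **FSC resolution**: localizations are split in two halves by whole
  particle of origin (repeat localizations of one site in one particle are
  correlated and must not straddle the split), each half is binned at 2 nm
  voxels and blurred with the mean lateral/axial σ, and the resolution is
  the inverse frequency where the shell correlation crosses 1/7 (½-bit is
  not implemented). A curve that never crosses is reported as
  Nyquist-limited (2 × voxel).
* **NPC structural parameters**, after moment alignment (principal axes of
  the localization covariance; the smallest-spread axis — the symmetry axis
  of a structure wider than tall — goes to z): ring distance as the peak
  separation of the 4-nm-bandwidth KDE of z; ring radii as the per-half
  radial KDE peaks after splitting at the z-density local minimum; angular
  shift by fitting b0 + b1 sin(8θ + b2) per ring (fine angular histogram,
  symmetric circular smoothing that leaves the harmonic phase unbiased,
  iterative least squares seeded by the exact 8th circular moment) and
  converting Δb2/8 to degrees, wrapped to (−22.5°, 22.5°]. With the default
  model the radial density of the two concentric site circles merges into a
  single peak at their mean (46.2 nm), which is what the radius estimator
  reports.
* **Tilt distribution**: the angle between each pose-rotated z axis and z.

## Simulator

Ground-truth models: the 2 × 16-site Nup107 NPC (eight azimuthal pairs per
ring, 12° pair split, outer/inner radii 49.7/42.7 nm, height 59 nm, 13°
inter-ring shift, exact C8); a regular dodecahedron (20 vertices, minimum
site distance 30.9 nm); a 20-site "building" box frame (20 × 100 × 60 nm);
and an asymmetric "ring-square" (8-point square plus an offset 8-point ring
tilted 26.6° from horizontal).

Per particle: sites label independently with probability DOL; PAINT draws
Poisson localization counts per labeled site; STORM draws
Geometric(p_bleach) blinks with 1 + Poisson(μ_on) localizations each, with
p_bleach solved (μ_on default 0.5) to match the requested mean count — same
mean as PAINT, heavier per-site dispersion, which is what distinguishes the
two kinetics here. σ_lat is Gamma-distributed (CV 0.3, configurable to
constant) around its mean; σ_ax = 3σ_lat exactly. Poses: uniform azimuth
about z, tilt uniform within ±36° (default) about a random in-plane axis,
or fully random orientation; translation jitter ±10 nm per axis
(segmentation centering error). Particles with no active site are resampled
by the dataset generator. What the simulator does *not* emulate: camera
image formation and multi-emitter fitting, drift, site-dependent labeling
efficiency, and background localizations (except as test fixtures), so
passing tests bound algorithmic performance under the stated noise model,
not under every experimental pathology.

## Problem sizes and numerical choices

The bundled end-to-end checks run one seeded 30-particle dataset per
condition with a 48-rotation grid, 3 bootstrap rounds and a 2000-point
resample target — the same pipeline as a full study (which would average
many datasets of 100 particles each) at a workstation-friendly size.
Optimizer: L-BFGS-B, gradient tolerance 1e−8, 100 iterations (12 coarse).
Degenerate inputs are handled explicitly: empty particles are resampled,
zero-MAD score sets flag nothing, near-isotropic clouds make moment
alignment warn (and the pipeline skip re-gauging), identity-like
consistency matrices have indeterminate axes and are excluded from axis
density.

## Known limitations

* Pairwise orientation of near-dihedral structures at low DOL is
  information-limited; the progressive template resolves the global
  assignment, but individual pathological particles can remain flipped and
  are then caught (if at all) by the outlier stage.
* Fold detection needs enough consistency records (≥ 50 recommended) and
  distinct trace peaks; folds sharing all peak positions with a compound of
  smaller folds can be ranked below them in adversarial cases.
* The angular-shift fit assumes both rings carry a clear 8θ modulation
  (b1 bounded away from 0).
* FSC on localization data depends on the rendering blur; values are
  comparable within one rendering convention only.
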