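# smlmfuse

Template-free 3D particle fusion and symmetry detection for single-molecule
localization microscopy (SMLM).

SMLM produces point clouds of fluorophore localizations, but any single copy
of a macromolecular structure is incompletely labeled: at a degree of
labeling (DOL) of 50%, half the binding sites are simply missing. When a
sample contains many identical copies ("particles"), fusing them into one
**super-particle** restores the missing information and boosts
signal-to-noise by orders of magnitude. `smlmfuse` implements such a fusion
pipeline for 3D localization data with anisotropic uncertainties (axial
precision 2–4× worse than lateral), without requiring a structural template,
and additionally reads the structure's rotational symmetry group directly
off the registration residuals.

## Method

For N particles, all N(N−1)/2 pairs are registered rigidly: each cloud is an
isotropic Gaussian mixture (one component per localization) and the L2
distance between the mixtures is minimized from many rotational starts
covering SO(3); candidates are ranked by an anisotropic Bhattacharyya
overlap that accounts for each localization's covariance
diag(σ_lat², σ_lat², σ_ax²). The relative poses M_ij are then averaged into
absolute poses M_i by robust (L1, Weiszfeld-reweighted) averaging in the Lie
algebra se(3), relative transforms are recomputed as M̂_ij = M_j M_i⁻¹, and
pairs whose consistency matrix

    S_ij = R_ij (R̂_ij)⁻¹,   trace(S_ij) = 1 + 2 cos ψ_ij

deviates from trace 3 by more than ε = 0.5 are pruned; the loop is iterated.
For an n-fold symmetric structure the traces pile up at 1 + 2cos(2πk/n)
(e.g. {3, 1+√2, 1, 1−√2, −1} for C8), so the histogram of trace(S_ij)
identifies the fold and the rotation axes of the S_ij identify the symmetry
axes — this is how the NPC's 8-fold symmetry is detected from data alone.
Finally every particle is re-registered to density-resampled versions of the
data-driven template for several bootstrap rounds (with random symmetry
rotations per round to avoid hotspot artifacts), and outlier particles are
flagged by a scaled-MAD rule on mutual overlap scores.

A built-in simulator provides the benchmark structures (the 2×16-site Nup107
NPC model with a 13° inter-ring shift, a dodecahedron, a "building", and an
asymmetric "ring-square") with PAINT or STORM blinking statistics, and the
evaluation module computes the ground-truth registration error (mean
pairwise RMS site distance, minimized over cyclic site correspondences), FSC
resolution, and NPC structural parameters (ring distance, radii, inter-ring
phase shift). See `docs/methods.md` for the full model description and
design choices.

## Worked example

```python
from smlmfuse.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(model="npc", mode="PAINT", dol=0.5, sigma_lat_mean=3.0,
                     n_particles=30, seed=21, grid_n=48,
                     bootstrap_rounds=3, resample_target=2000)
result = run_pipeline(cfg)
print("error [nm]:", round(result.registration_error, 1))
print("detected folds:", result.symmetry_report.folds)
```

which prints (one seeded 30-particle PAINT dataset, DOL 50%, σ_lat 3 nm):

```
error [nm]: 2.5
detected folds: [8]
```

i.e. the fused reconstruction places the ground-truth binding sites to
within ~3 nm — well below the ~25 nm success threshold set by the spacing of
the NPC's 8-fold subunits — and the 8-fold rotational symmetry is recovered
from the consistency records without prior knowledge. The same run with
STORM kinetics at σ_lat = 13 nm fails (error well above 20 nm), reproducing
the method's sensitivity to localization precision.

The same pipeline is available from the shell:

```bash
smlmfuse simulate --model npc --n-particles 30 --seed 1 --out particles.csv
smlmfuse fuse particles.csv --out-prefix run1
smlmfuse evaluate run1_superparticle.csv
smlmfuse run --seed 1 --dry-run
```

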