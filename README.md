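# acmap

White-matter group studies on diffusion MRI usually compare voxel-local
microstructure indices — fractional anisotropy (FA), mean, radial and
axial diffusivity (MD, RD, AD) from the diffusion tensor model.  These
indices cannot see *connectedness*: a focal lesion that disrupts a
pathway changes FA only where the tissue itself is altered, while its
consequences propagate along the whole tract.  **Anatomical Connectivity
Mapping (ACM)** captures that propagation: seed probabilistic
streamlines in *every* brain-mask voxel, then count, per voxel, how many
streamlines pass through it.  The resulting map reflects each voxel's
participation in the global pathway system and can reveal tract-wide
alterations that voxel-local indices miss.

`acmap` implements the complete analysis chain in Python:

- **DTI fitting** — log-linear and nonlinear least squares for
  `S(g,b) = S0 · exp(−b gᵀDg)`, with the standard scalars
  MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2 and
  FA = √(3/2) · ‖λ − MD‖ / ‖λ‖.
- **Probabilistic tractography** — bidirectional Euler streamlines
  (default 500 per voxel, 2000 steps, 0.5 mm step, curvature-cosine
  threshold 0.2) with per-voxel fibre orientation distributions modelled
  as Watson densities `f(x) ∝ exp(κ (μᵀx)²)`, supporting crossing-fibre
  voxels with several compartments.
- **ACM** — unique-visitation streamline counting inside the brain mask.
- **Group statistics** — Gaussian smoothing (4 mm FWHM), voxel-wise GLM
  (group + age, gender, brain-mask voxel count), threshold-free cluster
  enhancement `TFCE(v) = Σ_h extent(v,h)^E · h^H · dh` (E = 0.5, H = 2),
  family-wise error control by the Freedman–Lane permutation
  distribution of the image-wide maximum, tract-specific small-volume
  correction, a Lilliefors residual-normality screen, and an ACM-vs-ICV
  correlation check.
- **Synthetic phantoms** — tube-tract DWI phantoms with Rician noise and
  cohorts carrying a focal radial-diffusivity lesion, so the whole chain
  is testable end to end without any acquisition.

## Worked example

```python
import numpy as np
from acmap import synthetic, dti, tracking, acm

# a 16x8x8 voxel phantom (2 mm isotropic) with one straight tract,
# imaged with 30 directions at b = 1500 s/mm^2 + 4 b=0 volumes, SNR 20
scheme = synthetic.make_gradient_scheme(n_directions=30, b_value=1500, n_b0=4, seed=1)
spec = synthetic.default_tube_phantom_spec()
dwi, mask, truth, rois = synthetic.build_phantom(spec, seed=0, scheme=scheme)

tensors = dti.fit_tensor_lls(dwi, scheme, mask)
scalars = dti.tensor_scalars(tensors)
tube = rois["tube_0"].data
print(f"mean FA inside tract: {scalars['FA'].data[tube].mean():.3f}")
print(f"mean FA in background: {scalars['FA'].data[~tube].mean():.3f}")

model = tracking.OrientationModel.from_tensor(tensors)
params = tracking.TrackingParams(n_per_voxel=20, seed=7)
streamlines = tracking.whole_brain_tracking(model, mask, params)
print(f"streamlines: {len(streamlines)} from {mask.n_voxels} seed voxels")

cmap = acm.acm_from_streamlines(streamlines, mask)
print(f"ACM floor (min over mask): {cmap.data[mask.data].min()}")
```

prints

```
mean FA inside tract: 0.797
mean FA in background: 0.104
streamlines: 20480 from 1024 seed voxels
ACM floor (min over mask): 28
```

The tract voxels recover the ground-truth FA of ≈ 0.80 (eigenvalues
1.7/0.3/0.3 × 10⁻³ mm²/s) against an isotropic background; each of the
1024 mask voxels seeds 20 streamlines, and because a voxel's own seeds
always traverse it, no masked voxel can fall below 20 counts — here the
minimum is 28, the excess coming from streamlines seeded elsewhere.

The same stages are available from the shell:

```bash
acmap fit-dti --dwi dwi.nii.gz --bval d.bval --bvec d.bvec --mask mask.nii.gz --out-dir dti/
acmap track   --dwi dwi.nii.gz --bval d.bval --bvec d.bvec --mask mask.nii.gz \
              --n-per-voxel 500 --seed 1 --out tracks.tck
acmap acm     --tracks tracks.tck --mask mask.nii.gz --out acm.nii.gz
acmap group-stats --maps maps.csv --design design.csv --contrast "NS>CB" \
              --n-perm 5000 --fwhm 4 --svc lesion_roi.nii.gz --seed 1 --out-dir stats/
```

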