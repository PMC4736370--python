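# Methods

## Signal model and tensor fitting

Each voxel's diffusion-weighted signal follows the multi-tensor forward
model

    S(g, b) = S0 · [ Σ_c f_c · exp(−b gᵀ D_c g) + f_iso · exp(−b d_iso) ],

where each fibre compartment `c` is axially symmetric (eigenvalues
λ∥ ≥ λ⊥ > 0 about a unit orientation μ), fractions sum to at most 1, and
the remainder is isotropic with diffusivity `d_iso` (default
0.8 × 10⁻³ mm²/s, a typical parenchyma value).  White-matter
compartments default to λ∥ = 1.7 × 10⁻³, λ⊥ = 0.3 × 10⁻³ mm²/s,
giving single-fibre FA ≈ 0.80.

Fitting inverts the single-tensor special case.  The log-linear (LLS)
fit solves `log S = log S0 − b gᵀDg` by least squares per voxel,
excluding non-positive samples and flagging voxels with fewer than
seven usable samples as invalid.  The nonlinear (NLS) fit minimises the
untransformed residual `Σ (S_obs − S0 e^{−b gᵀDg})²` with a
Levenberg–Marquardt trust-region step (analytic Jacobian, ftol 1e-10,
at most 100 iterations per parameter), initialised from the LLS
solution and falling back to it on non-convergence.  NLS implicitly
weights high-signal samples more and is measurably more accurate under
Rician noise: at SNR 20 its FA mean absolute error is ≈ 78% of the LLS
error (replicate simulation, 500 voxels × 8 anisotropy levels).  For
pipeline stages where thousands of voxels are fitted repeatedly
(cohort simulations, calibration runs) the LLS fit is used; the two are
identical on noise-free data to 1e-8.

Scalar maps use the eigenvalues sorted descending, clamped below at
ε = 1e-12 mm²/s so that noisy background voxels cannot produce FA > 1
or NaNs; an all-zero tensor is defined to have FA = 0.

## Orientation model and tractography

Probabilistic tracking needs a per-voxel distribution over fibre
orientations.  Here each compartment is summarised by a bipolar Watson
density `f(x) ∝ exp(κ (μᵀx)²)` with mean μ and concentration κ.  For
tensor-fitted data there is one compartment per voxel with μ the
principal eigenvector and κ = κ_max · FA² (κ_max default 200, so a
coherent FA 0.8 voxel gets κ ≈ 128 ≈ 5° dispersion and an FA 0 voxel
samples uniformly).  Phantom ground truth can instead populate the
model with the true crossing compartments.  The Watson model is a
deliberate, isolated stand-in for posterior orientation sampling: any
backend that yields per-voxel (mean, concentration, fraction) entries
can be swapped in behind the same contract.

Watson draws use exact rejection sampling: propose t = cos θ from the
truncated-exponential density ∝ e^{κt} on [0, 1] (stable form
`t = 1 + log(u + (1−u)e^{−κ})/κ`), accept with probability
`exp(κ t (t − 1))`.  Since t² ≤ t on [0, 1] the bound is exact, and the
acceptance rate stays above ~1/2 for every κ, so the sampler has
uniform cost from κ = 0 (uniform directions) to κ = ∞ (the mean
itself).  The empirical mean resultant length matches numerical
integration of the Watson density to well under 2%.

Streamlines propagate by Euler steps `x ← x + ℓ·d` with ℓ = 0.5 mm,
at most 2000 steps per direction, and terminate when the next point
would leave the mask or when the cosine between successive steps falls
below 0.2 (≈ 78.5°; the violating step is not taken, so every returned
streamline satisfies the constraint at every interior point).  Tracking
runs in both directions from the seed along ±(first sampled direction)
and concatenates the reversed backward half, the seed, and the forward
half.  Whole-brain tracking seeds `n_per_voxel` streamlines (default
500) at the centre of every masked voxel; each voxel draws from its own
RNG stream spawned from `(seed, flat voxel index)`, which makes results
bit-reproducible and independent of iteration order.  Voxel membership
uses the voxel-centre convention (`round(world → voxel)`), matching the
counting stage.

## Anatomical connectivity mapping

The ACM counts, per masked voxel, the number of streamlines that
traverse it, each streamline at most once per voxel (a loop does not
double-count).  Traversal is detected by resampling every streamline
segment to at most half the smallest voxel edge and collecting the
containing voxels; an exact 3-D grid-crossing enumeration is available
behind a flag and serves as the oracle in tests (it can only add voxels
that a segment grazes between sample points).  Counts are *not*
normalised by brain size — brain size enters the group model as a
covariate instead, which keeps the map an integer count with an exact
floor: every masked voxel is traversed by its own seeds, so
ACM ≥ n_per_voxel throughout the mask.  Seed and count masks are
separate arguments, so grey-matter seeds can be excluded from counting
if a study calls for it.

## Group inference

Per-subject maps are smoothed with an isotropic Gaussian of 4 mm FWHM
(σ = FWHM/2√(2 ln 2) per axis, converted to voxels through the affine;
zero boundary).  The GLM has one indicator column per group plus
mean-centred covariates (age in years, gender 0/1, brain-mask voxel
count); vector contrasts yield t, matrix contrasts F.  Significance is
assessed nonparametrically: the data are residualised against the
nuisance columns, subject rows of the residualised data are permuted
(Freedman–Lane, the standard scheme for nuisance covariates), the full
model is refitted, and the maximum of the TFCE-enhanced statistic over
the analysis mask forms the null distribution, giving

    p_FWE(v) = (1 + #{perm max ≥ observed(v)}) / (n_perm + 1),

with minimum attainable p = 1/(n_perm + 1).  When all n! permutations
can be enumerated the exact distribution is used instead (with a
warning).  TFCE uses E = 0.5, H = 2, 26-connectivity and 100
integration steps by default; thresholds are exact multiples of dh so
the discrete integral matches a brute-force oracle to machine
precision.  Small-volume correction re-forms the max-statistic null
inside an a-priori ROI from the retained per-permutation maps, so
SVC p ≤ global p voxel-wise by construction; it reports surviving voxel
count, peak p, and the world coordinate of the peak.  A Lilliefors test
on per-voxel GLM residuals quantifies how non-normal the data are (the
justification for the permutation route), and a per-group Pearson
correlation of ROI-mean ACM against intracranial volume checks that
connectedness differences are not mere brain-size effects.

## Synthetic study conditions

The phantom generator defines the conditions every test runs under:

- **Acquisition** — 61 gradient directions at b = 1500 s/mm² plus 10
  b = 0 volumes, spread by electrostatic repulsion of antipodal pairs;
  SNR (S0/σ) 20 with Rician noise `M = |(S+n₁) + i n₂|`.  Pipeline-level
  tests use a reduced 30-direction/4-b0 scheme of the same b-value to
  keep replicate simulations fast; tensor-accuracy checks use the full
  scheme.
- **Geometry** — tube tracts (polyline centreline + radius) on a
  2 mm isotropic grid; voxels inside one tube carry a single compartment
  along the local tangent, overlap voxels one compartment per tube with
  equal fractions.  The canonical single-tract phantom is a 16×8×8 grid
  with a 2.5 mm-radius tube spanning the full x-extent, so the tract
  terminates at the volume boundary like a projection pathway meeting
  the mask edge.  (With the tube ends inside the volume, streamlines
  dying just past the endpoint linger around the caps and inflate
  end-of-tract counts, inverting the mid-tract accumulation the
  connectedness map should show.)
- **Lesion** — a 5 mm sphere at mid-tract whose fibre compartments get
  λ⊥ × f.  The cohort default is f = 3.5 (ground-truth FA 0.80 → 0.30),
  modelling severe focal demyelination: RD and MD rise, AD is exactly
  unchanged, and streamline dispersion inside the lesion disconnects
  the tract ends.  Milder lesions (f = 2, FA → 0.58) alter the DTI
  scalars but barely perturb tracking at desk scale — dispersed
  streamlines stay inside any tract wider than ~1 voxel, and can even
  *raise* ACM by visiting more same-tract voxels — so the dissociation
  between local and connectedness effects requires both a narrow tract
  (2 mm radius) and a severe lesion.  These conditions were fixed by
  replicate simulation before the statistical analyses were built.
- **Cohorts** — per-subject multiplicative log-normal jitter (5%) on
  the eigenvalues, independent noise, ages drawn per group
  (controls 46 ± 13, lesioned group 42 ± 13 years), random 0/1 gender,
  and a per-subject jittered ellipsoidal brain mask.  The mask jitter
  is what gives the brain-size covariate its between-subject variance;
  with identical masks the covariate column would be constant and the
  design rank-deficient.  Control groups always have f = 1.

What the phantoms do *not* emulate: head geometry, susceptibility or
motion artefacts, spatial normalisation error, partial-volume
fractions below voxel scale, and MCMC posterior orientation
uncertainty.  Passing tests therefore demonstrate the correctness and
calibration of the algorithms under known generative conditions, not
performance on acquired data.

## Problem sizes and runtime choices

Replicate counts and grid sizes are chosen so the full suite runs on a
single CPU in minutes: fitting-accuracy simulations use 500 replicate
voxels per anisotropy level; calibration uses 20 null cohorts of 2 × 6
subjects on a 10×8×8 grid with 500 permutations; the lesioned cohort
uses 8 + 8 subjects on a 16×8×8 grid with 20 streamlines per voxel for
ACM (the per-voxel floor scales with it; comparisons are
between-group, so the reduced seeding only adds Monte-Carlo variance).
The tracking contract itself is exercised at the full 500 streamlines
per voxel on a 100-voxel mask.

A note on gradient tables: scanner exports disagree on the bvec sign
convention, and a wrong sign mirrors every fitted orientation.  The DWI
reader exposes a per-axis ±1 flip; synthetic data are unaffected, so
the default is no flip.

## Known limitations

- The single-tensor fit is the only signal model; crossing-fibre voxels
  are handled in tracking (via multi-compartment orientation models)
  but not in scalar estimation, where a crossing lowers FA as it does
  in real DTI.
- Watson concentrations come from a deterministic κ(FA) rule, not from
  posterior uncertainty; κ_max rescaling changes absolute dispersion
  but not the qualitative contrasts tested.
- Permutation inference assumes subject exchangeability under the null
  within the Freedman–Lane scheme; grouped or longitudinal designs are
  out of scope.
- TFCE runtime grows with the number of integration steps times the
  cost of connected-component labelling; maps much larger than ~10⁵
  voxels per permutation would need a coarser dh or an incremental
  clustering scheme.
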