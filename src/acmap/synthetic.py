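"""Synthetic crossing-fibre DWI phantoms and cohorts.

Phantoms are rectangular voxel grids containing tubular fibre tracts
(parametric polylines with a radius).  Voxels inside one tube carry a
single axially-symmetric diffusion compartment oriented along the local
tube tangent; voxels inside several tubes carry one compartment per tube
with equal volume fractions, giving genuine crossing-fibre signal.  The
remaining volume fraction in every voxel is isotropic with a background
diffusivity.  A spherical "lesion" multiplies the radial eigenvalue of
fibre compartments it covers by a factor f >= 1, which lowers FA and
raises RD and MD while leaving AD untouched — the signature of a
demyelinating white-matter alteration.

Cohorts are collections of such phantoms with per-subject Rician noise,
multiplicative log-normal jitter on the eigenvalues, a per-subject brain
mask, and group-dependent lesion severity; a control group always has
f = 1.  The default acquisition is 61 gradient directions at
b = 1500 s/mm^2 plus 10 b = 0 volumes at SNR (S0/sigma) = 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    CohortDesign,
    GradientScheme,
    ImageVolume,
    MaskVolume,
    ValidationError,
    voxel_to_world,
)
from .dti import TensorField

__all__ = [
    "FibreCompartment",
    "Tube",
    "LesionSpec",
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "GroundTruth",
    "Subject",
    "make_gradient_scheme",
    "simulate_signal",
    "add_rician_noise",
    "build_phantom",
    "make_cohort",
    "default_cohort_spec",
    "default_tube_phantom_spec",
]

#: default white-matter eigenvalues, mm^2/s (ground-truth FA ~= 0.80)
LAMBDA_PARALLEL = 1.7e-3
LAMBDA_PERP = 0.3e-3
#: default isotropic background diffusivity, mm^2/s
BACKGROUND_DIFFUSIVITY = 0.8e-3


@dataclass
class FibreCompartment:
    """One axially-symmetric fibre population within a voxel."""

    orientation: np.ndarray  # unit 3-vector
    lambda_parallel: float = LAMBDA_PARALLEL
    lambda_perp: float = LAMBDA_PERP
    volume_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if n == 0:
            raise ValidationError("compartment orientation must be nonzero")
        self.orientation = self.orientation / n
        if not (self.lambda_parallel >= self.lambda_perp > 0):
            raise ValidationError(
                "eigenvalues must satisfy lambda_parallel >= lambda_perp > 0; "
                f"got ({self.lambda_parallel}, {self.lambda_perp})"
            )
        if not 0 <= self.volume_fraction <= 1:
            raise ValidationError("volume fraction must lie in [0, 1]")

    def tensor(self) -> np.ndarray:
        """Dense 3x3 diffusion tensor of this compartment."""
        mu = self.orientation
        return self.lambda_perp * np.eye(3) + (
            self.lambda_parallel - self.lambda_perp
        ) * np.outer(mu, mu)


@dataclass
class Tube:
    """A tubular tract: polyline centreline (world mm) with a radius."""

    points: np.ndarray  # (M, 3)
    radius: float  # mm
    lambda_parallel: float = LAMBDA_PARALLEL
    lambda_perp: float = LAMBDA_PERP
    volume_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValidationError("tube centreline needs at least 2 points")
        if self.radius <= 0:
            raise ValidationError("tube radius must be positive")

    @classmethod
    def straight(cls, start, end, radius, **kw) -> "Tube":
        return cls(points=np.array([start, end], dtype=float), radius=radius, **kw)


@dataclass
class LesionSpec:
    """Spherical region whose fibre compartments get lambda_perp * f."""

    center: np.ndarray  # world mm
    radius: float  # mm
    rd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.rd_multiplier < 1:
            raise ValidationError("lesion rd_multiplier must be >= 1")
        if self.radius <= 0:
            raise ValidationError("lesion radius must be positive")


@dataclass
class PhantomSpec:
    """Everything needed to build one synthetic subject."""

    shape: tuple = (20, 20, 20)
    voxel_size: float = 2.0  # mm, isotropic
    tubes: list = field(default_factory=list)
    background_diffusivity: float = BACKGROUND_DIFFUSIVITY
    lesion: LesionSpec | None = None
    s0: float = 100.0
    snr: float = 20.0  # S0 / sigma; sigma = 0 for noiseless phantoms
    brain_mask_shape: str = "full"  # "full" or "ellipsoid"
    ellipsoid_scale: float = 1.0

    @property
    def sigma(self) -> float:
        return 0.0 if np.isinf(self.snr) else self.s0 / self.snr

    def to_dict(self) -> dict:
        d = asdict(self)
        for t in d["tubes"]:
            t["points"] = np.asarray(t["points"]).tolist()
        if d["lesion"] is not None:
            d["lesion"]["center"] = np.asarray(d["lesion"]["center"]).tolist()
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["tubes"] = [Tube(**t) for t in d.get("tubes", [])]
        if d.get("lesion") is not None:
            d["lesion"] = LesionSpec(**d["lesion"])
        d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass
class GroupSpec:
    """One cohort arm: size, lesion severity and covariate distribution."""

    name: str
    n: int
    lesion_multiplier: float = 1.0
    age_mean: float = 46.0
    age_sd: float = 13.0


@dataclass
class CohortSpec:
    """A cohort of phantoms sharing one geometry, split into groups."""

    base: PhantomSpec
    groups: list  # list[GroupSpec]
    jitter_scale: float = 0.05  # log-normal sd on eigenvalues
    mask_jitter: float = 0.03  # relative jitter on ellipsoid semi-axes
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort needs at least one group")
        for g in self.groups:
            if g.n < 2:
                raise ValidationError(f"group {g.name!r} needs n >= 2; got {g.n}")
        if min(g.lesion_multiplier for g in self.groups) != 1.0:
            raise ValidationError("the control group must have lesion_multiplier 1.0")


@dataclass
class GroundTruth:
    """Noise-free generative parameters of one phantom, per voxel."""

    n_compartments: np.ndarray  # (X, Y, Z) int
    orientations: np.ndarray  # (X, Y, Z, K, 3)
    lambdas: np.ndarray  # (X, Y, Z, K, 2) — (parallel, perp)
    fractions: np.ndarray  # (X, Y, Z, K)
    iso_fraction: np.ndarray  # (X, Y, Z)
    iso_diffusivity: float
    affine: np.ndarray

    def tensor_field(self) -> TensorField:
        """Fraction-weighted effective tensor per voxel (exact for single-
        compartment voxels, a mixture average where fibres cross)."""
        X, Y, Z, K, _ = self.orientations.shape
        mu = self.orientations
        lp = self.lambdas[..., 0]
        lt = self.lambdas[..., 1]
        f = self.fractions
        D = np.zeros((X, Y, Z, 3, 3))
        eye = np.eye(3)
        for k in range(K):
            outer = mu[..., k, :, None] * mu[..., k, None, :]
            Dk = lt[..., k, None, None] * eye + (
                (lp[..., k] - lt[..., k])[..., None, None] * outer
            )
            D += f[..., k, None, None] * Dk
        D += (self.iso_fraction * self.iso_diffusivity)[..., None, None] * eye
        six = np.stack(
            [D[..., 0, 0], D[..., 1, 1], D[..., 2, 2], D[..., 0, 1], D[..., 0, 2], D[..., 1, 2]],
            axis=-1,
        )
        valid = np.ones(D.shape[:3], dtype=bool)
        s0 = np.ones(D.shape[:3])
        return TensorField(tensors=six, s0=s0, affine=self.affine, valid=valid)


@dataclass
class Subject:
    """One synthetic cohort member."""

    id: str
    group: str
    dwi: ImageVolume
    mask: MaskVolume
    ground_truth: GroundTruth
    rois: dict


# ---------------------------------------------------------------------------
# gradient scheme


def _repulsion_directions(n: int, seed: int, n_iter: int = 2000) -> np.ndarray:
    """Approximately uniform directions on the half-sphere by electrostatic
    repulsion of antipodal point pairs (gradient descent on 1/r energy)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.05
    for it in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]  # v_i - v_j
        summ = v[:, None, :] + v[None, :, :]  # v_i + v_j  (antipodal image)
        dd = np.linalg.norm(diff, axis=-1)
        ds = np.linalg.norm(summ, axis=-1)
        np.fill_diagonal(dd, np.inf)
        np.fill_diagonal(ds, np.inf)
        force = (diff / dd[..., None] ** 3).sum(axis=1) + (
            summ / ds[..., None] ** 3
        ).sum(axis=1)
        # project tangentially to the sphere and take a damped step
        force -= (force * v).sum(axis=1, keepdims=True) * v
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        v = v + step * force / norm
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        step *= 0.998
    return v


def make_gradient_scheme(
    n_directions: int = 61, b_value: float = 1500.0, n_b0: int = 10, seed: int = 0
) -> GradientScheme:
    """Gradient table with n_b0 leading b=0 volumes and n_directions
    diffusion-weighted directions spread by electrostatic repulsion."""
    if n_directions < 6:
        raise ValidationError("tensor estimation needs at least 6 directions")
    if n_b0 < 1:
        raise ValidationError("need at least one b=0 volume")
    dirs = _repulsion_directions(n_directions, seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# forward signal model


def simulate_signal(
    compartments: list,
    scheme: GradientScheme,
    s0: float = 100.0,
    isotropic_diffusivity: float = BACKGROUND_DIFFUSIVITY,
) -> np.ndarray:
    """Noise-free multi-tensor signal, one value per scheme volume.

    S(g, b) = S0 * [ sum_c f_c exp(-b g^T D_c g) + f_iso exp(-b d_iso) ]
    where f_iso = 1 - sum_c f_c.
    """
    fsum = sum(c.volume_fraction for c in compartments)
    if fsum > 1 + 1e-9:
        raise ValidationError(f"compartment fractions sum to {fsum} > 1")
    b = scheme.bvals
    g = scheme.bvecs
    signal = np.zeros(len(scheme))
    for c in compartments:
        proj = g @ c.orientation
        adc = c.lambda_perp + (c.lambda_parallel - c.lambda_perp) * proj**2
        signal += c.volume_fraction * np.exp(-b * adc)
    f_iso = 1.0 - fsum
    if f_iso > 0:
        signal += f_iso * np.exp(-b * isotropic_diffusivity)
    return s0 * signal


def add_rician_noise(signal: np.ndarray, sigma: float, seed=None) -> np.ndarray:
    """Magnitude-MRI noise: M = |(S + n1) + i n2| with n1, n2 ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# phantom construction


def _tube_distance_and_tangent(tube: Tube, centers: np.ndarray):
    """Min distance of each point to the tube centreline and the tangent of
    the nearest segment.  centers: (V, 3)."""
    best_d = np.full(len(centers), np.inf)
    best_t = np.zeros((len(centers), 3))
    for a, b in zip(tube.points[:-1], tube.points[1:]):
        ab = b - a
        L2 = ab @ ab
        if L2 == 0:
            continue
        t = np.clip(((centers - a) @ ab) / L2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(centers - proj, axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_t[closer] = ab / np.sqrt(L2)
    return best_d, best_t


def _default_affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spec.voxel_size
    return aff


def _brain_mask(spec: PhantomSpec, rng: np.random.Generator | None, mask_jitter: float) -> np.ndarray:
    shape = np.asarray(spec.shape)
    if spec.brain_mask_shape == "full":
        return np.ones(spec.shape, dtype=bool)
    if spec.brain_mask_shape != "ellipsoid":
        raise ValidationError(f"unknown brain_mask_shape {spec.brain_mask_shape!r}")
    center = (shape - 1) / 2.0
    semi = (shape / 2.0) * spec.ellipsoid_scale
    if rng is not None and mask_jitter > 0:
        semi = semi * (1.0 + mask_jitter * rng.standard_normal(3))
    idx = np.indices(spec.shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def build_phantom(
    spec: PhantomSpec,
    seed: int = 0,
    scheme: GradientScheme | None = None,
    lambda_scale: tuple = (1.0, 1.0),
    _mask_rng: np.random.Generator | None = None,
    _mask_jitter: float = 0.0,
):
    """Build one phantom: DWI volume, brain mask, ground truth and ROI masks.

    Parameters
    ----------
    lambda_scale : (parallel, perp) multiplicative factors applied to every
        tube's eigenvalues — the hook used by :func:`make_cohort` for
        between-subject variability.

    Returns
    -------
    (ImageVolume with attached scheme, MaskVolume, GroundTruth, dict of ROI
    MaskVolumes with keys ``tube_<i>``, ``lesion`` and ``background``).
    """
    if scheme is None:
        scheme = make_gradient_scheme(seed=0)
    affine = _default_affine(spec)
    shape = tuple(spec.shape)
    ijk = np.indices(shape).reshape(3, -1).T
    centers = voxel_to_world(affine, ijk)
    lo = centers.min(axis=0) - spec.voxel_size / 2
    hi = centers.max(axis=0) + spec.voxel_size / 2

    n_tubes = len(spec.tubes)
    K = max(n_tubes, 1)
    inside = np.zeros((len(centers), n_tubes), dtype=bool)
    tangents = np.zeros((len(centers), n_tubes, 3))
    for ti, tube in enumerate(spec.tubes):
        if np.any(tube.points < lo) or np.any(tube.points > hi):
            raise ValidationError(f"tube {ti} extends outside the grid")
        d, t = _tube_distance_and_tangent(tube, centers)
        inside[:, ti] = d <= tube.radius
        tangents[:, ti] = t

    n_comp = inside.sum(axis=1)
    orientations = np.zeros((len(centers), K, 3))
    lambdas = np.zeros((len(centers), K, 2))
    fractions = np.zeros((len(centers), K))
    lp_scale, lt_scale = lambda_scale
    for ti, tube in enumerate(spec.tubes):
        sel = inside[:, ti]
        slot = (inside[sel, :ti]).sum(axis=1)  # compartment slot per voxel
        rows = np.where(sel)[0]
        orientations[rows, slot] = tangents[rows, ti]
        lambdas[rows, slot, 0] = tube.lambda_parallel * lp_scale
        lambdas[rows, slot, 1] = tube.lambda_perp * lt_scale
        fractions[rows, slot] = tube.volume_fraction
    # equal fractions where tubes overlap; cap the total at 1
    multi = n_comp > 0
    total = fractions.sum(axis=1)
    over = total > 1
    fractions[over] /= total[over, None]
    iso_fraction = 1.0 - fractions.sum(axis=1)

    lesion_mask_flat = np.zeros(len(centers), dtype=bool)
    if spec.lesion is not None:
        d = np.linalg.norm(centers - spec.lesion.center, axis=1)
        lesion_mask_flat = d <= spec.lesion.radius
        affected = lesion_mask_flat & multi
        lam = lambdas[affected]
        lam[..., 1] = np.minimum(lam[..., 1] * spec.lesion.rd_multiplier, lam[..., 0])
        lambdas[affected] = lam

    # forward signal, voxel by voxel group (vectorized over volumes)
    b = scheme.bvals
    g = scheme.bvecs
    signal = np.zeros((len(centers), len(scheme)))
    iso_term = np.exp(-b * spec.background_diffusivity)
    signal += iso_fraction[:, None] * iso_term[None, :]
    for k in range(K):
        have = fractions[:, k] > 0
        if not have.any():
            continue
        mu = orientations[have, k]
        proj = mu @ g.T  # (V_k, N)
        lp = lambdas[have, k, 0][:, None]
        lt = lambdas[have, k, 1][:, None]
        adc = lt + (lp - lt) * proj**2
        signal[have] += fractions[have, k][:, None] * np.exp(-b[None, :] * adc)
    signal *= spec.s0

    rng = np.random.default_rng(seed)
    noisy = add_rician_noise(signal, spec.sigma, rng)

    data = noisy.reshape(shape + (len(scheme),))
    mask_data = _brain_mask(spec, _mask_rng, _mask_jitter)
    dwi = ImageVolume(data=data, affine=affine, units="a.u.", scheme=scheme)
    mask = MaskVolume(data=mask_data, affine=affine)

    gt = GroundTruth(
        n_compartments=n_comp.reshape(shape),
        orientations=orientations.reshape(shape + (K, 3)),
        lambdas=lambdas.reshape(shape + (K, 2)),
        fractions=fractions.reshape(shape + (K,)),
        iso_fraction=iso_fraction.reshape(shape),
        iso_diffusivity=spec.background_diffusivity,
        affine=affine,
    )
    rois = {}
    for ti in range(n_tubes):
        rois[f"tube_{ti}"] = MaskVolume(inside[:, ti].reshape(shape), affine)
    if spec.lesion is not None and lesion_mask_flat.any():
        rois["lesion"] = MaskVolume(lesion_mask_flat.reshape(shape), affine)
    bg = ~multi
    if bg.any():
        rois["background"] = MaskVolume(bg.reshape(shape), affine)
    return dwi, mask, gt, rois


# ---------------------------------------------------------------------------
# cohorts


def make_cohort(cohort_spec: CohortSpec, scheme: GradientScheme | None = None):
    """Generate per-subject phantoms plus the cohort design table.

    Each subject gets an independent noise realisation, log-normal jitter
    on the tube eigenvalues, a jittered brain mask, and covariates drawn
    from the per-group distributions.  Fully reproducible from
    ``cohort_spec.seed``; subject seeds are spawned, never shared.
    """
    if scheme is None:
        scheme = make_gradient_scheme(seed=0)
    root = np.random.SeedSequence(cohort_spec.seed)
    n_total = sum(g.n for g in cohort_spec.groups)
    child_seqs = root.spawn(n_total)

    subjects = []
    rows = []
    i = 0
    for gspec in cohort_spec.groups:
        for j in range(gspec.n):
            seq = child_seqs[i]
            rng = np.random.default_rng(seq)
            jit = np.exp(cohort_spec.jitter_scale * rng.standard_normal(2))
            spec = PhantomSpec(
                shape=cohort_spec.base.shape,
                voxel_size=cohort_spec.base.voxel_size,
                tubes=cohort_spec.base.tubes,
                background_diffusivity=cohort_spec.base.background_diffusivity,
                lesion=_scaled_lesion(cohort_spec.base.lesion, gspec.lesion_multiplier),
                s0=cohort_spec.base.s0,
                snr=cohort_spec.base.snr,
                brain_mask_shape=cohort_spec.base.brain_mask_shape,
                ellipsoid_scale=cohort_spec.base.ellipsoid_scale,
            )
            dwi, mask, gt, rois = build_phantom(
                spec,
                seed=rng.integers(0, 2**31 - 1),
                scheme=scheme,
                lambda_scale=(jit[0], jit[1]),
                _mask_rng=rng,
                _mask_jitter=cohort_spec.mask_jitter,
            )
            sid = f"{gspec.name}{j:02d}"
            subjects.append(
                Subject(id=sid, group=gspec.name, dwi=dwi, mask=mask, ground_truth=gt, rois=rois)
            )
            rows.append(
                {
                    "id": sid,
                    "group": gspec.name,
                    "age": float(np.round(rng.normal(gspec.age_mean, gspec.age_sd), 1)),
                    "gender": int(rng.integers(0, 2)),
                    "mask_voxels": mask.n_voxels,
                }
            )
            i += 1
    design = CohortDesign(table=pd.DataFrame(rows))
    return subjects, design


def _scaled_lesion(lesion: LesionSpec | None, multiplier: float) -> LesionSpec | None:
    """Group-specific lesion: f = 1 (control) means the lesion is inert."""
    if lesion is None or multiplier == 1.0:
        return None
    return LesionSpec(center=lesion.center, radius=lesion.radius, rd_multiplier=multiplier)


def default_tube_phantom_spec(
    shape: tuple = (16, 8, 8),
    voxel_size: float = 2.0,
    radius: float = 2.5,
    snr: float = 20.0,
) -> PhantomSpec:
    """The canonical single-tract phantom: one straight tube spanning the
    full x-extent of the grid (its end caps fall outside the volume, so the
    tract terminates at the brain-mask boundary like a real projection
    pathway reaching cortex)."""
    y = (shape[1] - 1) * voxel_size / 2
    x_end = (shape[0] - 1) * voxel_size
    tube = Tube.straight((0.0, y, y), (x_end, y, y), radius=radius)
    return PhantomSpec(shape=shape, voxel_size=voxel_size, tubes=[tube], snr=snr)


def default_cohort_spec(
    n_per_group: int = 8,
    lesion_multiplier: float = 3.5,
    seed: int = 0,
    shape: tuple = (16, 8, 8),
    snr: float = 20.0,
) -> CohortSpec:
    """The canonical two-group study: sighted-like controls (NS) versus a
    lesioned group (CB) with a focal radial-diffusivity increase.

    The geometry is a single narrow tract (2 mm radius tube along x,
    roughly one voxel across) with a 5 mm spherical lesion at mid-tract.
    The default multiplier f = 3.5 models a severe focal demyelination
    (ground-truth FA 0.80 -> 0.30 inside the lesion), strong enough that
    streamline dispersion inside the lesion measurably disconnects the
    tract ends — the effect the connectedness map is designed to detect —
    while the FA change itself stays confined to the lesion.
    """
    vx = 2.0
    nx = shape[0]
    y = (shape[1] // 2 - 1) * vx  # a voxel-centre line
    tube = Tube.straight((2 * vx, y, y), ((nx - 2) * vx, y, y), radius=2.0)
    lesion = LesionSpec(center=((nx - 1) * vx / 2, y, y), radius=5.0, rd_multiplier=lesion_multiplier)
    base = PhantomSpec(
        shape=shape,
        voxel_size=vx,
        tubes=[tube],
        lesion=lesion,
        snr=snr,
        brain_mask_shape="ellipsoid",
        ellipsoid_scale=1.05,
    )
    groups = [
        GroupSpec(name="NS", n=n_per_group, lesion_multiplier=1.0, age_mean=46, age_sd=13),
        GroupSpec(name="CB", n=n_per_group, lesion_multiplier=lesion_multiplier, age_mean=42, age_sd=13),
    ]
    return CohortSpec(base=base, groups=groups, seed=seed)
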