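"""Probabilistic streamline tractography with a Watson orientation model.

Each voxel carries one or more fibre compartments, each described by a
mean orientation, a Watson concentration kappa and a volume fraction.
At every Euler step the tracker picks a compartment with probability
proportional to its fraction, draws a direction from the bipolar Watson
density  f(x) ∝ exp(kappa (mu^T x)^2)  about the compartment mean,
sign-aligns it with the previous step, and terminates the streamline
when the cosine between successive steps falls below the curvature
threshold, when the next point would leave the mask, or after
``max_steps`` steps per direction.  Tracking runs in both directions
from every seed and the two halves are concatenated.

Watson sampling uses an exact rejection scheme: propose t = cos(theta)
from the truncated-exponential density ∝ exp(kappa t) on [0, 1] and
accept with probability exp(kappa t (t - 1)), which bounds the target
∝ exp(kappa t^2) everywhere (t^2 <= t on [0, 1]).  Acceptance never
drops below ~1/2, so the cost is uniform in kappa; kappa = 0 degrades
gracefully to uniform directions and kappa = inf to the mean itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import MaskVolume, StreamlineSet, ValidationError, world_to_voxel, voxel_to_world
from .dti import TensorField, tensor_scalars

__all__ = [
    "TrackingParams",
    "OrientationModel",
    "sample_watson_cos",
    "sample_direction",
    "track_streamline",
    "whole_brain_tracking",
]

#: default concentration assigned to a voxel with FA = 1
KAPPA_MAX = 200.0


@dataclass
class TrackingParams:
    """Streamline propagation parameters (FSL probtrackx conventions)."""

    n_per_voxel: int = 500
    max_steps: int = 2000
    step_length: float = 0.5  # mm
    curvature_threshold: float = 0.2  # minimum cosine between steps
    kappa_max: float = KAPPA_MAX
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.curvature_threshold < 1:
            raise ValidationError("curvature threshold must be a cosine in (0, 1)")
        if self.step_length <= 0:
            raise ValidationError("step length must be positive")
        if self.n_per_voxel < 1:
            raise ValidationError("n_per_voxel must be >= 1")


@dataclass
class OrientationModel:
    """Per-voxel fibre orientation distributions.

    ``means``: (X, Y, Z, K, 3) unit orientations; ``kappas``: (X, Y, Z, K)
    Watson concentrations (0 = uniform, inf = deterministic);
    ``fractions``: (X, Y, Z, K) summing to 1 over the first ``n_comp``
    entries of each voxel.
    """

    means: np.ndarray
    kappas: np.ndarray
    fractions: np.ndarray
    n_comp: np.ndarray
    affine: np.ndarray
    _frames: tuple | None = None  # cached (e1, e2) orthonormal to each mean

    @property
    def shape(self):
        return self.means.shape[:3]

    def frames(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-compartment orthonormal basis (e1, e2) completing each mean."""
        if self._frames is None:
            mu = self.means
            norm = np.linalg.norm(mu, axis=-1, keepdims=True)
            mu = mu / np.maximum(norm, 1e-300)
            helper = np.where(np.abs(mu[..., 0:1]) < 0.9, [1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
            e1 = _cross(mu, helper)
            e1 /= np.maximum(np.linalg.norm(e1, axis=-1, keepdims=True), 1e-300)
            e2 = _cross(mu, e1)
            self._frames = (e1, e2)
        return self._frames

    @classmethod
    def from_tensor(
        cls,
        tensor_field: TensorField,
        kappa_rule=None,
        kappa_max: float = KAPPA_MAX,
    ) -> "OrientationModel":
        """Single-compartment model: mean = principal eigenvector,
        kappa = kappa_rule(FA) (default kappa_max * FA^2).  Voxels with an
        invalid fit get kappa = 0, i.e. isotropic sampling."""
        if kappa_rule is None:
            kappa_rule = lambda fa: kappa_max * fa**2  # noqa: E731
        scalars = tensor_scalars(tensor_field)
        fa = scalars["FA"].data
        shape = tensor_field.shape
        means = np.zeros(shape + (1, 3))
        means[..., 0, :] = tensor_field.principal_direction
        kappas = np.zeros(shape + (1,))
        kappas[..., 0] = np.where(tensor_field.valid, kappa_rule(fa), 0.0)
        fractions = np.ones(shape + (1,))
        n_comp = np.ones(shape, dtype=int)
        return cls(means, kappas, fractions, n_comp, np.asarray(tensor_field.affine))

    @classmethod
    def from_ground_truth(cls, gt, kappa_rule=None, kappa_max: float = KAPPA_MAX) -> "OrientationModel":
        """Model straight from phantom ground truth: one entry per true
        compartment; kappa from each compartment's single-fibre FA."""
        from .dti import fa_from_eigenvalues

        if kappa_rule is None:
            kappa_rule = lambda fa: kappa_max * fa**2  # noqa: E731
        lam = gt.lambdas  # (..., K, 2)
        eig = np.stack([lam[..., 0], lam[..., 1], lam[..., 1]], axis=-1)
        fa = fa_from_eigenvalues(eig)  # (..., K)
        frac = gt.fractions.copy()
        total = frac.sum(axis=-1, keepdims=True)
        has = total[..., 0] > 0
        frac[has] /= total[has]
        kappas = np.where(gt.fractions > 0, kappa_rule(fa), 0.0)
        n_comp = gt.n_compartments.astype(int).copy()
        # pure-background voxels: one isotropic entry
        iso = n_comp == 0
        n_comp[iso] = 1
        frac[iso, 0] = 1.0
        means = gt.orientations.copy()
        means[iso, 0] = (1.0, 0.0, 0.0)  # arbitrary mean; kappa = 0
        return cls(means, kappas, frac, n_comp, np.asarray(gt.affine))


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product on the last axis (avoids np.cross overhead)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


# ---------------------------------------------------------------------------
# Watson sampling


def sample_watson_cos(kappa: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw t = cos(theta) in [0, 1] from the bipolar Watson density
    ∝ exp(kappa t^2), one draw per entry of ``kappa`` (vectorized exact
    rejection sampling)."""
    kappa = np.asarray(kappa, dtype=float)
    flat = kappa.ravel()
    t = np.empty(flat.shape)
    inf = np.isinf(flat)
    t[inf] = 1.0
    tiny = flat < 1e-12
    pending = np.where(~inf & ~tiny)[0]
    t[tiny] = rng.random(int(tiny.sum()))
    while len(pending):
        k = flat[pending]
        u = rng.random(len(pending))
        v = rng.random(len(pending))
        # truncated-exponential proposal on [0, 1], numerically stable for large kappa
        prop = 1.0 + np.log(u + (1.0 - u) * np.exp(-k)) / k
        accept = v <= np.exp(k * prop * (prop - 1.0))
        t[pending[accept]] = prop[accept]
        pending = pending[~accept]
    return t.reshape(kappa.shape)


def _watson_directions(mu, e1, e2, kappas, rng: np.random.Generator) -> np.ndarray:
    """One Watson draw about each mean given its orthonormal frame;
    all inputs (n, 3)/(n,).  The sign of the result is random (bipolar)."""
    n = len(mu)
    t = sample_watson_cos(kappas, rng)
    phi = rng.random(n) * 2 * np.pi
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    s = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    return (
        (sign * t)[:, None] * mu
        + (s * np.cos(phi))[:, None] * e1
        + (s * np.sin(phi))[:, None] * e2
    )


def _sample_at_voxels(model: OrientationModel, vox: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One direction draw per row of ``vox`` ((n, 3) integer voxel indices):
    compartment choice by fraction, then a Watson draw."""
    i, j, k = vox[:, 0], vox[:, 1], vox[:, 2]
    e1f, e2f = model.frames()
    if model.means.shape[3] == 1:  # single-compartment model: no choice draw
        return _watson_directions(
            model.means[i, j, k, 0], e1f[i, j, k, 0], e2f[i, j, k, 0],
            model.kappas[i, j, k, 0], rng,
        )
    frac = model.fractions[i, j, k]  # (n, K)
    cum = np.cumsum(frac, axis=1)
    u = rng.random(len(vox))
    choice = (u[:, None] > cum).sum(axis=1)
    choice = np.minimum(choice, model.n_comp[i, j, k] - 1)
    ar = np.arange(len(vox))
    mu = model.means[i, j, k][ar, choice]
    return _watson_directions(
        mu, e1f[i, j, k][ar, choice], e2f[i, j, k][ar, choice],
        model.kappas[i, j, k][ar, choice], rng,
    )


def sample_direction(
    model: OrientationModel,
    voxel: tuple,
    previous_direction: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one propagation direction at ``voxel``.

    With a previous direction the draw is sign-aligned to it
    (dot >= 0); on the first step the bipolar sign is random.
    """
    vox = np.asarray(voxel, dtype=int).reshape(1, 3)
    d = _sample_at_voxels(model, vox, rng)[0]
    if previous_direction is not None:
        prev = np.asarray(previous_direction, dtype=float)
        if d @ prev < 0:
            d = -d
    return d


# ---------------------------------------------------------------------------
# propagation


def _in_mask(mask_data: np.ndarray, vox: np.ndarray) -> np.ndarray:
    shape = mask_data.shape
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    res = np.zeros(len(vox), dtype=bool)
    if ok.any():
        v = vox[ok]
        res[ok] = mask_data[v[:, 0], v[:, 1], v[:, 2]]
    return res


def _padded_mask(mask_data: np.ndarray) -> np.ndarray:
    """Mask padded with a 1-voxel False border for bounds-free lookups."""
    return np.pad(mask_data, 1, mode="constant", constant_values=False)


def _in_mask_padded(padded: np.ndarray, vox: np.ndarray) -> np.ndarray:
    v = np.clip(vox + 1, 0, np.array(padded.shape) - 1)
    return padded[v[:, 0], v[:, 1], v[:, 2]]


def _voxel_of(affine_inv3: np.ndarray, affine_invt: np.ndarray, pts: np.ndarray) -> np.ndarray:
    cont = pts @ affine_inv3.T + affine_invt
    return np.round(cont).astype(int)  # voxel centre convention


def _propagate_half(model, mask, starts, first_dirs, params, rng):
    """Propagate one half-streamline per row, taking the given first step
    directly, then sampling.  Returns a list of (m_i, 3) point arrays that
    EXCLUDE the seed point."""
    inv = np.linalg.inv(model.affine)
    inv3, invt = inv[:3, :3], inv[:3, 3]
    padded = mask if isinstance(mask, np.ndarray) else _padded_mask(mask.data)
    n = len(starts)
    rec_idx = []  # per-iteration streamline ids that received a point
    rec_pts = []

    x = np.asarray(starts, dtype=float).copy()
    d_prev = np.asarray(first_dirs, dtype=float).copy()

    # first step: deterministic along first_dirs
    x_new = x + params.step_length * d_prev
    vox_new = _voxel_of(inv3, invt, x_new)
    inm = _in_mask_padded(padded, vox_new)
    ai = np.where(inm)[0]
    rec_idx.append(ai)
    rec_pts.append(x_new[ai])
    x = x_new[ai]
    d_prev = d_prev[ai]

    for _ in range(params.max_steps - 1):
        if not len(ai):
            break
        vox = _voxel_of(inv3, invt, x)
        d = _sample_at_voxels(model, vox, rng)
        # sign-align with the previous step
        dots = np.einsum("ij,ij->i", d, d_prev)
        flip = dots < 0
        d[flip] = -d[flip]
        np.abs(dots, out=dots)
        # curvature termination: the violating step is not taken
        keep = dots >= params.curvature_threshold
        if not keep.all():
            ai, x, d = ai[keep], x[keep], d[keep]
        if not len(ai):
            break
        x_new = x + params.step_length * d
        vox_new = _voxel_of(inv3, invt, x_new)
        inm = _in_mask_padded(padded, vox_new)
        ai, x, d_prev = ai[inm], x_new[inm], d[inm]
        rec_idx.append(ai)
        rec_pts.append(x)

    halves = [[] for _ in range(n)]
    if rec_idx:
        all_idx = np.concatenate(rec_idx)
        if len(all_idx):
            all_pts = np.concatenate(rec_pts)
            order = np.argsort(all_idx, kind="stable")  # iteration order kept per id
            counts = np.bincount(all_idx, minlength=n)
            pieces = np.split(all_pts[order], np.cumsum(counts)[:-1])
            halves = [list(p) for p in pieces]
    return halves


def _track_from_seeds(model, mask, seeds, params, rng, padded=None):
    """Full bidirectional streamlines from the given seed points (n, 3).

    The two halves of all seeds propagate in one lockstep batch; the
    reversed backward half is concatenated in front of the forward half.
    """
    seeds = np.asarray(seeds, dtype=float)
    inv = np.linalg.inv(model.affine)
    vox0 = _voxel_of(inv[:3, :3], inv[:3, 3], seeds)
    d0 = _sample_at_voxels(model, vox0, rng)
    n = len(seeds)
    starts = np.concatenate([seeds, seeds])
    first = np.concatenate([d0, -d0])
    if padded is None:
        padded = _padded_mask(mask.data)
    halves = _propagate_half(model, padded, starts, first, params, rng)
    out = []
    for i in range(n):
        pts = halves[n + i][::-1] + [seeds[i]] + halves[i]
        out.append(np.asarray(pts))
    return out


def track_streamline(
    model: OrientationModel,
    mask: MaskVolume,
    seed_point: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One bidirectional streamline from a world-mm seed point."""
    seed = np.asarray(seed_point, dtype=float)
    vox = np.round(world_to_voxel(model.affine, seed)).astype(int)
    if not _in_mask(mask.data, vox.reshape(1, 3))[0]:
        raise ValidationError(f"seed point {seed.tolist()} is outside the mask")
    return _track_from_seeds(model, mask, seed.reshape(1, 3), params, rng)[0]


def whole_brain_tracking(
    model: OrientationModel,
    mask: MaskVolume,
    params: TrackingParams,
) -> StreamlineSet:
    """Seed ``n_per_voxel`` streamlines at the centre of every masked voxel.

    Each voxel gets its own RNG stream spawned from
    ``(params.seed, flat voxel index)``, so the result is bit-reproducible
    and independent of iteration order.
    """
    if not mask.data.any():
        raise ValidationError("mask is empty")
    vox_idx = np.argwhere(mask.data)
    flat = np.ravel_multi_index(vox_idx.T, mask.data.shape)
    padded = _padded_mask(mask.data)
    streamlines = []
    for v, fl in zip(vox_idx, flat):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(int(fl),))
        )
        center = voxel_to_world(model.affine, v)
        seeds = np.tile(center, (params.n_per_voxel, 1))
        streamlines.extend(_track_from_seeds(model, mask, seeds, params, rng, padded=padded))
    return StreamlineSet(
        streamlines=streamlines,
        affine=np.asarray(mask.affine),
        meta={
            "n_per_voxel": params.n_per_voxel,
            "max_steps": params.max_steps,
            "step_length": params.step_length,
            "curvature_threshold": params.curvature_threshold,
            "seed": params.seed,
            "n_seed_voxels": int(len(vox_idx)),
        },
    )
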