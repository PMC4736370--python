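"""Diffusion tensor fitting and scalar microstructure maps.

The single-tensor model of diffusion-weighted signal decay,

    S(g, b) = S0 * exp(-b g^T D g),

is fitted per voxel either by log-linear least squares (LLS) or by
nonlinear least squares (NLS) on the untransformed signal, initialised
from the LLS solution.  From the eigenvalues l1 >= l2 >= l3 of D the four
standard scalar indices are derived:

    MD = (l1 + l2 + l3) / 3          mean diffusivity
    AD = l1                          axial diffusivity
    RD = (l2 + l3) / 2               radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||   fractional anisotropy

Negative eigenvalues produced by noisy fits are clamped to a small
positive epsilon before the scalars are computed, which keeps FA <= 1 and
avoids NaNs in background voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core_io import GradientScheme, ImageVolume, MaskVolume, ValidationError

__all__ = [
    "TensorField",
    "ScalarMap",
    "design_matrix",
    "fit_tensor_lls",
    "fit_tensor_nls",
    "tensor_scalars",
    "fa_from_eigenvalues",
]

#: eigenvalue clamp floor, mm^2/s
EIGENVALUE_EPS = 1e-12

# index order of the 6 unique tensor elements
_TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor plus fitted baseline signal.

    ``tensors`` stores the 6 unique elements (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    in mm^2/s.  ``valid`` flags voxels with a usable fit, ``converged``
    flags voxels where the nonlinear optimiser reported convergence (always
    True for pure LLS fits).
    """

    tensors: np.ndarray  # (X, Y, Z, 6)
    s0: np.ndarray  # (X, Y, Z)
    affine: np.ndarray
    valid: np.ndarray  # (X, Y, Z) bool
    converged: np.ndarray | None = None
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.converged is None:
            self.converged = self.valid.copy()

    @property
    def shape(self):
        return self.tensors.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Dense (X, Y, Z, 3, 3) symmetric tensor array."""
        t = self.tensors
        out = np.empty(t.shape[:3] + (3, 3), dtype=float)
        out[..., 0, 0] = t[..., 0]
        out[..., 1, 1] = t[..., 1]
        out[..., 2, 2] = t[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = t[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = t[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = t[..., 5]
        return out

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues sorted descending (…, 3) and eigenvectors (…, 3, 3).

        ``eigenvectors[..., :, i]`` is the eigenvector of eigenvalue i;
        the principal direction is ``eigenvectors[..., :, 0]``.
        """
        if self._eig is None:
            w, v = np.linalg.eigh(self.as_matrices())
            order = np.argsort(w, axis=-1)[..., ::-1]
            w = np.take_along_axis(w, order, axis=-1)
            v = np.take_along_axis(v, order[..., None, :], axis=-1)
            self._eig = (w, v)
        return self._eig

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.eigensystem()[0]

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigensystem()[1][..., :, 0]


@dataclass
class ScalarMap:
    """A 3-D scalar lattice (FA/MD/RD/AD/ACM) with its affine and a kind tag."""

    data: np.ndarray
    affine: np.ndarray
    kind: str
    valid: np.ndarray | None = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Log-linear design: log S = B @ [log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = scheme.bvals
    g = scheme.bvecs
    B = np.empty((len(scheme), 7))
    B[:, 0] = 1.0
    B[:, 1] = -b * g[:, 0] ** 2
    B[:, 2] = -b * g[:, 1] ** 2
    B[:, 3] = -b * g[:, 2] ** 2
    B[:, 4] = -2 * b * g[:, 0] * g[:, 1]
    B[:, 5] = -2 * b * g[:, 0] * g[:, 2]
    B[:, 6] = -2 * b * g[:, 1] * g[:, 2]
    return B


def _check_scheme(scheme: GradientScheme) -> None:
    if scheme.n_distinct_directions < 6 or not np.any(scheme.b0_mask):
        raise ValidationError("tensor fit needs >=6 distinct b>0 directions and >=1 b=0")


def fit_tensor_lls(dwi: ImageVolume, scheme: GradientScheme, mask: MaskVolume) -> TensorField:
    """Log-linear least-squares tensor fit per masked voxel.

    Samples with non-positive signal are excluded voxel-wise; voxels with
    fewer than 7 usable samples are flagged invalid rather than raising.
    """
    _check_scheme(scheme)
    B = design_matrix(scheme)
    shape = dwi.data.shape[:3]
    Y = dwi.data[mask.data]  # (V, N)
    V = Y.shape[0]

    coefs = np.zeros((V, 7))
    ok = np.zeros(V, dtype=bool)
    positive = Y > 0
    full = positive.all(axis=1)

    if full.any():
        logY = np.log(Y[full])
        sol, *_ = np.linalg.lstsq(B, logY.T, rcond=None)
        coefs[full] = sol.T
        ok[full] = True

    # voxels with dropouts: refit individually on the usable subset
    for i in np.where(~full)[0]:
        use = positive[i]
        if use.sum() < 7:
            continue
        sol, *_ = np.linalg.lstsq(B[use], np.log(Y[i, use]), rcond=None)
        coefs[i] = sol
        ok[i] = True

    tensors = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    tensors[mask.data] = coefs[:, 1:]
    s0[mask.data] = np.where(ok, np.exp(np.clip(coefs[:, 0], -700, 700)), 0.0)
    valid[mask.data] = ok
    tensors[~valid] = 0.0
    return TensorField(tensors=tensors, s0=s0, affine=np.asarray(mask.affine), valid=valid)


def _nls_single(signal, B_dw, x0, max_iter):
    """NLS for one voxel. x = [S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""

    def model(x):
        return x[0] * np.exp(B_dw @ x[1:])

    def resid(x):
        return model(x) - signal

    def jac(x):
        e = np.exp(B_dw @ x[1:])
        J = np.empty((len(signal), 7))
        J[:, 0] = e
        J[:, 1:] = x[0] * e[:, None] * B_dw
        return J

    res = least_squares(
        resid, x0, jac=jac, method="lm", ftol=1e-10, xtol=1e-12, gtol=1e-10,
        max_nfev=100 * len(x0),
    )
    niter = res.nfev
    converged = res.status > 0 and niter < 100 * len(x0)
    return res.x, converged


def fit_tensor_nls(
    dwi: ImageVolume,
    scheme: GradientScheme,
    mask: MaskVolume,
    init: TensorField | None = None,
    max_iter: int = 100,
) -> TensorField:
    """Nonlinear least-squares tensor fit on the untransformed signal.

    Minimises sum((S_obs - S0 exp(-b g^T D g))^2) per voxel with a
    Levenberg-Marquardt trust-region step, initialised from ``init``
    (default: the LLS fit).  Non-converged voxels fall back to the
    initial solution and are flagged.
    """
    _check_scheme(scheme)
    if init is None:
        init = fit_tensor_lls(dwi, scheme, mask)
    B_dw = design_matrix(scheme)[:, 1:]  # signal model uses raw S, no log
    shape = dwi.data.shape[:3]

    tensors = init.tensors.copy()
    s0 = init.s0.copy()
    valid = init.valid.copy()
    converged = np.zeros(shape, dtype=bool)

    idx = np.argwhere(mask.data & valid)
    for i, j, k in idx:
        signal = dwi.data[i, j, k]
        x0 = np.concatenate(([max(s0[i, j, k], 1e-10)], tensors[i, j, k]))
        try:
            x, conv = _nls_single(signal, B_dw, x0, max_iter)
        except Exception:
            conv = False
        if conv:
            s0[i, j, k] = x[0]
            tensors[i, j, k] = x[1:]
            converged[i, j, k] = True
        # else: keep LLS fallback, converged stays False
    return TensorField(
        tensors=tensors, s0=s0, affine=np.asarray(mask.affine), valid=valid,
        converged=converged,
    )


def fa_from_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (…, 3) eigenvalues; 0 for all-zero tensors."""
    lam = np.asarray(eigenvalues, dtype=float)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - md) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num / den)
    return np.where(den > 0, fa, 0.0)


def tensor_scalars(tensor_field: TensorField) -> dict[str, ScalarMap]:
    """FA, MD, RD and AD maps from a fitted tensor field.

    Eigenvalues below ``EIGENVALUE_EPS`` are clamped up to it in valid
    voxels before the scalars are computed; invalid voxels map to 0.
    """
    lam = tensor_field.eigenvalues.copy()
    valid = tensor_field.valid
    nonzero = np.abs(lam).sum(axis=-1) > 0
    clamp = valid & nonzero
    lam[clamp] = np.clip(lam[clamp], EIGENVALUE_EPS, None)
    lam[~valid] = 0.0

    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = lam[..., 1:].mean(axis=-1)
    fa = np.clip(fa_from_eigenvalues(lam), 0.0, 1.0)
    aff = tensor_field.affine
    return {
        "FA": ScalarMap(fa, aff, "FA", valid),
        "MD": ScalarMap(md, aff, "MD", valid),
        "RD": ScalarMap(rd, aff, "RD", valid),
        "AD": ScalarMap(ad, aff, "AD", valid),
    }
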