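"""Voxel-wise nonparametric group inference on scalar maps.

Implements the full inferential chain used for ACM and DTI group
comparisons: Gaussian smoothing in millimetres, a voxel-wise general
linear model (group indicators plus nuisance covariates), threshold-free
cluster enhancement (TFCE), family-wise-error control by the permutation
distribution of the image-wide maximum statistic (Freedman-Lane scheme
for nuisance covariates), tract-specific small-volume correction, a
Lilliefors residual-normality screen, and the ACM-vs-ICV linear
correlation check.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .core_io import CohortDesign, MaskVolume, ValidationError, voxel_to_world
from .dti import ScalarMap

__all__ = [
    "DesignMatrix",
    "StatMaps",
    "SVCResult",
    "build_design_matrix",
    "group_contrast",
    "group_f_contrast",
    "smooth_map",
    "glm_stat",
    "tfce",
    "permutation_test",
    "small_volume_correct",
    "residual_normality_check",
    "icv_correlation",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class DesignMatrix:
    """Subjects-by-predictors matrix: group indicators then covariates.

    Group columns are cell-mean indicators (one per group, no intercept);
    covariates are mean-centred so group contrasts estimate adjusted
    group means.
    """

    X: np.ndarray
    columns: list
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            bad = self._collinear_columns()
            raise ValidationError(f"design matrix is rank deficient; collinear columns: {bad}")

    def _collinear_columns(self) -> list:
        names = []
        for j in range(self.X.shape[1]):
            others = np.delete(self.X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(self.X):
                names.append(self.columns[j])
        return names or list(self.columns)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def groups(self) -> list:
        return [c for c in self.columns if c.startswith("group:")]


def build_design_matrix(
    design: CohortDesign, covariates: tuple = ("age", "gender", "mask_voxels")
) -> DesignMatrix:
    labels = design.group_labels()
    groups = design.groups
    cols = []
    names = []
    for g in groups:
        cols.append((labels == g).astype(float))
        names.append(f"group:{g}")
    for c in covariates:
        v = design.table[c].to_numpy(dtype=float)
        cols.append(v - v.mean())  # centred so group columns stay interpretable
        names.append(c)
    X = np.column_stack(cols)
    return DesignMatrix(X=X, columns=names, group_labels=labels)


def group_contrast(dm: DesignMatrix, spec: str) -> np.ndarray:
    """Vector contrast from a string like ``"NS>CB"`` (+1 on NS, -1 on CB)."""
    if ">" not in spec:
        raise ValueError(f"contrast spec {spec!r} must look like 'A>B'")
    a, b = (s.strip() for s in spec.split(">", 1))
    c = np.zeros(len(dm.columns))
    try:
        c[dm.columns.index(f"group:{a}")] = 1.0
        c[dm.columns.index(f"group:{b}")] = -1.0
    except ValueError as e:
        raise ValueError(f"unknown group in contrast {spec!r}") from e
    return c


def group_f_contrast(dm: DesignMatrix) -> np.ndarray:
    """(g-1) x p contrast matrix testing any difference among group means."""
    gcols = [i for i, c in enumerate(dm.columns) if c.startswith("group:")]
    if len(gcols) < 2:
        raise ValueError("need at least 2 groups for an F contrast")
    C = np.zeros((len(gcols) - 1, len(dm.columns)))
    for r, gi in enumerate(gcols[1:]):
        C[r, gcols[0]] = 1.0
        C[r, gi] = -1.0
    return C


# ---------------------------------------------------------------------------
# smoothing


def smooth_map(scalar_map: ScalarMap, fwhm_mm: float) -> ScalarMap:
    """Isotropic Gaussian smoothing with the kernel width given in mm FWHM.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxels through
    the affine; fwhm = 0 is the identity.  Zero-padding at the boundary
    keeps total mass conserved away from the edges.
    """
    if fwhm_mm < 0:
        raise ValidationError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return ScalarMap(scalar_map.data.copy(), scalar_map.affine, scalar_map.kind, scalar_map.valid)
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = sigma_mm / scalar_map.voxel_size
    out = ndimage.gaussian_filter(scalar_map.data.astype(float), sigma=sigma_vox, mode="constant", cval=0.0, truncate=6.0)
    return ScalarMap(out, scalar_map.affine, scalar_map.kind, scalar_map.valid)


# ---------------------------------------------------------------------------
# GLM


def _ols_stat(Y: np.ndarray, X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """t (vector contrast) or F (matrix contrast) per column of Y.

    Y: (n, V); X: (n, p); C: (p,) or (q, p).  Returns (V,).
    """
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof  # (V,)
    XtX_inv = np.linalg.inv(X.T @ X)
    C = np.asarray(C, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if C.ndim == 1:
            num = C @ beta  # (V,)
            den = np.sqrt(sigma2 * (C @ XtX_inv @ C))
            stat = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        else:
            q = C.shape[0]
            CB = C @ beta  # (q, V)
            M = np.linalg.inv(C @ XtX_inv @ C.T)  # (q, q)
            num = np.einsum("qv,qr,rv->v", CB, M, CB) / q
            stat = np.where(sigma2 > 0, num / np.where(sigma2 > 0, sigma2, 1.0), 0.0)
    return stat


def glm_stat(maps: np.ndarray, dm: DesignMatrix, contrast: np.ndarray) -> np.ndarray:
    """Per-voxel OLS statistic over stacked subject maps.

    ``maps``: (n_subjects, …spatial) array (or a list of per-subject
    arrays).  Vector contrasts yield t maps, matrix contrasts F maps.
    """
    arr = np.asarray(maps, dtype=float)
    n = arr.shape[0]
    if n != dm.n_subjects:
        raise ValidationError(f"{n} maps but {dm.n_subjects} design rows")
    spatial = arr.shape[1:]
    stat = _ols_stat(arr.reshape(n, -1), dm.X, contrast)
    return stat.reshape(spatial)


# ---------------------------------------------------------------------------
# TFCE


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18 or 26")


def tfce(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    connectivity: int = 26,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    TFCE(v) = sum over thresholds h = dh, 2 dh, … <= stat(v) of
    extent(cluster containing v at h)^E * h^H * dh, with clusters formed
    at ``stat >= h`` under the given connectivity.  Default dh is
    max(stat)/n_steps.  Negative values are ignored (enhance ``-map``
    separately for the opposite tail).
    """
    pos = np.clip(np.asarray(stat_map, dtype=float), 0.0, None)
    hmax = pos.max()
    if hmax <= 0:
        return np.zeros_like(pos)
    if dh is None:
        dh = hmax / n_steps
    if dh <= 0:
        raise ValidationError("dh must be positive")
    struct = _structure(connectivity)
    out = np.zeros_like(pos)
    n_thr = int(np.floor(hmax / dh + 1e-9))
    for i in range(1, n_thr + 1):
        h = i * dh
        labels, nlab = ndimage.label(pos >= h, structure=struct)
        if nlab:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            contrib = sizes.astype(float) ** E * h**H * dh
            out += contrib[labels]
    return out


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class StatMaps:
    """Observed statistic, its TFCE enhancement, and FWE-corrected p-values."""

    stat: np.ndarray
    enhanced: np.ndarray
    p_fwe: np.ndarray
    affine: np.ndarray
    null_max: np.ndarray  # per-permutation maxima (random permutations only)
    meta: dict = field(default_factory=dict)
    null_maps: np.ndarray | None = None  # (n_perm, …spatial) when retained

    @property
    def min_attainable_p(self) -> float:
        return self.meta["min_p"]


def _permutations(n: int, n_perm: int, rng: np.random.Generator):
    """n_perm row permutations of range(n); exhaustive when n! <= n_perm."""
    total = math.factorial(n)
    if total <= n_perm:
        warnings.warn(
            f"only {total} distinct permutations exist; enumerating all",
            stacklevel=3,
        )
        return [np.asarray(p) for p in itertools.permutations(range(n))], True
    perms = [rng.permutation(n) for _ in range(n_perm)]
    return perms, False


def permutation_test(
    maps: np.ndarray,
    dm: DesignMatrix,
    contrast: np.ndarray,
    n_perm: int = 5000,
    tfce_on: bool = True,
    roi: MaskVolume | None = None,
    mask: np.ndarray | None = None,
    seed: int = 0,
    tfce_kwargs: dict | None = None,
    keep_null_maps: bool = True,
    affine: np.ndarray | None = None,
) -> StatMaps:
    """FWE-corrected voxel-wise inference by sign-free subject permutation.

    Uses the Freedman-Lane scheme: the data are residualized against the
    nuisance columns (those with zero contrast weight), the residualized
    rows are permuted, and the full model is refitted to each permuted
    dataset.  The null distribution is the per-permutation maximum of the
    (optionally TFCE-enhanced) statistic over ``mask`` (or ``roi``), and

        p(v) = (1 + #{perm max >= observed(v)}) / (n_perm + 1),

    so the observed labelling is always counted.  When every distinct
    permutation can be enumerated, the exact distribution is used instead
    (with a warning) and p = #{>=}/n_total.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    arr = np.asarray(maps, dtype=float)
    n = arr.shape[0]
    spatial = arr.shape[1:]
    Y = arr.reshape(n, -1)
    X = dm.X
    C = np.asarray(contrast, dtype=float)

    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    scope = roi.data if roi is not None else mask
    flat_scope = (scope & mask).ravel()
    if not flat_scope.any():
        raise ValidationError("empty analysis region")

    # Freedman-Lane: residualize against nuisance-only columns
    involved = (np.atleast_2d(C) != 0).any(axis=0)
    Z = X[:, ~involved]
    if Z.shape[1]:
        Rz = np.eye(n) - Z @ np.linalg.pinv(Z)
        E = Rz @ Y
    else:
        E = Y

    tk = dict(tfce_kwargs or {})

    def enhanced_stat(data):
        s = _ols_stat(data, X, C)
        s = np.where(mask.ravel(), s, 0.0)
        if tfce_on:
            return tfce(s.reshape(spatial), **tk).ravel()
        return s

    obs_stat = np.where(mask.ravel(), _ols_stat(Y, X, C), 0.0)
    obs_enh = enhanced_stat(Y)

    rng = np.random.default_rng(seed)
    perms, exhaustive = _permutations(n, n_perm, rng)
    null_max = np.empty(len(perms))
    null_maps = np.empty((len(perms), E.shape[1])) if keep_null_maps else None
    for j, p in enumerate(perms):
        enh = enhanced_stat(E[p])
        null_max[j] = enh[flat_scope].max()
        if keep_null_maps:
            null_maps[j] = enh

    if exhaustive:
        denom = len(perms)
        count = (null_max[None, :] >= obs_enh[:, None]).sum(axis=1)
        p_fwe = count / denom
        min_p = 1.0 / denom
    else:
        count = (null_max[None, :] >= obs_enh[:, None]).sum(axis=1)
        p_fwe = (1.0 + count) / (n_perm + 1.0)
        min_p = 1.0 / (n_perm + 1.0)
    p_fwe = np.where(flat_scope, p_fwe, 1.0)

    return StatMaps(
        stat=obs_stat.reshape(spatial),
        enhanced=obs_enh.reshape(spatial),
        p_fwe=p_fwe.reshape(spatial),
        affine=np.asarray(affine) if affine is not None else np.eye(4),
        null_max=null_max,
        meta={
            "n_perm": len(perms),
            "exhaustive": exhaustive,
            "tfce": tfce_on,
            "contrast": np.asarray(contrast).tolist(),
            "roi": roi is not None,
            "min_p": min_p,
            "mask": mask,
        },
        null_maps=null_maps,
    )


@dataclass
class SVCResult:
    """Small-volume-corrected inference inside an a-priori ROI."""

    p_fwe: np.ndarray  # corrected p inside the ROI (1 outside)
    n_significant: int  # surviving voxels at alpha
    peak_p: float
    peak_coord_world: np.ndarray
    alpha: float
    meta: dict = field(default_factory=dict)


def small_volume_correct(
    result: StatMaps, roi_mask: MaskVolume, alpha: float = 0.05
) -> SVCResult:
    """Re-correct a permutation result with the max statistic restricted
    to ``roi_mask`` — the tract-specific small-volume correction.

    Requires that the permutation run retained its null maps
    (``keep_null_maps=True``).  Reports surviving voxel count, peak
    corrected p and the world coordinate of the peak.
    """
    roi = np.asarray(roi_mask.data, dtype=bool)
    analysis_mask = result.meta.get("mask")
    if analysis_mask is not None:
        roi = roi & analysis_mask
    if not roi.any():
        raise ValidationError("ROI is empty (or outside the analysis mask)")
    if result.null_maps is None:
        raise ValidationError("permutation result did not retain null maps; rerun with keep_null_maps=True")
    flat_roi = roi.ravel()
    null_max_roi = result.null_maps[:, flat_roi].max(axis=1)
    obs = result.enhanced.ravel()
    count = (null_max_roi[None, :] >= obs[:, None]).sum(axis=1)
    if result.meta.get("exhaustive"):
        p = count / len(null_max_roi)
    else:
        p = (1.0 + count) / (len(null_max_roi) + 1.0)
    p = np.where(flat_roi, p, 1.0).reshape(result.enhanced.shape)
    inside = np.argwhere(roi)
    p_in = p[roi]
    order = np.argsort(p_in, kind="stable")
    peak_idx = inside[order[0]]
    peak_coord = voxel_to_world(roi_mask.affine, peak_idx)
    return SVCResult(
        p_fwe=p,
        n_significant=int((p_in < alpha).sum()),
        peak_p=float(p_in.min()),
        peak_coord_world=peak_coord,
        alpha=alpha,
        meta={"n_roi_voxels": int(roi.sum()), **result.meta},
    )


# ---------------------------------------------------------------------------
# model diagnostics


def residual_normality_check(maps: np.ndarray, dm: DesignMatrix, mask: np.ndarray | None = None, alpha: float = 0.05) -> dict:
    """Lilliefors test on GLM residuals per voxel.

    Returns the per-voxel statistic and p-value plus the fraction of
    voxels rejecting normality at ``alpha`` — the screen that motivates a
    nonparametric inference route.  Voxels with (numerically) constant
    residuals are flagged degenerate and excluded from the fraction.
    """
    arr = np.asarray(maps, dtype=float)
    n = arr.shape[0]
    if n - dm.X.shape[1] < 5 or n < 5:
        raise ValidationError("too few subjects for a residual normality check")
    spatial = arr.shape[1:]
    Y = arr.reshape(n, -1)
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    flat = np.asarray(mask, dtype=bool).ravel()
    beta = np.linalg.pinv(dm.X) @ Y
    resid = Y - dm.X @ beta
    stat = np.full(Y.shape[1], np.nan)
    pval = np.full(Y.shape[1], np.nan)
    degenerate = np.zeros(Y.shape[1], dtype=bool)
    for v in np.where(flat)[0]:
        r = resid[:, v]
        if np.std(r) < 1e-12 * max(1.0, np.abs(r).max()):
            degenerate[v] = True
            continue
        stat[v], pval[v] = lilliefors(r, dist="norm")
    usable = flat & ~degenerate
    frac = float((pval[usable] < alpha).mean()) if usable.any() else np.nan
    return {
        "stat": stat.reshape(spatial),
        "p": pval.reshape(spatial),
        "degenerate": degenerate.reshape(spatial),
        "rejection_fraction": frac,
        "alpha": alpha,
    }


def icv_correlation(acm_maps, roi_mask: MaskVolume, icv_values, group_labels) -> dict:
    """Per-group Pearson correlation of ROI-mean ACM against ICV.

    Checks whether connectedness merely tracks intracranial volume, which
    would confound group comparisons of raw (unnormalized) ACM.
    Returns {group: (r, two-sided p)}.
    """
    arr = np.asarray([np.asarray(m, dtype=float)[roi_mask.data].mean() for m in acm_maps])
    icv = np.asarray(icv_values, dtype=float)
    labels = np.asarray(group_labels)
    out = {}
    for g in np.unique(labels):
        sel = labels == g
        if sel.sum() < 3:
            raise ValidationError(f"group {g!r} needs >= 3 subjects for a correlation")
        x, y = arr[sel], icv[sel]
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValidationError(f"zero variance in group {g!r}")
        r, p = sps.pearsonr(x, y)
        out[str(g)] = (float(r), float(p))
    return out
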