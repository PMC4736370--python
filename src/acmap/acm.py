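"""Anatomical Connectivity Mapping: voxel-wise streamline counting.

The ACM of a whole-brain tractogram assigns to every voxel inside the
brain mask the number of streamlines that pass through it, each
streamline counted at most once per voxel.  Because every masked voxel
seeds streamlines itself, the map has an exact floor of ``n_per_voxel``
everywhere in the mask, and values above the floor measure how strongly
the voxel participates in pathways seeded elsewhere — a connectedness
map that accumulates effects along entire tract systems rather than
voxel-local microstructure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import MaskVolume, StreamlineSet, ValidationError
from .dti import ScalarMap, fit_tensor_lls, fit_tensor_nls
from .tracking import OrientationModel, TrackingParams, whole_brain_tracking

__all__ = ["ACMMap", "acm_from_streamlines", "acm_pipeline", "streamline_voxels"]


@dataclass
class ACMMap:
    """Per-voxel streamline counts with provenance."""

    data: np.ndarray  # (X, Y, Z) int
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.data.shape

    def as_scalar_map(self) -> ScalarMap:
        return ScalarMap(self.data.astype(float), self.affine, "ACM")


def _densify(points: np.ndarray, max_spacing: float) -> np.ndarray:
    """Resample a polyline so consecutive points are <= max_spacing apart."""
    if len(points) < 2:
        return points
    seg = np.diff(points, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    n_sub = np.maximum(np.ceil(lengths / max_spacing).astype(int), 1)
    if (n_sub == 1).all():
        return points
    pieces = [points[:1]]
    for p0, s, n in zip(points[:-1], seg, n_sub):
        frac = np.arange(1, n + 1) / n
        pieces.append(p0 + frac[:, None] * s)
    return np.concatenate(pieces)


def _segment_voxels_exact(p0: np.ndarray, p1: np.ndarray, affine_inv) -> list:
    """All voxels a segment passes through, by 3-D DDA grid traversal
    (voxel-centre convention: voxel i spans [i - 0.5, i + 0.5))."""
    inv3, invt = affine_inv
    a = p0 @ inv3.T + invt
    b = p1 @ inv3.T + invt
    out = [tuple(np.round(a).astype(int))]
    d = b - a
    L = np.linalg.norm(d)
    if L == 0:
        return out
    # parametric crossings of the half-integer planes on each axis
    ts = [0.0]
    for ax in range(3):
        if d[ax] == 0:
            continue
        lo, hi = sorted((a[ax], b[ax]))
        first = np.floor(lo + 0.5) + 0.5
        planes = np.arange(first, hi, 1.0)
        ts.extend(((planes - a[ax]) / d[ax]).tolist())
    ts = sorted(t for t in ts if 0 <= t <= 1)
    ts.append(1.0)
    for t0, t1 in zip(ts[:-1], ts[1:]):
        mid = a + d * (t0 + t1) / 2
        out.append(tuple(np.round(mid).astype(int)))
    # keep order of first visitation, drop consecutive duplicates
    dedup = [out[0]]
    for v in out[1:]:
        if v != dedup[-1]:
            dedup.append(v)
    return dedup


def streamline_voxels(points: np.ndarray, affine: np.ndarray, exact: bool = False) -> np.ndarray:
    """Distinct voxel indices (m, 3) visited by one streamline.

    Default: sample the polyline at <= half the smallest voxel edge and
    collect containing voxels.  ``exact=True`` enumerates every voxel the
    polyline geometrically intersects (slower; used as an oracle).
    """
    inv = np.linalg.inv(affine)
    inv3, invt = inv[:3, :3], inv[:3, 3]
    if exact:
        vox = []
        pts = np.asarray(points, dtype=float)
        if len(pts) == 1:
            vox.append(tuple(np.round(pts[0] @ inv3.T + invt).astype(int)))
        for p0, p1 in zip(pts[:-1], pts[1:]):
            vox.extend(_segment_voxels_exact(p0, p1, (inv3, invt)))
        return np.unique(np.asarray(vox, dtype=int), axis=0)
    voxel_size = np.linalg.norm(affine[:3, :3], axis=0).min()
    dense = _densify(np.asarray(points, dtype=float), voxel_size / 2.0)
    vox = np.round(dense @ inv3.T + invt).astype(int)
    return np.unique(vox, axis=0)


def _flat_in_mask(vox: np.ndarray, mask: MaskVolume) -> np.ndarray:
    """Flat indices of the in-bounds, in-mask rows of (m, 3) voxel indices."""
    shape = mask.data.shape
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    flat = np.ravel_multi_index(vox[ok].T, shape) if ok.any() else np.empty(0, dtype=np.int64)
    return flat[mask.data.ravel()[flat]]


def _all_visit_keys(sls: list, mask: MaskVolume, nflat: int) -> np.ndarray:
    """(streamline * nflat + voxel) keys for every in-mask point visit."""
    if not sls:
        return np.empty(0, dtype=np.int64)
    lengths = np.array([len(s) for s in sls])
    pts = np.concatenate(sls) if lengths.sum() else np.empty((0, 3))
    sid = np.repeat(np.arange(len(sls)), lengths)
    # densify any segment longer than half the smallest voxel edge
    max_spacing = np.linalg.norm(mask.affine[:3, :3], axis=0).min() / 2.0
    if len(pts) > 1:
        seg = np.diff(pts, axis=0)
        same = sid[1:] == sid[:-1]
        seglen = np.linalg.norm(seg, axis=1)
        long = same & (seglen > max_spacing)
        if long.any():
            extra_pts, extra_sid = [], []
            for i in np.where(long)[0]:
                n_sub = int(np.ceil(seglen[i] / max_spacing))
                frac = np.arange(1, n_sub) / n_sub
                extra_pts.append(pts[i] + frac[:, None] * seg[i])
                extra_sid.append(np.full(n_sub - 1, sid[i]))
            pts = np.concatenate([pts] + extra_pts)
            sid = np.concatenate([sid] + extra_sid)
    inv = np.linalg.inv(mask.affine)
    vox = np.round(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = mask.data.shape
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    vox, sid = vox[ok], sid[ok]
    flat = np.ravel_multi_index(vox.T, shape)
    inm = mask.data.ravel()[flat]
    return sid[inm].astype(np.int64) * nflat + flat[inm]


def acm_from_streamlines(
    streamlines, mask: MaskVolume, exact: bool = False
) -> ACMMap:
    """Count, per masked voxel, the streamlines that traverse it.

    Each streamline increments a voxel at most once, regardless of how
    often it loops through; voxels outside the mask are ignored.
    """
    if isinstance(streamlines, StreamlineSet) and streamlines.affine is not None:
        if not np.allclose(streamlines.affine, mask.affine, atol=1e-6):
            raise ValidationError("streamline reference affine does not match the mask")
    shape = mask.data.shape
    counts = np.zeros(shape, dtype=np.int64)
    nflat = int(np.prod(shape))
    sls = [np.asarray(s, dtype=float).reshape(-1, 3) for s in streamlines]
    if exact:
        keys = []
        for si, sl in enumerate(sls):
            vox = streamline_voxels(sl, mask.affine, exact=True)
            keys.append(si * nflat + _flat_in_mask(vox, mask))
        key_arr = np.concatenate(keys) if keys else np.empty(0, dtype=np.int64)
    else:
        # vectorized over the whole tractogram: densify every segment to
        # <= half the smallest voxel edge, then collapse (streamline, voxel)
        # pairs to unique visits
        key_arr = _all_visit_keys(sls, mask, nflat)
    if len(key_arr):
        uniq = np.unique(key_arr)
        counts_flat = np.bincount(uniq % nflat, minlength=nflat)
        counts = counts_flat.reshape(shape)
    meta = dict(getattr(streamlines, "meta", {}) or {})
    meta["n_streamlines"] = len(list(streamlines)) if not hasattr(streamlines, "__len__") else len(streamlines)
    return ACMMap(data=counts, affine=np.asarray(mask.affine), provenance=meta)


def acm_pipeline(
    dwi,
    scheme,
    mask: MaskVolume,
    params: TrackingParams,
    fit_method: str = "lls",
    count_mask: MaskVolume | None = None,
) -> ACMMap:
    """Tensor fit -> orientation model -> whole-brain tracking -> counting.

    ``mask`` seeds the tractography; ``count_mask`` (default: same mask)
    restricts the counting, so grey-matter seeds can be excluded from the
    map if desired.  Fully reproducible from ``params.seed``.
    """
    if fit_method == "lls":
        tf = fit_tensor_lls(dwi, scheme, mask)
    elif fit_method == "nls":
        tf = fit_tensor_nls(dwi, scheme, mask)
    else:
        raise ValueError(f"unknown fit method {fit_method!r}")
    model = OrientationModel.from_tensor(tf, kappa_max=params.kappa_max)
    streamlines = whole_brain_tracking(model, mask, params)
    return acm_from_streamlines(streamlines, count_mask or mask)
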