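"""Shared spatial data model and on-disk formats.

Volumes are NIfTI-1 (via nibabel), gradient tables are FSL-dialect
``bval``/``bvec`` text files (bvec = 3 rows x N columns), streamlines are
TCK (default) or TRK containers with points in world millimetres, and
cohort designs are CSV/TSV tables.

Conventions: voxel indexing is 0-based; ``point_world = affine @ [i, j, k, 1]``
maps a voxel index to the world position of that voxel's centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "GradientScheme",
    "ImageVolume",
    "MaskVolume",
    "CohortDesign",
    "StreamlineSet",
    "voxel_to_world",
    "world_to_voxel",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "read_scalar",
    "write_scalar",
    "read_streamlines",
    "write_streamlines",
    "read_design",
    "write_design",
    "load_config",
    "save_config",
]

#: tolerance on the Euclidean norm of diffusion-weighted gradient directions
UNIT_NORM_TOL = 1e-6


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


@dataclass
class GradientScheme:
    """Per-volume diffusion weightings and gradient directions.

    Parameters
    ----------
    bvals : (N,) array
        b-value of each volume in s/mm^2.
    bvecs : (N, 3) array
        Unit gradient direction for each b > 0 volume; zero vector for
        b = 0 volumes.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3); got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"bvals has {len(self.bvals)} entries but bvecs has "
                f"{len(self.bvecs)}"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > UNIT_NORM_TOL):
            bad = np.where(dw & (np.abs(norms - 1.0) > UNIT_NORM_TOL))[0]
            raise ValidationError(
                f"non-unit gradient direction(s) at volume(s) {bad.tolist()}"
            )
        if np.any(norms[~dw] > UNIT_NORM_TOL):
            raise ValidationError("b=0 volumes must carry a zero direction")
        if not np.any(~dw):
            raise ValidationError("scheme needs at least one b=0 volume")
        if self.n_distinct_directions < 6:
            raise ValidationError(
                "scheme needs at least 6 distinct b>0 directions for tensor "
                f"fitting; got {self.n_distinct_directions}"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dw_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def n_distinct_directions(self) -> int:
        """Number of distinct b>0 directions, identifying g with -g."""
        dirs = self.bvecs[self.dw_mask]
        # canonicalize sign so antipodal pairs collapse
        sign = np.where(
            dirs[:, 0] != 0,
            np.sign(dirs[:, 0]),
            np.where(dirs[:, 1] != 0, np.sign(dirs[:, 1]), np.sign(dirs[:, 2])),
        )
        canon = np.round(dirs * sign[:, None], 5)
        return len(np.unique(canon, axis=0))


@dataclass
class ImageVolume:
    """A 3-D scalar lattice or 4-D intensity lattice with a world affine."""

    data: np.ndarray
    affine: np.ndarray
    units: str = ""
    scheme: GradientScheme | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4; got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValidationError("affine is not invertible")
        if self.scheme is not None:
            if self.data.ndim != 4:
                raise ValidationError("a gradient scheme requires 4-D data")
            if self.data.shape[3] != len(self.scheme):
                raise FormatError(
                    f"image has {self.data.shape[3]} volumes but scheme has "
                    f"{len(self.scheme)}"
                )

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class MaskVolume:
    """A binary 3-D region with the same spatial conventions as ImageVolume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("mask values must be 0 or 1")
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4; got {self.affine.shape}")
        if self.data.ndim != 3:
            raise ValidationError("mask must be 3-D")
        if not self.data.any():
            raise ValidationError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class CohortDesign:
    """Subject table: group labels and nuisance covariates.

    The canonical covariates are age (years), gender (0/1 coded) and
    mask_voxels (brain-mask voxel count in native space).
    """

    table: pd.DataFrame
    covariate_names: tuple = ("age", "gender", "mask_voxels")

    def __post_init__(self) -> None:
        required = {"id", "group", *self.covariate_names}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table is missing columns {sorted(missing)}")
        if self.table[list(required)].isna().any().any():
            raise ValidationError("design table has missing values")
        counts = self.table["group"].value_counts()
        if len(counts) < 2:
            raise ValidationError("design needs at least 2 groups")
        small = counts[counts < 2]
        if len(small):
            raise ValidationError(
                f"group(s) with fewer than 2 subjects: {small.index.tolist()}"
            )

    @property
    def groups(self) -> list:
        return sorted(self.table["group"].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def group_labels(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    def covariates(self) -> np.ndarray:
        return self.table[list(self.covariate_names)].to_numpy(dtype=float)


@dataclass
class StreamlineSet:
    """An ordered collection of streamlines, points in world mm.

    ``affine`` records the voxel grid the streamlines were generated on
    (provenance only — points are already in world coordinates).
    """

    streamlines: list
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float).reshape(-1, 3) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]


# ---------------------------------------------------------------------------
# coordinate helpers


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices (…, 3) to world mm coordinates."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map world mm coordinates (…, 3) to continuous voxel indices."""
    inv = np.linalg.inv(affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


# ---------------------------------------------------------------------------
# DWI + gradient table


def read_dwi(
    image_path, bval_path, bvec_path, bvec_flip: tuple = (1, 1, 1)
) -> tuple[ImageVolume, GradientScheme]:
    """Load a 4-D DWI NIfTI together with its FSL bval/bvec gradient table.

    ``bvec_flip`` multiplies the gradient axes by ±1 — scanner exports
    disagree on the bvec sign convention, and a wrong sign silently
    mirrors every fitted fibre orientation.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected 4-D DWI; got shape {data.shape}")
    bvals = np.loadtxt(str(bval_path), ndmin=1)
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        pass  # ambiguous but row-per-axis FSL dialect assumed; 3 volumes
    elif bvecs.shape[1] != 3:
        raise FormatError(f"bvec table must be 3 x N; got {bvecs.shape}")
    if len(bvals) != data.shape[3]:
        raise FormatError(
            f"bval file has {len(bvals)} entries but image has "
            f"{data.shape[3]} volumes"
        )
    bvecs = bvecs * np.asarray(bvec_flip, dtype=float)[None, :]
    scheme = GradientScheme(bvals=bvals, bvecs=bvecs)
    vol = ImageVolume(data=data, affine=np.asarray(img.affine), scheme=scheme)
    return vol, scheme


def write_dwi(volume: ImageVolume, scheme: GradientScheme, image_path, bval_path, bvec_path) -> None:
    if volume.data.ndim != 4 or volume.data.shape[3] != len(scheme):
        raise FormatError("volume 4th axis must match scheme length")
    nib.save(nib.Nifti1Image(volume.data.astype(np.float64), volume.affine), str(image_path))
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.8f")


def read_mask(path) -> MaskVolume:
    img = nib.load(str(path))
    return MaskVolume(data=np.asarray(img.dataobj) > 0.5, affine=np.asarray(img.affine))


def write_mask(mask: MaskVolume, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def read_scalar(path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(data=np.asarray(img.dataobj, dtype=float), affine=np.asarray(img.affine))


def write_scalar(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


# ---------------------------------------------------------------------------
# streamlines (TCK default; TRK when the extension says so)


def write_streamlines(streamlines, path, reference: ImageVolume | MaskVolume | None = None) -> None:
    """Write streamlines (world mm points) to a TCK or TRK container.

    TCK is the default container (points stored in RAS mm, no grid header);
    TRK additionally needs a reference volume for its header.  An empty
    streamline set writes a valid container with count 0.
    """
    path = Path(path)
    sl = list(streamlines)
    tractogram = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        if reference is None:
            raise ValueError("TRK output needs a reference volume for its header")
        header = {
            nib.streamlines.Field.VOXEL_TO_RASMM: np.asarray(reference.affine, dtype=np.float32),
            nib.streamlines.Field.VOXEL_SIZES: reference.voxel_size.astype(np.float32),
            nib.streamlines.Field.DIMENSIONS: np.asarray(reference.data.shape[:3], dtype=np.int16),
        }
        nib.streamlines.save(tractogram, str(path), header=header)
    else:
        nib.streamlines.save(tractogram, str(path))


def read_streamlines(path) -> StreamlineSet:
    tf = nib.streamlines.load(str(path))
    return StreamlineSet(streamlines=[np.asarray(s) for s in tf.streamlines])


# ---------------------------------------------------------------------------
# cohort design tables


def read_design(table_path) -> CohortDesign:
    """Read a delimited subject table with columns id, group, age, gender, mask_voxels."""
    path = Path(table_path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    return CohortDesign(table=table)


def write_design(design: CohortDesign, table_path) -> None:
    path = Path(table_path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    design.table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# pipeline configuration


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
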