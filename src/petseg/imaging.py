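"""Geometry-aware PET volume containers, NIfTI I/O, SUV conversion and VOI arithmetic.

All physical computations in this package (spheres, shells, dilation,
gradients) work in millimetre space derived from the voxel spacing; voxel
indices are 0-based and voxel centers sit at ``index * spacing``.  NIfTI
affines are preserved opaquely on round-trip but never interpreted: nothing
in the analysis needs patient-space orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Unit",
    "SUVImage",
    "BinaryMask",
    "PatientMeta",
    "read_volume",
    "read_mask",
    "write_volume",
    "to_suv",
    "mask_volume_ml",
    "dilate_mask",
    "read_patient_meta_csv",
]


class Unit(str, Enum):
    """Voxel-value unit of a PET volume."""

    BQ_PER_ML = "Bq/mL"
    SUV = "SUV"


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive and finite, got {spacing}")
    return spacing


@dataclass(eq=False)
class SUVImage:
    """A 3-D scalar PET grid with anisotropic voxel spacing in mm.

    Parameters
    ----------
    values
        3-D array of voxel values (coerced to float64).
    spacing
        (dx, dy, dz) voxel pitch in mm, strictly positive.
    unit
        Whether the values are activity concentration (Bq/mL) or SUV.
    affine
        Optional NIfTI affine, carried opaquely for round-trip fidelity.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    unit: Unit = Unit.SUV
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got {self.values.ndim}-D")
        if self.values.size == 0:
            raise ValueError("volume grid is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)
        self.unit = Unit(self.unit)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(eq=False)
class BinaryMask:
    """A 3-D boolean VOI sharing an :class:`SUVImage`'s geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got {self.values.ndim}-D")
        if self.values.size == 0:
            raise ValueError("mask grid is empty")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def require_same_geometry(a, b) -> None:
    """Raise ValueError unless two grids share shape and spacing."""
    if a.values.shape != b.values.shape:
        raise ValueError(f"shape mismatch: {a.values.shape} vs {b.values.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


@dataclass(frozen=True)
class PatientMeta:
    """Injected activity and body weight used for SUV normalization.

    SUV = concentration / (injected_activity / body_weight), with activity in
    Bq and weight in g, so SUV is dimensionless for Bq/mL input (1 g ~ 1 mL
    tissue density convention).
    """

    injected_activity_bq: float
    body_weight_g: float
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not self.injected_activity_bq > 0:
            raise ValueError("injected activity must be > 0")
        if not self.body_weight_g > 0:
            raise ValueError("body weight must be > 0")


def read_patient_meta_csv(path) -> list[PatientMeta]:
    """Read patient metadata from a CSV with columns id, injected_activity_MBq, weight_kg."""
    df = pd.read_csv(path)
    required = {"id", "injected_activity_MBq", "weight_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV is missing columns: {sorted(missing)}")
    return [
        PatientMeta(
            injected_activity_bq=float(row.injected_activity_MBq) * 1e6,
            body_weight_g=float(row.weight_kg) * 1e3,
            patient_id=str(row.id),
        )
        for row in df.itertuples()
    ]


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    spacing = _check_spacing(zooms)
    return data, spacing, img.affine


def read_volume(path, unit: Unit = Unit.SUV) -> SUVImage:
    """Read a 3-D NIfTI volume; spacing comes from the header zooms.

    The unit is not encoded in NIfTI, so it must be stated by the caller
    (default SUV).
    """
    data, spacing, affine = _load_nifti(path)
    return SUVImage(values=data, spacing=spacing, unit=unit, affine=affine)


def read_mask(path) -> BinaryMask:
    """Read a binary VOI from NIfTI; values must be coded 0/1."""
    data, spacing, affine = _load_nifti(path)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{path}: mask values must be 0/1, found {uniq[:10]}")
    return BinaryMask(values=data > 0, spacing=spacing, affine=affine)


def write_volume(obj: SUVImage | BinaryMask, path) -> None:
    """Write an image (float64) or mask (uint8 coded 0/1) to NIfTI.

    Round-trip preserves grid values bit-exactly and the spacing to float
    precision.
    """
    path = Path(path)
    if isinstance(obj, BinaryMask):
        data = obj.values.astype(np.uint8)
    elif isinstance(obj, SUVImage):
        data = obj.values
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    affine = obj.affine
    if affine is None:
        affine = np.diag(list(obj.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(obj.spacing)
    nib.save(img, str(path))


def to_suv(image: SUVImage, meta: PatientMeta) -> SUVImage:
    """Convert an activity-concentration image (Bq/mL) to SUV.

    Each voxel v becomes v / (injected_activity / body_weight); the bare
    body-weight ratio, with decay correction assumed already applied in the
    input image.
    """
    if image.unit is Unit.SUV:
        raise ValueError("image is already in SUV; refusing to convert twice")
    factor = meta.injected_activity_bq / meta.body_weight_g
    return SUVImage(
        values=image.values / factor,
        spacing=image.spacing,
        unit=Unit.SUV,
        affine=image.affine,
    )


def mask_volume_ml(mask: BinaryMask) -> float:
    """Metabolically active tumor volume of a VOI in mL (1 mL = 1000 mm^3)."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def dilate_mask(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Spacing-aware Euclidean dilation: include every voxel whose center lies
    within ``radius_mm`` of a mask voxel's center.  Output is a superset of the
    input; radius 0 is the identity."""
    if radius_mm < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius_mm == 0 or not mask.values.any():
        return BinaryMask(values=mask.values.copy(), spacing=mask.spacing, affine=mask.affine)
    dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
    return BinaryMask(values=dist <= radius_mm, spacing=mask.spacing, affine=mask.affine)
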