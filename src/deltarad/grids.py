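"""Volumes, masks and sessions on axis-aligned physical grids.

All images live on axis-aligned grids: the physical position of voxel
index ``(i, j, k)`` is ``origin + index * spacing`` (millimetres, identity
direction cosines).  CT volumes carry Hounsfield units, PET volumes carry
standardized uptake values (SUV, unitless).  Masks delimit the gross tumor
volume (GTV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

Modality = Literal["CT", "SUV"]
Timepoint = Literal["pre", "mid", "post"]

CT_BACKGROUND_HU = -1000.0
SUV_BACKGROUND = 0.0


class DimensionalityError(ValueError):
    """Raised when an image is not a 3D scalar volume."""


@dataclass
class VolumeGrid:
    """A 3D scalar field with physical spacing and origin.

    ``voxels[i, j, k]`` sits at physical position ``origin + (i, j, k) * spacing``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = "CT"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.voxels.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm3."""
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def same_grid(self, other: "VolumeGrid | RoiMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class RoiMask:
    """Binary 3D mask aligned to a :class:`VolumeGrid`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D mask, got {self.mask.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def same_grid(self, other: "VolumeGrid | RoiMask", tol: float = 1e-6) -> bool:
        return VolumeGrid.same_grid(self, other, tol)  # type: ignore[arg-type]


@dataclass
class ScanSession:
    """One patient x one timepoint bundle: CT, SUV and the GTV on each grid."""

    patient_id: str
    timepoint: Timepoint
    ct: VolumeGrid
    suv: VolumeGrid
    gtv_ct: RoiMask
    gtv_suv: RoiMask

    def __post_init__(self) -> None:
        if not self.gtv_ct.same_grid(self.ct):
            raise ValueError(f"{self.patient_id}/{self.timepoint}: gtv_ct not aligned to ct")
        if not self.gtv_suv.same_grid(self.suv):
            raise ValueError(f"{self.patient_id}/{self.timepoint}: gtv_suv not aligned to suv")


@dataclass
class CohortTable:
    """Patient ids with binary recurrence labels (1 = recurrence)."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["patient_id", "recurrence"]))

    def __post_init__(self) -> None:
        t = self.table
        if not {"patient_id", "recurrence"} <= set(t.columns):
            raise ValueError("cohort table needs patient_id and recurrence columns")
        if t["patient_id"].duplicated().any():
            raise ValueError("duplicate patient ids in cohort table")
        if not t["recurrence"].isin([0, 1]).all():
            raise ValueError("recurrence labels must be 0/1")

    @property
    def patient_ids(self) -> list[str]:
        return [str(p) for p in self.table["patient_id"]]

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            self.table["recurrence"].to_numpy(int),
            index=[str(p) for p in self.table["patient_id"]],
            name="recurrence",
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# File I/O


def _infer_format(path: str | Path) -> str:
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise ValueError(f"cannot infer image format from {path!r}")


def read_volume(path: str | Path, format: str | None = None,
                modality: Modality = "CT") -> VolumeGrid:
    """Read a NIfTI or NRRD volume into a :class:`VolumeGrid`.

    Spacing and origin come from the header; voxel values pass through
    unchanged (HU for CT, SUV for PET).
    """
    fmt = format or _infer_format(path)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise DimensionalityError(f"{path}: expected 3D image, got {data.ndim}D")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return VolumeGrid(data, spacing, origin, modality)
    if fmt == "nrrd":
        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise DimensionalityError(
                f"{path}: expected 3D image, got {img.GetDimension()}D")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return VolumeGrid(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()),
                          modality)
    raise ValueError(f"unknown format {fmt!r}")


def write_volume(vol: VolumeGrid, path: str | Path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(vol.voxels), affine), str(path))
    elif fmt == "nrrd":
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.asarray(vol.voxels).transpose(2, 1, 0)))
        img.SetSpacing(vol.spacing)
        img.SetOrigin(vol.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_mask(path: str | Path, format: str | None = None) -> RoiMask:
    """Read an integer image (foreground = 1) as a binary ROI mask."""
    vol = read_volume(path, format)
    return RoiMask(vol.voxels > 0.5, vol.spacing, vol.origin)


def write_mask(mask: RoiMask, path: str | Path, format: str | None = None) -> None:
    write_volume(
        VolumeGrid(mask.mask.astype(np.uint8), mask.spacing, mask.origin), path, format
    )


# ---------------------------------------------------------------------------
# SUV conversion


def suv_from_activity(concentration_kbq_ml: np.ndarray | float,
                      body_weight_kg: float,
                      injected_dose_mbq: float) -> np.ndarray | float:
    """Convert decay-corrected activity concentration to body-weight SUV.

    SUV = concentration [kBq/mL] x body weight [g] / injected dose [kBq],
    assuming tissue density 1 g/mL, hence unitless:

        SUV = c * (w * 1000) / (D * 1000) = c * w / D
    """
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg}")
    if injected_dose_mbq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_mbq}")
    c = np.asarray(concentration_kbq_ml, dtype=float)
    if np.any(c < 0):
        raise ValueError("activity concentrations must be non-negative")
    suv = c * body_weight_kg / injected_dose_mbq
    return float(suv) if np.isscalar(concentration_kbq_ml) else suv


# ---------------------------------------------------------------------------
# Resampling between grids (shared physical frame, axis-aligned)


def _index_coords_in_source(target: VolumeGrid | RoiMask,
                            source: VolumeGrid | RoiMask) -> np.ndarray:
    """Fractional source-index coordinates of every target voxel center."""
    idx = np.indices(target.shape, dtype=float)
    coords = np.empty_like(idx)
    for a in range(3):
        phys = target.origin[a] + idx[a] * target.spacing[a]
        coords[a] = (phys - source.origin[a]) / source.spacing[a]
    return coords


def resample_mask(mask: RoiMask, target: VolumeGrid | RoiMask) -> RoiMask:
    """Nearest-neighbor resample of a mask onto the target grid."""
    if mask.same_grid(target):
        return RoiMask(mask.mask.copy(), mask.spacing, mask.origin)
    coords = _index_coords_in_source(target, mask)
    nearest = np.round(coords).astype(int)
    inside = np.ones(target.shape, dtype=bool)
    for a in range(3):
        inside &= (nearest[a] >= 0) & (nearest[a] < mask.shape[a])
    out = np.zeros(target.shape, dtype=bool)
    if inside.any():
        n = tuple(np.clip(nearest[a], 0, mask.shape[a] - 1) for a in range(3))
        out[inside] = mask.mask[n[0][inside], n[1][inside], n[2][inside]]
    result = RoiMask(out, target.spacing, target.origin)
    if mask.n_foreground > 0 and result.n_foreground == 0:
        warnings.warn("resampled mask is empty: source foreground lies outside "
                      "the target extent", stacklevel=2)
    return result


def resample_volume(vol: VolumeGrid, target: VolumeGrid | RoiMask,
                    background: float | None = None) -> VolumeGrid:
    """Trilinear resample of a volume onto the target grid.

    Voxels outside the source extent are filled with ``background``
    (default -1000 HU for CT, 0 for SUV).
    """
    if background is None:
        background = CT_BACKGROUND_HU if vol.modality == "CT" else SUV_BACKGROUND
    if vol.same_grid(target):
        return VolumeGrid(vol.voxels.copy(), vol.spacing, vol.origin, vol.modality)
    coords = _index_coords_in_source(target, vol)
    out = ndimage.map_coordinates(
        vol.voxels.astype(float), coords.reshape(3, -1), order=1,
        mode="constant", cval=background,
    ).reshape(target.shape)
    outside = np.zeros(target.shape, dtype=bool)
    for a in range(3):
        outside |= (coords[a] < 0) | (coords[a] > vol.shape[a] - 1)
    out[outside] = background
    if outside.all():
        warnings.warn("target grid lies entirely outside the source extent",
                      stacklevel=2)
    return VolumeGrid(out, target.spacing, target.origin, vol.modality)
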