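"""NIfTI volume/mask input-output and geometric validation.

The package operates entirely in voxel space on a single grid per case:
a scalar intensity volume, a binary tumor mask, and (optionally) a binary
body mask, all with identical shape and voxel spacing. No resampling or
reorientation is performed; all physical quantities (mm, mm^2, mm^3) are
derived from the voxel spacing recorded in the NIfTI headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import EmptyRegionError, GeometryError, MaskEncodingError

#: maximum per-axis spacing disagreement (mm) tolerated between a volume
#: and its masks; beyond this the pair is rejected as geometrically
#: inconsistent rather than silently corrupting every mm^3 quantity.
SPACING_ATOL_MM = 1e-3

MANIFEST_REQUIRED_COLUMNS = ("case_id", "cohort_label", "volume_path", "tumor_mask_path")


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with per-axis voxel spacing in mm.

    Axes are (x, y, z) in voxel index order throughout the package.
    Intensities are in arbitrary scanner units; only ratiometric
    quantities derived from them are comparable across exams.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(f"volume must be 3D with nonempty axes, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must all be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths (mm), got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class RegionMask:
    """A binary voxel mask on the same grid as its paired :class:`ImageVolume`."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3 or min(self.mask.shape) < 1:
            raise GeometryError(f"mask must be 3D with nonempty axes, got shape {self.mask.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths (mm), got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


def volume_of(mask: RegionMask) -> float:
    """Physical volume of a mask in mm^3 (voxel count x voxel volume)."""
    return mask.voxel_count * mask.voxel_volume_mm3


def _read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), zooms


def load_volume(path: str | Path) -> ImageVolume:
    """Load a scalar NIfTI volume with spacing taken from the header."""
    data, zooms = _read_nifti(path)
    return ImageVolume(data=data.astype(np.float64), spacing=zooms)


def load_mask(path: str | Path, *, allow_empty: bool = False) -> RegionMask:
    """Load a binary NIfTI mask.

    The file may encode the mask with any two distinct values (0/1, 0/255,
    ...); the smaller value is treated as background. Three or more
    distinct values indicate a label map, not a binary mask, and raise
    :class:`MaskEncodingError`.
    """
    data, zooms = _read_nifti(path)
    values = np.unique(data)
    if len(values) > 2:
        raise MaskEncodingError(
            f"{path}: mask has {len(values)} distinct values {values[:5]}...; expected a binary mask"
        )
    if len(values) == 1:
        mask = np.zeros(data.shape, dtype=bool) if values[0] == 0 else np.ones(data.shape, dtype=bool)
    else:
        mask = data == values.max()
    if not allow_empty and not mask.any():
        raise EmptyRegionError(f"{path}: mask is empty")
    return RegionMask(mask=mask, spacing=zooms)


def _check_same_grid(volume: ImageVolume, mask: RegionMask, name: str) -> None:
    if volume.shape != mask.shape:
        raise GeometryError(f"{name} shape {mask.shape} does not match volume shape {volume.shape}")
    if any(abs(a - b) > SPACING_ATOL_MM for a, b in zip(volume.spacing, mask.spacing)):
        raise GeometryError(
            f"{name} spacing {mask.spacing} disagrees with volume spacing {volume.spacing} "
            f"beyond {SPACING_ATOL_MM} mm"
        )


def load_case(
    volume_path: str | Path,
    tumor_mask_path: str | Path,
    body_mask_path: str | Path | None = None,
) -> tuple[ImageVolume, RegionMask, RegionMask | None]:
    """Load one case: intensity volume, tumor mask, optional body mask.

    All images must share one voxel grid (identical shape; header spacings
    agreeing within :data:`SPACING_ATOL_MM` per axis). Mask values are
    coerced to boolean. The tumor mask must be nonempty.
    """
    volume = load_volume(volume_path)
    tumor = load_mask(tumor_mask_path, allow_empty=False)
    _check_same_grid(volume, tumor, "tumor mask")
    # after validation, trust the volume's spacing for all physical units
    tumor.spacing = volume.spacing
    body: RegionMask | None = None
    if body_mask_path is not None:
        body = load_mask(body_mask_path, allow_empty=False)
        _check_same_grid(volume, body, "body mask")
        body.spacing = volume.spacing
    return volume, tumor, body


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` to NIfTI with a diagonal affine."""
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_mask(mask: RegionMask, path: str | Path) -> None:
    """Write a :class:`RegionMask` to NIfTI as uint8 {0, 1}."""
    affine = np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def save_label_map(labels: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Write an integer label map (e.g. 1=tumor, 2=adipose, 3=fibroglandular)."""
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.uint8), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a per-case manifest CSV.

    Required columns: case_id, cohort_label, volume_path, tumor_mask_path.
    Optional column: body_mask_path (empty entries mean "no body mask").
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing required columns {missing}")
    if "body_mask_path" not in table.columns:
        table["body_mask_path"] = None
    base = path.parent
    for col in ("volume_path", "tumor_mask_path", "body_mask_path"):
        table[col] = [
            str(base / p) if isinstance(p, str) and p and not Path(p).is_absolute() else p
            for p in table[col]
        ]
    return table
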