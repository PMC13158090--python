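"""Equal-volume boundary shells and tumor size/shape metrics.

The boundary shell is the layer of non-tumor voxels immediately
surrounding a tumor segmentation, grown outward in spacing-aware
Euclidean distance until its physical volume first matches the tumor's
physical volume. Matching the volumes makes the mean-intensity
comparison between tumor and boundary a comparison of equally sized
samples, so the normalized contrast is not biased by an arbitrary
margin-thickness choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .errors import EmptyRegionError, GeometryError, NoBoundaryError
from .volume_io import ImageVolume, RegionMask, volume_of

#: 6-connectivity structuring element used for surface-voxel detection.
_FACE_STRUCTURE = ndi.generate_binary_structure(3, 1)


@dataclass
class BoundaryShell:
    """A boundary shell around a tumor mask.

    Attributes
    ----------
    mask:
        The shell voxels (disjoint from the tumor).
    tumor:
        The tumor mask the shell was grown from.
    thickness_mm:
        Realized margin thickness: the largest voxel-center distance from
        the tumor included in the shell.
    tumor_volume_mm3, shell_volume_mm3:
        Physical volumes. ``shell_volume_mm3 >= tumor_volume_mm3`` unless
        ``volume_deficit`` is set.
    volume_deficit:
        True when the eligible region (grid, or body mask if given) was
        exhausted before the shell could reach the tumor volume.
    """

    mask: RegionMask
    tumor: RegionMask
    thickness_mm: float
    tumor_volume_mm3: float
    shell_volume_mm3: float
    volume_deficit: bool = False


@dataclass
class ShapeMetrics:
    """Tumor size and shape descriptors.

    ``sphericity`` is (pi^(1/3) * (6V)^(2/3)) / A with the surface area A
    obtained by exposed-face counting. Face counting overestimates the
    area of smooth shapes (a digitized ball tends to A = 1.5 * 4*pi*r^2,
    giving sphericity -> 2/3 rather than 1), so sphericity here is a
    consistent relative shape index, not an absolute one.
    """

    volume_mm3: float
    max_extent_mm: float
    surface_area_mm2: float
    sphericity: float


def tumor_distance_map(tumor: RegionMask) -> np.ndarray:
    """Spacing-aware Euclidean distance from every voxel to the nearest tumor voxel.

    Distances are between voxel centers (zero inside the tumor); the
    anisotropic spacing enters via the distance-transform sampling so a
    2 mm slice step is not treated like a 1 mm in-plane step.
    """
    if not tumor.mask.any():
        raise EmptyRegionError("tumor mask is empty")
    return ndi.distance_transform_edt(~tumor.mask, sampling=tumor.spacing)


def build_boundary_shell(
    tumor: RegionMask,
    volume: ImageVolume | None = None,
    body: RegionMask | None = None,
) -> BoundaryShell:
    """Grow the equal-volume boundary shell around a tumor mask.

    The shell comprises all eligible non-tumor voxels whose center lies
    within distance t* of the tumor, where t* is the smallest distance
    stratum at which the shell's physical volume first reaches the
    tumor's physical volume. The final stratum is always included whole
    (deterministic; no random sub-sampling), so the shell can overshoot
    the tumor volume by at most one stratum.

    Parameters
    ----------
    tumor:
        Nonempty tumor mask.
    volume:
        Optional intensity volume; used only to verify the grids agree.
    body:
        Optional body mask restricting eligible shell voxels (e.g. to
        exclude air outside the breast). Without it the whole grid is
        eligible.
    """
    if not tumor.mask.any():
        raise EmptyRegionError("tumor mask is empty")
    if volume is not None and volume.shape != tumor.shape:
        raise GeometryError(f"tumor mask shape {tumor.shape} does not match volume shape {volume.shape}")
    if body is not None and body.shape != tumor.shape:
        raise GeometryError(f"body mask shape {body.shape} does not match tumor shape {tumor.shape}")

    eligible = ~tumor.mask
    if body is not None:
        eligible &= body.mask
    if not eligible.any():
        raise NoBoundaryError("tumor fills the entire eligible region; no boundary voxels exist")

    distance = tumor_distance_map(tumor)
    voxvol = tumor.voxel_volume_mm3
    tumor_volume = volume_of(tumor)

    dist_eligible = distance[eligible]
    strata, counts = np.unique(dist_eligible, return_counts=True)
    cumulative_volume = np.cumsum(counts) * voxvol

    if cumulative_volume[-1] < tumor_volume:
        t_star = float(strata[-1])
        deficit = True
    else:
        idx = int(np.searchsorted(cumulative_volume, tumor_volume))
        t_star = float(strata[idx])
        deficit = False

    shell_mask = eligible & (distance <= t_star)
    shell = RegionMask(mask=shell_mask, spacing=tumor.spacing)
    return BoundaryShell(
        mask=shell,
        tumor=tumor,
        thickness_mm=t_star,
        tumor_volume_mm3=tumor_volume,
        shell_volume_mm3=volume_of(shell),
        volume_deficit=deficit,
    )


def surface_voxels(mask: RegionMask) -> np.ndarray:
    """Boolean array of mask voxels with at least one non-mask face neighbor.

    Voxels on the grid border count as surface (out-of-grid is non-mask).
    """
    eroded = ndi.binary_erosion(mask.mask, structure=_FACE_STRUCTURE, border_value=0)
    return mask.mask & ~eroded


def surface_area_mm2(mask: RegionMask) -> float:
    """Surface area by exposed-face counting.

    Each voxel face adjoining a non-mask voxel (or the grid border)
    contributes its face area; faces normal to axis i have area equal to
    the product of the other two spacings.
    """
    m = mask.mask
    sx, sy, sz = mask.spacing
    face_area = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, area in enumerate(face_area):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)], constant_values=False)
        exposed = np.diff(padded.astype(np.int8), axis=axis) != 0
        total += exposed.sum() * area
    return float(total)


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Exact diameter of a point set (mm coordinates)."""
    n = len(points)
    if n == 1:
        return 0.0
    if n > 1500:
        # the diameter is attained between convex-hull vertices
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets stay brute-force
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def max_extent_mm(mask: RegionMask) -> float:
    """Largest pairwise Euclidean distance between voxel centers (mm).

    Computed over surface voxels only; the maximum over the full set is
    attained on the surface.
    """
    if not mask.mask.any():
        raise EmptyRegionError("mask is empty")
    surf = surface_voxels(mask)
    coords = np.argwhere(surf).astype(np.float64) * np.asarray(mask.spacing)
    return _max_pairwise_distance(coords)


def shape_metrics(tumor: RegionMask) -> ShapeMetrics:
    """Volume, maximum extent, face-count surface area, and sphericity."""
    if not tumor.mask.any():
        raise EmptyRegionError("tumor mask is empty")
    volume = volume_of(tumor)
    area = surface_area_mm2(tumor)
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    return ShapeMetrics(
        volume_mm3=volume,
        max_extent_mm=max_extent_mm(tumor),
        surface_area_mm2=area,
        sphericity=sphericity,
    )
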