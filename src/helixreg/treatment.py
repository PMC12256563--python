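"""Treatment-zone segmentation and targeting-error measurement.

After a bubble-cloud treatment the alternating agar/barium layers mix into a
region of homogeneous attenuation. That region is segmented from the
post-treatment CBCT with a seeded region grower (a documented stand-in for the
interactive grow-cut segmentation used clinically), followed by the standard
post-processing chain: keep the largest connected component, median-smooth,
and morphologically close / fill holes with a 1 mm kernel.

Targeting accuracy is the vector from planned target to observed zone
centroid: signed directional errors on the CBCT axes (-Z points toward the
transducer) and their Euclidean norm, the target registration error (TRE).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SegmentationError
from .volume import VoxelVolume

__all__ = [
    "TreatmentMeasurement",
    "segment_treatment_zone",
    "postprocess_mask",
    "measure_targeting",
]

_KERNEL_MM = 1.0


@dataclass(frozen=True)
class TreatmentMeasurement:
    """Planned vs. observed treatment location (all mm, CBCT frame)."""

    planned_target: np.ndarray
    observed_centroid: np.ndarray
    directional_error: np.ndarray  # observed - planned
    tre: float

    @property
    def unsigned_error(self) -> np.ndarray:
        return np.abs(self.directional_error)


def _ball(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Ellipsoidal structuring element covering ``radius_mm`` in every axis."""
    r_vox = np.maximum(np.rint(radius_mm / spacing).astype(int), 1)
    grids = np.ogrid[tuple(slice(-int(r), int(r) + 1) for r in r_vox)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm**2 + 1e-9


def _median_size(spacing: np.ndarray, kernel_mm: float = _KERNEL_MM) -> tuple[int, ...]:
    # odd kernel covering at least kernel_mm in every axis
    size = np.maximum(np.rint(kernel_mm / spacing).astype(int), 1)
    size += 1 - size % 2
    return tuple(int(s) for s in size)


def postprocess_mask(mask: np.ndarray, spacing, kernel_mm: float = _KERNEL_MM) -> np.ndarray:
    """Largest component -> median smoothing -> 1 mm closing and hole fill."""
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.reshape(-1))[1:]
    mask = labels == (int(np.argmax(counts)) + 1)
    mask = ndimage.median_filter(mask, size=_median_size(spacing, kernel_mm))
    ball = _ball(kernel_mm, spacing)
    mask = ndimage.binary_closing(mask, structure=ball)
    mask = ndimage.binary_fill_holes(mask)
    return mask


def segment_treatment_zone(
    post: VoxelVolume,
    seed_point,
    tolerance: float = 400.0,
    kernel_mm: float = _KERNEL_MM,
) -> VoxelVolume:
    """Seeded region growing of the homogenized treatment zone.

    Starting from the voxel containing ``seed_point`` (mm, CBCT frame), voxels
    are added (6-connectivity) while their intensity stays within ``tolerance``
    of the running mean of the grown region, then the post-processing chain of
    :func:`postprocess_mask` is applied. Returns the binary mask as a
    VoxelVolume sharing the input geometry.

    ``tolerance`` should sit between the image noise level and half the
    layer-to-layer contrast.
    """
    seed_idx = post.world_to_voxel_rounded(seed_point)
    data = post.data
    mask = np.zeros(post.shape, dtype=bool)
    queue: deque[tuple[int, int, int]] = deque()
    running_sum = 0.0
    count = 0

    def admit(idx: tuple[int, int, int]) -> None:
        nonlocal running_sum, count
        mask[idx] = True
        running_sum += float(data[idx])
        count += 1
        queue.append(idx)

    admit(seed_idx)
    shape = post.shape
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                continue
            if mask[ni, nj, nk]:
                continue
            if abs(float(data[ni, nj, nk]) - running_sum / count) <= tolerance:
                admit((ni, nj, nk))

    mask = postprocess_mask(mask, post.spacing, kernel_mm)
    if not mask.any():
        raise SegmentationError("region growing produced an empty segmentation")
    return VoxelVolume(mask, post.spacing.copy(), post.origin.copy(), frame=post.frame)


def measure_targeting(mask: VoxelVolume, planned_target) -> TreatmentMeasurement:
    """Directional and Euclidean targeting errors of a segmented treatment.

    The observed centroid is the unweighted mean world position of mask
    voxels; the directional error is observed minus planned on the CBCT axes
    and the TRE its Euclidean norm.
    """
    if not mask.data.any():
        raise SegmentationError("mask is empty")
    planned = np.asarray(planned_target, dtype=float).reshape(3)
    idx = np.argwhere(mask.data)
    observed = mask.origin + idx.mean(axis=0) * mask.spacing
    directional = observed - planned
    return TreatmentMeasurement(
        planned_target=planned,
        observed_centroid=observed,
        directional_error=directional,
        tre=float(np.linalg.norm(directional)),
    )
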