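"""Fiducial segmentation from CBCT volumes.

Fiducials are segmented with a global intensity threshold at a high percentile
of the volume histogram (the stainless-steel markers are by far the brightest
voxels), followed by 26-connected component analysis. Each component yields a
geometric (unweighted) centroid in world mm and an equivalent diameter — the
diameter of the sphere with the same volume as the component. Components are
then split into small/large classes at 2.25 mm, halfway between the 1.5 mm and
3 mm marker sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .phantom import ModelFiducial
from .volume import VoxelVolume

__all__ = [
    "DetectedFiducial",
    "ThresholdSpec",
    "SIZE_SPLIT_MM",
    "MIN_COMPONENT_VOXELS",
    "compute_threshold",
    "extract_fiducials",
    "classify_sizes",
    "detect_fiducials",
]

#: Small/large equivalent-diameter split (mm).
SIZE_SPLIT_MM = 2.25
#: Components smaller than this are treated as noise and discarded.
MIN_COMPONENT_VOXELS = 4

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DetectedFiducial:
    """A segmented fiducial (f(CBCT)): centroid in CBCT mm plus size info."""

    centroid: np.ndarray
    equivalent_diameter: float
    voxel_count: int
    size_class: str | None = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)

    @property
    def center(self) -> np.ndarray:
        """Alias so detected and model fiducials share an interface."""
        return self.centroid


@dataclass(frozen=True)
class ThresholdSpec:
    """How the global segmentation threshold tau is chosen.

    ``fixed-percentile`` takes the stated percentile of all voxel intensities
    (nearest-rank with ceiling, no interpolation). ``expected-volume`` derives
    the percentile from the number of voxels the visible fiducials are
    expected to occupy: ``100 * (1 - expected_voxels / total_voxels)``.
    """

    percentile: float = 99.99
    mode: str = "fixed-percentile"

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ConfigurationError("percentile must lie strictly in (0, 100)")
        if self.mode not in {"fixed-percentile", "expected-volume"}:
            raise ConfigurationError(f"unknown threshold mode {self.mode!r}")


def expected_volume_percentile(
    volume: VoxelVolume, visible_fiducials: Sequence[ModelFiducial]
) -> float:
    """Percentile such that the mask size matches the expected fiducial volume."""
    expected_mm3 = sum(
        4.0 / 3.0 * math.pi * f.radius**3 for f in visible_fiducials
    )
    expected_voxels = expected_mm3 / volume.voxel_volume_mm3()
    total = volume.data.size
    return 100.0 * (1.0 - expected_voxels / total)


def compute_threshold(
    volume: VoxelVolume,
    spec: ThresholdSpec | None = None,
    visible_fiducials: Sequence[ModelFiducial] | None = None,
) -> float:
    """Global threshold tau for fiducial segmentation.

    Nearest-rank percentile with ceiling: tau is the k-th smallest intensity
    with ``k = ceil(p/100 * N)``. In ``expected-volume`` mode the percentile is
    derived from the sphere volumes of ``visible_fiducials`` (required).
    """
    spec = spec or ThresholdSpec()
    if volume.data.size == 0:
        raise ConfigurationError("volume is empty")
    if spec.mode == "expected-volume":
        if visible_fiducials is None:
            raise ConfigurationError(
                "expected-volume mode requires the visible model fiducials"
            )
        percentile = expected_volume_percentile(volume, visible_fiducials)
    else:
        percentile = spec.percentile
    flat = volume.data.reshape(-1)
    k = math.ceil(percentile / 100.0 * flat.size)
    k = min(max(k, 1), flat.size)
    return float(np.partition(flat, k - 1)[k - 1])


def extract_fiducials(
    volume: VoxelVolume,
    tau: float,
    min_voxels: int = MIN_COMPONENT_VOXELS,
) -> list[DetectedFiducial]:
    """Connected-component extraction of fiducial candidates above ``tau``.

    The mask is ``data > tau`` (strict) under 26-connectivity; components with
    fewer than ``min_voxels`` voxels are discarded as noise. Centroids are
    unweighted means of member-voxel world positions; the equivalent diameter
    is ``(6 * voxel_count * voxel_volume / pi)^(1/3)``. An empty mask yields an
    empty list.
    """
    mask = volume.data > tau
    labels, n_labels = ndimage.label(mask, structure=_STRUCT_26)
    if n_labels == 0:
        return []
    counts = np.bincount(labels.reshape(-1))[1:]
    keep = np.flatnonzero(counts >= min_voxels) + 1
    if keep.size == 0:
        return []
    centroids_idx = ndimage.center_of_mass(mask, labels, keep)
    vox_mm3 = volume.voxel_volume_mm3()
    out = []
    for label, idx in zip(keep, centroids_idx):
        count = int(counts[label - 1])
        centroid = volume.origin + np.asarray(idx) * volume.spacing
        diameter = (6.0 * count * vox_mm3 / math.pi) ** (1.0 / 3.0)
        out.append(
            DetectedFiducial(
                centroid=centroid,
                equivalent_diameter=float(diameter),
                voxel_count=count,
            )
        )
    out.sort(key=lambda f: tuple(f.centroid))
    return out


def classify_sizes(
    fiducials: list[DetectedFiducial], split: float = SIZE_SPLIT_MM
) -> list[DetectedFiducial]:
    """Assign size classes in place: equivalent diameter >= split -> large."""
    for f in fiducials:
        f.size_class = "large" if f.equivalent_diameter >= split else "small"
    return fiducials


def detect_fiducials(
    volume: VoxelVolume,
    spec: ThresholdSpec | None = None,
    visible_fiducials: Sequence[ModelFiducial] | None = None,
    min_voxels: int = MIN_COMPONENT_VOXELS,
    split: float = SIZE_SPLIT_MM,
) -> tuple[list[DetectedFiducial], float]:
    """Threshold -> extract -> classify convenience pipeline.

    Returns the classified fiducials and the threshold used.
    """
    tau = compute_threshold(volume, spec, visible_fiducials)
    fiducials = classify_sizes(extract_fiducials(volume, tau, min_voxels), split)
    return fiducials, tau
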