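"""Voxel-volume container and readers/writers for NRRD, MetaImage and NIfTI.

Conventions
-----------
* ``data`` is indexed ``[i, j, k]`` along world X, Y, Z.
* ``spacing`` and ``origin`` are in mm; the world position of voxel index
  ``(i, j, k)`` is the voxel *center*, ``origin + index * spacing``.
* Only axis-aligned volumes (identity direction matrix) are supported; the
  CBCT isocenter convention used elsewhere places the volume center at the
  world origin.

File access is delegated to SimpleITK.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, UnsupportedGeometryError

__all__ = ["VoxelVolume", "read_volume", "write_volume", "centered_volume"]

_EXTENSIONS = {
    ".nrrd": "nrrd",
    ".mha": "mha",
    ".mhd": "mha",
    ".nii": "nifti",
}


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return "nifti"
    try:
        return _EXTENSIONS[path.suffix.lower()]
    except KeyError:
        raise FormatError(f"unsupported volume extension: {path.name}") from None


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical geometry.

    Attributes
    ----------
    data : (nx, ny, nz) ndarray
        Scalar attenuation values (arbitrary units).
    spacing : (3,) ndarray
        Voxel size in mm, strictly positive.
    origin : (3,) ndarray
        World position (mm) of the center of voxel (0, 0, 0).
    frame : str
        Coordinate-system label; always ``c`` for CBCT volumes.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    frame: str = "c"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of a voxel index (may be fractional)."""
        idx = np.asarray(index, dtype=float)
        flat = idx.reshape(-1, 3)
        if np.any(flat < -0.5) or np.any(flat > np.array(self.shape) - 0.5):
            raise IndexError(f"index {index} out of bounds for shape {self.shape}")
        return self.origin + idx * self.spacing

    def world_to_voxel(self, point) -> np.ndarray:
        """Continuous voxel index of a world point (inverse of voxel_to_world)."""
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def world_to_voxel_rounded(self, point) -> tuple[int, int, int]:
        idx = np.rint(self.world_to_voxel(point)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise IndexError(f"point {point} lies outside the volume")
        return tuple(int(v) for v in idx)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World extent covered by voxel cells (outer edges, not centers)."""
        lo = self.origin - self.spacing / 2.0
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return lo, hi


def centered_volume(data: np.ndarray, spacing) -> VoxelVolume:
    """Wrap an array so the volume center coincides with the world origin."""
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    shape = np.array(data.shape, dtype=float)
    origin = -(shape - 1) / 2.0 * spacing
    return VoxelVolume(data=data, spacing=spacing, origin=origin)


def read_volume(path, format: str | None = None) -> VoxelVolume:
    """Read an NRRD / MetaImage / NIfTI volume.

    Raises
    ------
    FormatError
        If the file cannot be parsed.
    UnsupportedGeometryError
        If the header carries a non-identity direction matrix.
    """
    p = Path(path)
    fmt = format or _detect_format(p)
    if fmt not in {"nrrd", "mha", "nifti"}:
        raise FormatError(f"unknown format {fmt!r}")
    try:
        img = sitk.ReadImage(str(p))
    except RuntimeError as exc:
        raise FormatError(f"failed to read {p}: {exc}") from exc
    if img.GetDimension() != 3:
        raise UnsupportedGeometryError(f"expected a 3D volume, got {img.GetDimension()}D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise UnsupportedGeometryError(
            f"non-identity direction matrix is not supported: {direction.tolist()}"
        )
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
    return VoxelVolume(
        data=data,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
    )


def write_volume(volume: VoxelVolume, path, format: str | None = None) -> None:
    """Write a volume; format inferred from the extension unless given."""
    p = Path(path)
    fmt = format or _detect_format(p)
    if fmt not in {"nrrd", "mha", "nifti"}:
        raise FormatError(f"unknown format {fmt!r}")
    data = volume.data
    if data.dtype not in (np.float32, np.int16):
        data = data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    try:
        sitk.WriteImage(img, str(p), useCompression=False)
    except RuntimeError as exc:
        raise FormatError(f"failed to write {p}: {exc}") from exc
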