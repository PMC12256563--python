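"""Synthetic CBCT rendering of the fiducial phantom and layered agar phantoms.

The registration pipeline consumes segmented fiducial centroids, not raw
projections, so rendering is done directly in the reconstructed volume domain:
bright spheres on a dark background with partial-volume edge weighting
(supersampled midpoint quadrature inside each voxel), cubic-FOV truncation and
additive Gaussian noise. Beam hardening, scatter and streaks are not
simulated.

The layered treatment phantom emulates the agar/barium stack used for
targeting evaluation: alternating layers (≈3.5 mm agar, ≈1 mm agar+barium)
along Z, and a post-treatment volume in which an ellipsoidal "bubble cloud"
zone is homogenized to the mean of the two layer intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .phantom import ModelFiducial
from .transforms import HomogeneousTransform, apply_point, identity
from .volume import VoxelVolume, centered_volume

__all__ = [
    "RenderConfig",
    "TreatmentPhantomConfig",
    "render_phantom_cbct",
    "render_treatment_pair",
]


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters for synthetic CBCT volumes.

    ``fov_side`` must be an integer multiple of ``voxel_size``; the volume is
    centered on the world origin (isocenter convention). ``supersampling`` is
    the per-axis subdivision count used for partial-volume weighting at sphere
    boundaries. Intensities are arbitrary CBCT units.
    """

    fov_side: float = 160.0
    voxel_size: float = 0.5
    fiducial_intensity: float = 3000.0
    background_intensity: float = 0.0
    noise_sigma: float = 10.0
    supersampling: int = 3
    seed: int = 0
    cylinder_intensity: float | None = None  # optional PVC body, default off

    def __post_init__(self) -> None:
        n = self.fov_side / self.voxel_size
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"fov_side/voxel_size must be an integer, got {n}"
            )
        if self.supersampling < 1:
            raise ConfigurationError("supersampling must be >= 1")

    @property
    def n_voxels(self) -> int:
        return int(round(self.fov_side / self.voxel_size))


def _empty_volume(cfg: RenderConfig) -> VoxelVolume:
    n = cfg.n_voxels
    data = np.full((n, n, n), cfg.background_intensity, dtype=np.float64)
    return centered_volume(data, [cfg.voxel_size] * 3)


def _subvoxel_offsets(cfg: RenderConfig) -> np.ndarray:
    s = cfg.supersampling
    return ((np.arange(s) + 0.5) / s - 0.5) * cfg.voxel_size


def _render_sphere(vol: VoxelVolume, center: np.ndarray, radius: float, excess: float,
                   offsets: np.ndarray) -> None:
    """Add ``excess * fraction_inside`` to voxels overlapping the sphere."""
    h = vol.spacing
    shape = np.array(vol.shape)
    lo = np.maximum(np.floor((center - radius - vol.origin) / h).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((center + radius - vol.origin) / h).astype(int) + 1, shape - 1)
    if np.any(lo > hi):
        return  # sphere entirely outside the FOV
    axes_sq = []
    for ax in range(3):
        coords = vol.origin[ax] + np.arange(lo[ax], hi[ax] + 1) * h[ax]
        d = coords[:, None] + offsets[None, :] - center[ax]  # (n_ax, s)
        axes_sq.append(d * d)
    dx2, dy2, dz2 = axes_sq
    r2 = radius * radius
    inside = (
        dx2[:, None, None, :, None, None]
        + dy2[None, :, None, None, :, None]
        + dz2[None, None, :, None, None, :]
    ) <= r2
    frac = inside.mean(axis=(3, 4, 5))
    vol.data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += excess * frac


def _render_cylinder(vol: VoxelVolume, tp2c: HomogeneousTransform, radius: float,
                     length: float, excess: float) -> None:
    """Voxel-center rendering of the PVC cylinder body (no supersampling)."""
    n = vol.shape
    xs = vol.origin[0] + np.arange(n[0]) * vol.spacing[0]
    ys = vol.origin[1] + np.arange(n[1]) * vol.spacing[1]
    zs = vol.origin[2] + np.arange(n[2]) * vol.spacing[2]
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    # express voxel centers in phantom coordinates
    inv = np.linalg.inv(tp2c.matrix)
    local = pts @ inv[:3, :3].T + inv[:3, 3]
    mask = (local[:, 0] ** 2 + local[:, 1] ** 2 <= radius**2) & (
        np.abs(local[:, 2]) <= length / 2.0
    )
    vol.data.reshape(-1)[mask] += excess


def render_phantom_cbct(
    model: Sequence[ModelFiducial],
    tp2c: HomogeneousTransform | None = None,
    cfg: RenderConfig | None = None,
) -> tuple[VoxelVolume, pd.DataFrame]:
    """Render the fiducial phantom into a CBCT-like volume.

    Parameters
    ----------
    model : list of ModelFiducial
        Digital phantom model in phantom coordinates.
    tp2c : HomogeneousTransform, optional
        Phantom-to-CBCT pose; identity (centered, axis-aligned) by default.
    cfg : RenderConfig, optional

    Returns
    -------
    volume : VoxelVolume
    truth : pandas.DataFrame
        Ground truth with columns ``index, x_mm, y_mm, z_mm, diameter_mm,
        size_class, visible`` (visible = full sphere inside the FOV cube).
    """
    cfg = cfg or RenderConfig()
    pose = tp2c or identity("p", "c")
    if pose.frame_from != "p" or pose.frame_to != "c":
        raise ConfigurationError("tp2c must map phantom (p) to CBCT (c) coordinates")
    vol = _empty_volume(cfg)
    offsets = _subvoxel_offsets(cfg)
    half = cfg.fov_side / 2.0
    excess = cfg.fiducial_intensity - cfg.background_intensity

    if cfg.cylinder_intensity is not None:
        # infer the cylinder extent from the helix radius; body rendering is a
        # visualization aid and never drives segmentation at default settings
        r = float(np.max(np.linalg.norm([f.center[:2] for f in model], axis=1)))
        length = float(
            np.ptp([f.center[2] for f in model])
            + 4 * max(f.diameter for f in model)
        )
        _render_cylinder(vol, pose, r, length,
                         cfg.cylinder_intensity - cfg.background_intensity)

    rows = []
    for fid in model:
        c = apply_point(pose, fid.center)
        visible = bool(np.all(np.abs(c) + fid.radius <= half))
        _render_sphere(vol, c, fid.radius, excess, offsets)
        rows.append(
            {
                "index": fid.index,
                "x_mm": c[0],
                "y_mm": c[1],
                "z_mm": c[2],
                "diameter_mm": fid.diameter,
                "size_class": fid.size_class,
                "visible": visible,
            }
        )
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        vol.data += rng.normal(0.0, cfg.noise_sigma, size=vol.shape)
    return vol, pd.DataFrame(rows)


@dataclass(frozen=True)
class TreatmentPhantomConfig:
    """Layered agar/barium phantom with an ellipsoidal homogenized zone.

    Layers alternate along Z with period ``agar_layer_thickness +
    barium_layer_thickness``. ``zone_intensity`` defaults to the mean of the
    two layer intensities, emulating the mixing of layers after treatment.
    """

    agar_layer_thickness: float = 3.5
    barium_layer_thickness: float = 1.0
    layer_intensities: tuple[float, float] = (800.0, 2400.0)
    zone_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    zone_radii: tuple[float, float, float] = (4.0, 4.0, 6.0)
    zone_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.agar_layer_thickness <= 0 or self.barium_layer_thickness <= 0:
            raise ConfigurationError("layer thicknesses must be positive")

    @property
    def layer_period(self) -> float:
        return self.agar_layer_thickness + self.barium_layer_thickness

    @property
    def effective_zone_intensity(self) -> float:
        if self.zone_intensity is not None:
            return self.zone_intensity
        return float(np.mean(self.layer_intensities))


def render_treatment_pair(
    cfg: TreatmentPhantomConfig | None = None,
    render: RenderConfig | None = None,
) -> tuple[VoxelVolume, VoxelVolume, np.ndarray]:
    """Render pre-/post-treatment volumes of the layered phantom.

    The post volume is identical to the pre volume except voxels whose centers
    lie inside the ellipsoidal zone, which take the homogenized zone intensity
    (both share the same noise realization, so they differ only inside the
    zone). Returns ``(pre, post, true_centroid)`` where the centroid is the
    mean world position of the replaced voxels (the measurable ground truth);
    for an empty zone the configured center is returned.
    """
    cfg = cfg or TreatmentPhantomConfig()
    render = render or RenderConfig()
    half = render.fov_side / 2.0
    center = np.asarray(cfg.zone_center, dtype=float)
    radii = np.asarray(cfg.zone_radii, dtype=float)
    if np.any(np.abs(center) + radii > half):
        raise ConfigurationError("treatment zone does not fit inside the FOV")

    pre = _empty_volume(render)
    n = render.n_voxels
    zs = pre.origin[2] + np.arange(n) * render.voxel_size
    phase = np.mod(zs + half, cfg.layer_period)
    layer = np.where(
        phase < cfg.agar_layer_thickness,
        cfg.layer_intensities[0],
        cfg.layer_intensities[1],
    )
    pre.data += layer[None, None, :] - render.background_intensity

    xs = pre.origin[0] + np.arange(n) * render.voxel_size
    ys = pre.origin[1] + np.arange(n) * render.voxel_size
    if np.all(radii > 0):
        u = ((xs - center[0]) / radii[0]) ** 2
        v = ((ys - center[1]) / radii[1]) ** 2
        w = ((zs - center[2]) / radii[2]) ** 2
        mask = u[:, None, None] + v[None, :, None] + w[None, None, :] <= 1.0
    else:
        mask = np.zeros(pre.shape, dtype=bool)

    post_data = pre.data.copy()
    post_data[mask] = cfg.effective_zone_intensity
    if render.noise_sigma > 0:
        rng = np.random.default_rng(render.seed)
        noise = rng.normal(0.0, render.noise_sigma, size=pre.shape)
        pre.data += noise
        post_data += noise
    post = VoxelVolume(post_data, pre.spacing.copy(), pre.origin.copy())

    if mask.any():
        idx = np.argwhere(mask)
        true_centroid = pre.origin + idx.mean(axis=0) * pre.spacing
    else:
        true_centroid = center
    return pre, post, true_centroid
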