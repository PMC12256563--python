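"""Digital model of the helical fiducial registration phantom.

The physical phantom is a PVC cylinder (diameter 108 mm, length 257 mm) with
32 stainless-steel fiducials seated in its surface along a helix of pitch
62 mm, spaced 32 mm apart measured along the helical path: 22 small (1.5 mm)
and 10 large (3 mm) fiducials in an asymmetric pattern so that any
sufficiently long run of large fiducials identifies its position on the helix
from inter-fiducial distances alone.

Phantom coordinates: local Z is the cylinder axis, the helix is centered
axially on the origin, and helix phase 0 points along local +X.

The exact large/small arrangement of the physical phantom is not published;
:data:`DEFAULT_LARGE_INDICES` is a reconstruction found by deterministic
search, constrained to (a) require exactly four large fiducials for unique
pattern identification (including reversed runs) and (b) place exactly one
large fiducial among the two outermost helix positions at each end, so that a
centered 160 mm cubic FOV sees 8 large and 20 small fiducials.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GeometryError, PatternValidationError
from .transforms import HomogeneousTransform, apply_point, identity

__all__ = [
    "DEFAULT_LARGE_INDICES",
    "PhantomGeometry",
    "ModelFiducial",
    "FovReport",
    "generate_model",
    "fiducials_in_fov",
    "min_unique_large_count",
    "load_geometry",
    "save_geometry",
    "export_model_csv",
    "export_model_json",
]

#: Reconstructed helix positions (1-based) carrying 3 mm fiducials.
DEFAULT_LARGE_INDICES: tuple[int, ...] = (1, 4, 5, 12, 18, 20, 23, 28, 29, 32)


@dataclass(frozen=True)
class PhantomGeometry:
    """Parameters of the helical fiducial phantom (all lengths in mm)."""

    cylinder_diameter: float = 108.0
    cylinder_length: float = 257.0
    helix_pitch: float = 62.0
    fiducial_spacing_along_helix: float = 32.0
    n_small: int = 22
    small_diameter: float = 1.5
    n_large: int = 10
    large_diameter: float = 3.0
    large_indices: tuple[int, ...] = field(default=DEFAULT_LARGE_INDICES)

    def __post_init__(self) -> None:
        object.__setattr__(self, "large_indices", tuple(int(i) for i in self.large_indices))
        n = self.n_total
        if len(self.large_indices) != self.n_large:
            raise GeometryError(
                f"large_indices has {len(self.large_indices)} entries, expected {self.n_large}"
            )
        if len(set(self.large_indices)) != self.n_large:
            raise GeometryError("large_indices contains duplicates")
        if any(i < 1 or i > n for i in self.large_indices):
            raise GeometryError(f"large_indices must lie within [1, {n}]")
        if self.axial_span + self.large_diameter > self.cylinder_length:
            raise GeometryError(
                f"helix axial span {self.axial_span:.1f} mm exceeds cylinder "
                f"length {self.cylinder_length:.1f} mm"
            )

    @property
    def n_total(self) -> int:
        return self.n_small + self.n_large

    @property
    def radius(self) -> float:
        return self.cylinder_diameter / 2.0

    @property
    def helix_turn_length(self) -> float:
        """Arc length of one full helix turn."""
        return float(np.hypot(np.pi * self.cylinder_diameter, self.helix_pitch))

    @property
    def axial_advance_per_fiducial(self) -> float:
        """Axial (Z) advance between consecutive fiducials."""
        return (
            self.fiducial_spacing_along_helix
            * self.helix_pitch
            / self.helix_turn_length
        )

    @property
    def angular_advance_per_fiducial(self) -> float:
        """Azimuthal advance (radians) between consecutive fiducials."""
        return (
            2.0 * np.pi * self.fiducial_spacing_along_helix / self.helix_turn_length
        )

    @property
    def axial_span(self) -> float:
        """Center-to-center axial extent of the full fiducial set."""
        return (self.n_total - 1) * self.axial_advance_per_fiducial


@dataclass(frozen=True)
class ModelFiducial:
    """One fiducial of the digital model (f(model))."""

    index: int  # 1-based helix position
    center: np.ndarray  # phantom coordinates, mm
    diameter: float
    size_class: str  # "small" | "large"

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        c.setflags(write=False)
        object.__setattr__(self, "center", c)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def generate_model(geometry: PhantomGeometry | None = None) -> list[ModelFiducial]:
    """Place fiducial centers along the helix.

    Centers sit on the cylinder surface (radius = cylinder_diameter / 2),
    equidistant in helix arc length, with the set centered axially on the
    phantom origin. Deterministic: identical geometry yields bitwise-identical
    centers.
    """
    g = geometry or PhantomGeometry()
    n = g.n_total
    large = set(g.large_indices)
    dz = g.axial_advance_per_fiducial
    dtheta = g.angular_advance_per_fiducial
    model = []
    for i in range(1, n + 1):
        theta = (i - 1) * dtheta
        z = (i - (n + 1) / 2.0) * dz
        center = np.array([g.radius * np.cos(theta), g.radius * np.sin(theta), z])
        is_large = i in large
        model.append(
            ModelFiducial(
                index=i,
                center=center,
                diameter=g.large_diameter if is_large else g.small_diameter,
                size_class="large" if is_large else "small",
            )
        )
    return model


@dataclass(frozen=True)
class FovReport:
    """Visibility of the phantom fiducials inside a cubic FOV."""

    fov_side: float
    visible_indices: tuple[int, ...]
    n_large: int
    n_small: int

    @property
    def n_total(self) -> int:
        return self.n_large + self.n_small


def fiducials_in_fov(
    model: Sequence[ModelFiducial],
    fov_side: float,
    phantom_pose: HomogeneousTransform | None = None,
) -> FovReport:
    """Count fiducials whose entire sphere lies inside the cubic FOV.

    The FOV is the axis-aligned cube of side ``fov_side`` centered on the CBCT
    origin (the isocenter). ``phantom_pose`` maps phantom to CBCT coordinates;
    the default identity pose corresponds to the phantom centered at isocenter
    with its long axis on the gantry rotational axis.
    """
    if fov_side <= 0:
        raise GeometryError("fov_side must be positive")
    pose = phantom_pose or identity("p", "c")
    half = fov_side / 2.0
    visible: list[int] = []
    n_large = n_small = 0
    for fid in model:
        c = apply_point(pose, fid.center)
        if np.all(np.abs(c) + fid.radius <= half):
            visible.append(fid.index)
            if fid.size_class == "large":
                n_large += 1
            else:
                n_small += 1
    return FovReport(
        fov_side=float(fov_side),
        visible_indices=tuple(visible),
        n_large=n_large,
        n_small=n_small,
    )


def min_unique_large_count(
    model: Sequence[ModelFiducial], margin: float = 1e-6
) -> int:
    """Smallest run of large fiducials that the distance pattern identifies.

    Enumerates every contiguous run of ``m`` large fiducials along the helix,
    in forward and reversed orientation, and checks that the distance-pattern
    correspondence assigns each run member to its true model index with a
    strictly unique minimum (second-best cost at least ``margin`` away).
    Returns the smallest ``m`` for which every run passes.

    Raises :class:`PatternValidationError` if no ``m`` up to the number of
    large fiducials achieves uniqueness.
    """
    from .registration import pattern_distance_costs

    large = [f for f in model if f.size_class == "large"]
    if len(large) < 2:
        raise PatternValidationError("need at least 2 large fiducials")
    large.sort(key=lambda f: f.index)
    pts = np.array([f.center for f in large])
    n = len(large)

    for m in range(2, n + 1):
        if _all_runs_identified(pts, m, margin):
            return m
    raise PatternValidationError(
        f"no run length up to {n} uniquely identifies the pattern"
    )


def _all_runs_identified(pts: np.ndarray, m: int, margin: float) -> bool:
    from .registration import pattern_distance_costs

    n = len(pts)
    for start in range(n - m + 1):
        forward = np.arange(start, start + m)
        for run_ids in (forward, forward[::-1]):
            costs = pattern_distance_costs(pts[run_ids], pts)
            for a in range(m):
                order = np.argsort(costs[a])
                best, second = order[0], order[1]
                if best != run_ids[a]:
                    return False
                if costs[a, second] - costs[a, best] < margin:
                    return False
    return True


# ---------------------------------------------------------------------------
# configuration / export


def load_geometry(path) -> PhantomGeometry:
    """Read a PhantomGeometry from JSON (or TOML, by extension)."""
    p = Path(path)
    if p.suffix.lower() == ".toml":
        import tomllib

        payload = tomllib.loads(p.read_text())
    else:
        payload = json.loads(p.read_text())
    if "large_indices" in payload:
        payload["large_indices"] = tuple(payload["large_indices"])
    return PhantomGeometry(**payload)


def save_geometry(geometry: PhantomGeometry, path) -> None:
    payload = {
        "cylinder_diameter": geometry.cylinder_diameter,
        "cylinder_length": geometry.cylinder_length,
        "helix_pitch": geometry.helix_pitch,
        "fiducial_spacing_along_helix": geometry.fiducial_spacing_along_helix,
        "n_small": geometry.n_small,
        "small_diameter": geometry.small_diameter,
        "n_large": geometry.n_large,
        "large_diameter": geometry.large_diameter,
        "large_indices": list(geometry.large_indices),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def export_model_csv(model: Sequence[ModelFiducial], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "x", "y", "z", "diameter", "size_class"])
        for f in model:
            writer.writerow([f.index, *(f"{v:.9f}" for v in f.center), f.diameter, f.size_class])


def export_model_json(model: Sequence[ModelFiducial], path) -> None:
    payload = [
        {
            "index": f.index,
            "center": f.center.tolist(),
            "diameter": f.diameter,
            "size_class": f.size_class,
        }
        for f in model
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model_json(path) -> list[ModelFiducial]:
    payload = json.loads(Path(path).read_text())
    return [
        ModelFiducial(
            index=item["index"],
            center=np.asarray(item["center"], dtype=float),
            diameter=item["diameter"],
            size_class=item["size_class"],
        )
        for item in payload
    ]
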