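"""Homogeneous-coordinate transform algebra for image-to-robot registration.

Coordinate systems follow the convention used throughout the package: a
transform named ``Ta2b`` maps points expressed in frame ``a`` to frame ``b``.
The frames of interest are

* ``r`` — robot base,
* ``e`` — robot tool attachment point (end effector),
* ``p`` — helical fiducial phantom,
* ``h`` — histotripsy transducer,
* ``c`` — CBCT volume.

The registration chain is ``Tr2c = Tp2c * Te2p * Tr2e(Reg)`` and the targeting
pose that places the transducer focal point on a CBCT target ``x`` with
transducer orientation ``Rh2c`` is

``Tr2e(Tx) = Te2h^-1 * [Rh2c | x]^-1 * Tr2c``.

All lengths are millimetres; serialized matrices are row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import polar

from .errors import (
    DegenerateTransformError,
    FormatError,
    FrameChainError,
    ReflectionError,
)

__all__ = [
    "HomogeneousTransform",
    "RigidTransform",
    "TargetPlan",
    "identity",
    "translation",
    "rotation_about_axis",
    "compose",
    "invert",
    "apply_point",
    "project_to_rigid",
    "robot_to_cbct",
    "targeting_pose",
    "load_transform",
    "save_transform",
]

_BOTTOM = np.array([0.0, 0.0, 0.0, 1.0])


@dataclass(frozen=True)
class HomogeneousTransform:
    """A 4x4 homogeneous transform mapping points ``frame_from -> frame_to``.

    Parameters
    ----------
    matrix : (4, 4) array_like
        Homogeneous matrix; translation components in mm. The bottom row must
        be exactly ``[0, 0, 0, 1]`` and the matrix must be invertible.
    frame_from, frame_to : str
        Coordinate-system labels (``r``, ``e``, ``p``, ``c``, ``h``).
    """

    matrix: np.ndarray
    frame_from: str
    frame_to: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise DegenerateTransformError(f"expected a 4x4 matrix, got {m.shape}")
        if not np.array_equal(m[3], _BOTTOM):
            raise DegenerateTransformError(f"bottom row must be [0,0,0,1], got {m[3]}")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise DegenerateTransformError("transform matrix is singular")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        """Upper-left 3x3 block."""
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        """Translation column in mm."""
        return self.matrix[:3, 3]

    def __matmul__(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        return compose(self, other)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation (scale exactly 1).

    ``rotation`` must be orthonormal with determinant +1 (tolerance 1e-9);
    ``translation`` is in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise DegenerateTransformError(f"rotation must be 3x3, got {r.shape}")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise DegenerateTransformError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ReflectionError("rotation has determinant -1 (reflection)")
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def as_homogeneous(self, frame_from: str, frame_to: str) -> HomogeneousTransform:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return HomogeneousTransform(m, frame_from, frame_to)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation


@dataclass(frozen=True)
class TargetPlan:
    """A planned treatment target in CBCT coordinates.

    ``target`` is the focal-point location x (mm, CBCT frame) and
    ``transducer_orientation`` is the rotation Rh2c between transducer and
    CBCT frames (angular tilt chosen for the acoustic window).
    """

    target: np.ndarray
    transducer_orientation: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )

    def __post_init__(self) -> None:
        x = np.asarray(self.target, dtype=float).reshape(3)
        r = np.asarray(self.transducer_orientation, dtype=float)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9) or np.linalg.det(r) < 0:
            raise DegenerateTransformError(
                "transducer_orientation must be a proper rotation"
            )
        x.setflags(write=False)
        r.setflags(write=False)
        object.__setattr__(self, "target", x)
        object.__setattr__(self, "transducer_orientation", r)

    def transducer_to_cbct(self) -> HomogeneousTransform:
        """The transform [Rh2c | x] mapping transducer frame -> CBCT frame."""
        m = np.eye(4)
        m[:3, :3] = self.transducer_orientation
        m[:3, 3] = self.target
        return HomogeneousTransform(m, "h", "c")


def identity(frame_from: str = "c", frame_to: str | None = None) -> HomogeneousTransform:
    """Identity transform; defaults to an endomorphism of ``frame_from``."""
    return HomogeneousTransform(np.eye(4), frame_from, frame_to or frame_from)


def translation(t, frame_from: str = "p", frame_to: str = "c") -> HomogeneousTransform:
    m = np.eye(4)
    m[:3, 3] = np.asarray(t, dtype=float).reshape(3)
    return HomogeneousTransform(m, frame_from, frame_to)


def rotation_about_axis(
    axis, angle_deg: float, frame_from: str = "p", frame_to: str = "c", t=(0.0, 0.0, 0.0)
) -> HomogeneousTransform:
    """Rigid transform rotating by ``angle_deg`` about ``axis`` then translating."""
    from scipy.spatial.transform import Rotation

    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    m = np.eye(4)
    m[:3, :3] = Rotation.from_rotvec(np.radians(angle_deg) * a).as_matrix()
    m[:3, 3] = np.asarray(t, dtype=float).reshape(3)
    return HomogeneousTransform(m, frame_from, frame_to)


def compose(a: HomogeneousTransform, b: HomogeneousTransform) -> HomogeneousTransform:
    """Chain two transforms: the result maps ``b.frame_from -> a.frame_to``.

    Raises :class:`FrameChainError` unless ``a.frame_from == b.frame_to``.
    """
    if a.frame_from != b.frame_to:
        raise FrameChainError(
            f"cannot chain T{b.frame_from}2{b.frame_to} into "
            f"T{a.frame_from}2{a.frame_to}: frames do not match"
        )
    return HomogeneousTransform(a.matrix @ b.matrix, b.frame_from, a.frame_to)


def invert(t: HomogeneousTransform) -> HomogeneousTransform:
    """Inverse transform with frames swapped."""
    try:
        m = np.linalg.inv(t.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by ctor
        raise DegenerateTransformError(str(exc)) from exc
    m[3] = _BOTTOM  # scrub round-off in the bottom row
    return HomogeneousTransform(m, t.frame_to, t.frame_from)


def apply_point(t: HomogeneousTransform, p) -> np.ndarray:
    """Map a point (or (n, 3) array of points) through ``t``."""
    pts = np.asarray(p, dtype=float)
    return pts @ t.linear.T + t.translation


def project_to_rigid(t: HomogeneousTransform) -> RigidTransform:
    """Nearest rigid transform: orthonormal polar factor of the linear block.

    The affine least-squares estimate of the phantom pose may carry a small
    residual scale/shear; physical robot motion cannot realize either, so the
    linear block is replaced by its polar rotation factor before refinement.

    Raises :class:`ReflectionError` if the linear block has non-positive
    determinant (no proper rotation nearby).
    """
    a = t.linear
    if np.linalg.det(a) <= 0:
        raise ReflectionError("linear block has non-positive determinant")
    u, _ = polar(a)
    if np.linalg.det(u) < 0:  # pragma: no cover - excluded by det check above
        raise ReflectionError("polar factor is a reflection")
    return RigidTransform(u, t.translation.copy())


def robot_to_cbct(
    tp2c: HomogeneousTransform,
    te2p: HomogeneousTransform,
    tr2e_reg: HomogeneousTransform,
) -> HomogeneousTransform:
    """Registration chain ``Tr2c = Tp2c * Te2p * Tr2e(Reg)``.

    ``tr2e_reg`` is the robot pose held during registration, ``te2p`` the fixed
    phantom-attachment calibration and ``tp2c`` the estimated phantom pose.
    """
    return compose(compose(tp2c, te2p), tr2e_reg)


def targeting_pose(
    plan: TargetPlan,
    te2h: HomogeneousTransform,
    tr2c: HomogeneousTransform,
) -> HomogeneousTransform:
    """Robot pose aligning the transducer focal point with the planned target.

    Computes ``Tr2e(Tx) = Te2h^-1 * [Rh2c | x]^-1 * Tr2c``. The induced
    transducer-to-CBCT transform ``Tr2c * Tr2e(Tx)^-1 * Te2h^-1`` then equals
    ``[Rh2c | x]``: the transducer-frame origin (the focal point) lands on x.
    """
    th2c = plan.transducer_to_cbct()
    return compose(compose(invert(te2h), invert(th2c)), tr2c)


def load_transform(path) -> HomogeneousTransform:
    """Read a transform JSON file ``{"frame_from", "frame_to", "matrix"}``."""
    try:
        payload = json.loads(Path(path).read_text())
        matrix = payload["matrix"]
        frame_from = payload["frame_from"]
        frame_to = payload["frame_to"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"invalid transform file {path}: {exc}") from exc
    return HomogeneousTransform(np.asarray(matrix, dtype=float), frame_from, frame_to)


def save_transform(t: HomogeneousTransform, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "frame_from": t.frame_from,
                "frame_to": t.frame_to,
                "matrix": t.matrix.tolist(),
            },
            indent=2,
        )
    )
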