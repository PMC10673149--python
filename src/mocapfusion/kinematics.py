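"""Forward kinematics of the eight-joint wearable-sensor skeleton.

Joint positions are expressed in the navigation (n-) frame whose origin is
the upper chest.  Every body segment carries an IMU that reports the
segment's attitude as pitch/roll/yaw Euler angles; a segment's long axis is
the x-axis of its body (b-) frame, so a child joint lies at the segment
length along the *first column* of the torso-relative rotation matrix,
offset from its parent joint.

The chain is: shoulders -> elbows -> wrists (arms) and hips -> knees ->
ankles (legs).  Shoulder and hip anchor positions are part of the body
model; only elbows, wrists, knees and ankles are estimated joints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SEGMENTS",
    "LIMB_SEGMENTS",
    "JOINTS",
    "EulerAttitude",
    "BodyModel",
    "SkeletonPose",
    "euler_to_rotation",
    "rotation_from_angles",
    "relative_rotation",
    "child_joint",
    "compute_skeleton",
    "is_rotation",
]

#: All instrumented segments: the torso reference plus the 8 limb segments.
SEGMENTS = (
    "torso",
    "upper_arm_l", "upper_arm_r",
    "forearm_l", "forearm_r",
    "thigh_l", "thigh_r",
    "shank_l", "shank_r",
)

#: Limb segments only (everything but the torso reference frame).
LIMB_SEGMENTS = SEGMENTS[1:]

#: The 8 estimated joints, in canonical order.
JOINTS = (
    "elbow_l", "elbow_r",
    "wrist_l", "wrist_r",
    "knee_l", "knee_r",
    "ankle_l", "ankle_r",
)


@dataclass(frozen=True)
class EulerAttitude:
    """Segment attitude as pitch/roll/yaw (radians)."""

    pitch: float
    roll: float
    yaw: float
    segment_id: str = "torso"

    def __post_init__(self) -> None:
        for name in ("pitch", "roll", "yaw"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {name}: {v!r}")
        if self.segment_id not in SEGMENTS:
            raise ValueError(
                f"unknown segment_id {self.segment_id!r}; expected one of {SEGMENTS}"
            )


def _vec3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass(frozen=True)
class BodyModel:
    """Limb lengths and shoulder/hip anchor positions (metres).

    Anchors are expressed in the torso-origin navigation frame.  Defaults
    are plausible adult proportions and fully overridable.
    """

    l_upper_arm_l: float = 0.30
    l_upper_arm_r: float = 0.30
    l_forearm_l: float = 0.25
    l_forearm_r: float = 0.25
    l_thigh_l: float = 0.40
    l_thigh_r: float = 0.40
    l_shank_l: float = 0.40
    l_shank_r: float = 0.40
    shoulder_l: np.ndarray = field(default_factory=lambda: np.array([-0.20, 0.0, 0.0]))
    shoulder_r: np.ndarray = field(default_factory=lambda: np.array([0.20, 0.0, 0.0]))
    hip_l: np.ndarray = field(default_factory=lambda: np.array([-0.10, 0.0, -0.50]))
    hip_r: np.ndarray = field(default_factory=lambda: np.array([0.10, 0.0, -0.50]))

    def __post_init__(self) -> None:
        for name in (
            "l_upper_arm_l", "l_upper_arm_r", "l_forearm_l", "l_forearm_r",
            "l_thigh_l", "l_thigh_r", "l_shank_l", "l_shank_r",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"limb length {name} must be positive, got {v!r}")
        for name in ("shoulder_l", "shoulder_r", "hip_l", "hip_r"):
            object.__setattr__(self, name, _vec3(getattr(self, name)))

    def limb_length(self, joint: str) -> float:
        """Length of the segment whose distal end is ``joint``."""
        return {
            "elbow_l": self.l_upper_arm_l, "elbow_r": self.l_upper_arm_r,
            "wrist_l": self.l_forearm_l, "wrist_r": self.l_forearm_r,
            "knee_l": self.l_thigh_l, "knee_r": self.l_thigh_r,
            "ankle_l": self.l_shank_l, "ankle_r": self.l_shank_r,
        }[joint]

    def to_dict(self) -> dict:
        return {
            "l_upper_arm_l": self.l_upper_arm_l, "l_upper_arm_r": self.l_upper_arm_r,
            "l_forearm_l": self.l_forearm_l, "l_forearm_r": self.l_forearm_r,
            "l_thigh_l": self.l_thigh_l, "l_thigh_r": self.l_thigh_r,
            "l_shank_l": self.l_shank_l, "l_shank_r": self.l_shank_r,
            "shoulder_l": list(self.shoulder_l), "shoulder_r": list(self.shoulder_r),
            "hip_l": list(self.hip_l), "hip_r": list(self.hip_r),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BodyModel":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown body-model keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class SkeletonPose:
    """Navigation-frame positions of the 8 estimated joints at one instant.

    ``positions`` is an (8, 3) array ordered as :data:`JOINTS`.
    """

    timestamp: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.shape != (len(JOINTS), 3):
            raise ValueError(f"positions must be {(len(JOINTS), 3)}, got {p.shape}")
        object.__setattr__(self, "positions", p)

    def __getitem__(self, joint: str) -> np.ndarray:
        return self.positions[JOINTS.index(joint)]


def rotation_from_angles(pitch, roll, yaw) -> np.ndarray:
    """Navigation-to-body rotation from pitch θ, roll γ, yaw φ (radians).

    The matrix is the product Roll(γ, y) · Pitch(θ, x) · Yaw(φ, z).  Inputs
    may be scalars or broadcastable arrays; the rotation axes occupy the two
    trailing output dimensions.
    """
    pitch, roll, yaw = np.broadcast_arrays(
        np.asarray(pitch, float), np.asarray(roll, float), np.asarray(yaw, float)
    )
    ct, st = np.cos(pitch), np.sin(pitch)
    cg, sg = np.cos(roll), np.sin(roll)
    cf, sf = np.cos(yaw), np.sin(yaw)
    C = np.empty(pitch.shape + (3, 3))
    C[..., 0, 0] = cg * cf + sg * sf * st
    C[..., 0, 1] = -cg * sf + sg * cf * st
    C[..., 0, 2] = -sg * ct
    C[..., 1, 0] = sf * ct
    C[..., 1, 1] = cf * ct
    C[..., 1, 2] = st
    C[..., 2, 0] = sg * cf - cg * sf * st
    C[..., 2, 1] = -sg * sf - cg * cf * st
    C[..., 2, 2] = cg * ct
    return C


def euler_to_rotation(att: EulerAttitude) -> np.ndarray:
    """Rotation matrix of one segment attitude (see :func:`rotation_from_angles`)."""
    if not all(map(math.isfinite, (att.pitch, att.roll, att.yaw))):
        raise ValueError("non-finite attitude angle")
    return rotation_from_angles(att.pitch, att.roll, att.yaw)


def is_rotation(C: np.ndarray, tol: float = 1e-10) -> bool:
    """True if C is orthonormal with determinant +1 within ``tol``."""
    C = np.asarray(C, float)
    if C.shape != (3, 3):
        return False
    return (
        np.allclose(C.T @ C, np.eye(3), atol=tol)
        and abs(np.linalg.det(C) - 1.0) < tol
    )


def relative_rotation(C_n_b0: np.ndarray, C_n_bj: np.ndarray) -> np.ndarray:
    """Rotation taking segment j's b-frame into the torso b0-frame.

    Computed as C_n_b0 · (C_n_bj)ᵀ.
    """
    return np.asarray(C_n_b0, float) @ np.asarray(C_n_bj, float).T


def child_joint(parent_pos, C_rel: np.ndarray, length: float) -> np.ndarray:
    """Distal joint position: ``length`` along C_rel's first column from the parent."""
    if not (math.isfinite(length) and length > 0):
        raise ValueError(f"segment length must be positive, got {length!r}")
    C_rel = np.asarray(C_rel, float)
    return length * C_rel[:, 0] + _vec3(parent_pos)


#: (joint, segment, parent) — parent "shoulder_*"/"hip_*" are anchors,
#: other parents are previously computed joints.
_CHAIN = (
    ("elbow_l", "upper_arm_l", "shoulder_l"),
    ("elbow_r", "upper_arm_r", "shoulder_r"),
    ("wrist_l", "forearm_l", "elbow_l"),
    ("wrist_r", "forearm_r", "elbow_r"),
    ("knee_l", "thigh_l", "hip_l"),
    ("knee_r", "thigh_r", "hip_r"),
    ("ankle_l", "shank_l", "knee_l"),
    ("ankle_r", "shank_r", "knee_r"),
)


def compute_skeleton(
    attitudes, body: BodyModel, timestamp: float = 0.0
) -> SkeletonPose:
    """Forward kinematics: per-segment attitudes -> 8 joint positions.

    Parameters
    ----------
    attitudes
        Mapping from segment id (see :data:`SEGMENTS`) to
        :class:`EulerAttitude`; every segment must be present.
    body
        Limb lengths and shoulder/hip anchors.
    """
    missing = [s for s in SEGMENTS if s not in attitudes]
    if missing:
        raise ValueError(f"missing attitude for segment(s): {missing}")
    C_n = {s: euler_to_rotation(attitudes[s]) for s in SEGMENTS}
    C0 = C_n["torso"]

    pos: dict[str, np.ndarray] = {
        "shoulder_l": body.shoulder_l, "shoulder_r": body.shoulder_r,
        "hip_l": body.hip_l, "hip_r": body.hip_r,
    }
    for joint, segment, parent in _CHAIN:
        C_rel = relative_rotation(C0, C_n[segment])
        pos[joint] = child_joint(pos[parent], C_rel, body.limb_length(joint))
    return SkeletonPose(timestamp, np.array([pos[j] for j in JOINTS]))
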