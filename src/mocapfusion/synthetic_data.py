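"""Synthetic motion, sensor errors and vision outages.

The generator emulates the statistical structure the fusion method
assumes: smooth band-limited random attitude trajectories pushed through
the forward kinematics give the ground-truth joint tracks; the IMU
solution adds a per-axis random-walk drift (the cumulative error inertial
integration suffers) plus white noise; the vision solution adds white
noise and loses samples in randomly placed per-joint outage intervals
that are drawn independently per joint, so outages do not strike all
joints simultaneously.

Default conditions: 60 s at 100 Hz, vision noise 0.02 m (depth-camera
class), IMU white noise 0.005 m, drift rate 0.01 m/sqrt(s), and on
average 3 outages per joint lasting 1-3 s each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion_pipeline import SensorStreams
from .kinematics import JOINTS, SEGMENTS, BodyModel, rotation_from_angles

__all__ = [
    "MotionScenario",
    "attitude_trajectories",
    "generate_truth",
    "corrupt_imu",
    "corrupt_vision",
    "make_streams",
]


@dataclass(frozen=True)
class MotionScenario:
    """Parameters of one synthetic recording.

    amplitude is the per-harmonic attitude swing in radians (the torso is
    scaled down by ``torso_scale``); ``freq_band`` bounds the harmonic
    frequencies in Hz.  ``outages_per_joint`` is the *expected* outage
    count (Poisson-drawn per joint).
    """

    duration: float = 60.0
    dt: float = 0.01
    amplitude: float = 0.5
    freq_band: tuple = (0.1, 0.5)
    n_harmonics: int = 4
    torso_scale: float = 0.3
    sigma_imu: float = 0.005
    sigma_drift: float = 0.01
    sigma_vision: float = 0.02
    outages_per_joint: float = 3.0
    outage_duration: tuple = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        for name in ("sigma_imu", "sigma_drift", "sigma_vision"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.freq_band
        if not (0 < lo <= hi):
            raise ValueError(f"invalid frequency band {self.freq_band}")
        lo, hi = self.outage_duration
        if not (0 < lo <= hi):
            raise ValueError(f"invalid outage duration range {self.outage_duration}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt


def attitude_trajectories(
    scenario: MotionScenario, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Smooth random attitudes per segment: (T, 3) of (pitch, roll, yaw)."""
    t = scenario.times
    out = {}
    lo, hi = scenario.freq_band
    for segment in SEGMENTS:
        scale = scenario.torso_scale if segment == "torso" else 1.0
        amp = scale * scenario.amplitude / scenario.n_harmonics
        angles = np.zeros((t.size, 3))
        for k in range(3):
            f = rng.uniform(lo, hi, scenario.n_harmonics)
            phase = rng.uniform(0, 2 * np.pi, scenario.n_harmonics)
            a = rng.uniform(0.5, 1.0, scenario.n_harmonics) * amp
            angles[:, k] = np.sum(
                a[:, None] * np.sin(2 * np.pi * f[:, None] * t + phase[:, None]),
                axis=0,
            )
        out[segment] = angles
    return out


def _skeleton_series(angles: dict[str, np.ndarray], body: BodyModel) -> np.ndarray:
    """Vectorised forward kinematics over time: (T, 8, 3) joint positions."""
    C = {
        s: rotation_from_angles(a[:, 0], a[:, 1], a[:, 2]) for s, a in angles.items()
    }
    C0 = C["torso"]
    anchors = {
        "shoulder_l": body.shoulder_l, "shoulder_r": body.shoulder_r,
        "hip_l": body.hip_l, "hip_r": body.hip_r,
    }
    chain = (
        ("elbow_l", "upper_arm_l", "shoulder_l"),
        ("elbow_r", "upper_arm_r", "shoulder_r"),
        ("wrist_l", "forearm_l", "elbow_l"),
        ("wrist_r", "forearm_r", "elbow_r"),
        ("knee_l", "thigh_l", "hip_l"),
        ("knee_r", "thigh_r", "hip_r"),
        ("ankle_l", "shank_l", "knee_l"),
        ("ankle_r", "shank_r", "knee_r"),
    )
    pos: dict[str, np.ndarray] = dict(anchors)
    for joint, segment, parent in chain:
        # first column of C0 @ Cj^T, per time step
        col = np.einsum("tab,tb->ta", C0, C[segment][:, 0, :])
        pos[joint] = body.limb_length(joint) * col + pos[parent]
    return np.stack([pos[j] for j in JOINTS], axis=1)


def generate_truth(
    scenario: MotionScenario,
    body: BodyModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth joint positions: returns (times (T,), positions (T, 8, 3))."""
    body = body or BodyModel()
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    angles = attitude_trajectories(scenario, rng)
    return scenario.times, _skeleton_series(angles, body)


def corrupt_imu(
    truth: np.ndarray, scenario: MotionScenario, rng: np.random.Generator
) -> np.ndarray:
    """IMU position solution: truth + random-walk drift + white noise.

    Drift increments are N(0, sigma_drift^2 * dt) per axis, so the drift
    variance grows linearly in time at rate sigma_drift^2.
    """
    truth = np.asarray(truth, float)
    drift = np.cumsum(
        rng.normal(0.0, scenario.sigma_drift * np.sqrt(scenario.dt), truth.shape),
        axis=0,
    )
    white = rng.normal(0.0, scenario.sigma_imu, truth.shape)
    return truth + drift + white


def _draw_outages(
    scenario: MotionScenario, rng: np.random.Generator
) -> list[tuple[float, float]]:
    n = rng.poisson(scenario.outages_per_joint)
    lo, hi = scenario.outage_duration
    spans = []
    for _ in range(n):
        start = rng.uniform(0.0, scenario.duration)
        dur = rng.uniform(lo, hi)
        if start + dur > scenario.duration:
            import warnings

            warnings.warn("outage clipped at the end of the record")
            dur = scenario.duration - start
        spans.append((start, start + dur))
    return spans


def corrupt_vision(
    truth: np.ndarray, scenario: MotionScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vision solution and availability mask.

    White noise N(0, sigma_vision^2) on every sample; the mask is False
    inside outage intervals drawn independently for each joint.
    """
    truth = np.asarray(truth, float)
    vision = truth + rng.normal(0.0, scenario.sigma_vision, truth.shape)
    T, J = truth.shape[:2]
    t = scenario.times[:T]
    mask = np.ones((T, J), bool)
    for j in range(J):
        for start, stop in _draw_outages(scenario, rng):
            mask[(t >= start) & (t < stop), j] = False
    return vision, mask


def make_streams(
    scenario: MotionScenario | None = None,
    body: BodyModel | None = None,
    seed: int | None = None,
) -> SensorStreams:
    """Full synthetic recording: truth, IMU, vision and availability mask.

    ``seed`` overrides ``scenario.seed``; a single generator drives the
    trajectory, IMU-error and vision-error draws in a fixed order, so the
    whole record is reproducible from one integer.
    """
    scenario = scenario or MotionScenario()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    times, truth = generate_truth(scenario, body, rng)
    imu = corrupt_imu(truth, scenario, rng)
    vision, mask = corrupt_vision(truth, scenario, rng)
    return SensorStreams(times, imu, vision, mask, truth=truth)
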