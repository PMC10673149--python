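"""Two-stage ELM/FIR fusion of IMU and vision joint-position streams.

Training stage (vision available): UFIR filters 1 and 2 smooth the IMU and
vision position streams; their outputs drive a two-model IMM whose
combined estimate is refined by an RTS smoother — that smoothed track is
the stage output and the pipeline's best estimate of the joint position.
Meanwhile ELM 1 learns the mapping from the IMU solution to the vision
solution, FIR filter 3 tracks ELM 1's output, and ELM 2 learns the
residual between the RTS output and FIR 3's output.

Prediction stage (vision outage): the IMU position feeds ELM 1 directly;
its output is FIR 3's measurement, and the final estimate is FIR 3's
output plus ELM 2's additive correction.

The ELM/KF baseline is the identical scheme with every FIR filter
replaced by a Kalman filter sharing the same Q, R and sampling time.
Outages are handled independently per joint, and models are refreshed
from the most recent available segment at each outage onset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .elm import ELMModel, elm_from_dict, elm_predict, elm_to_dict, elm_train
from .imm_fusion import IMMConfig, imm_filter_series
from .kinematics import JOINTS
from .state_filters import (
    CVModel,
    FIRConfig,
    FIRFilter,
    KFFilter,
    fir_filter_series,
    rts_smooth_arrays,
)

__all__ = [
    "SensorStreams",
    "FusionConfig",
    "TrainedFusion",
    "EvaluationReport",
    "run_training_stage",
    "run_prediction_stage",
    "run_full",
    "run_baseline_elm_kf",
    "imm_rts_fuse",
    "compute_report",
    "improvement_percent",
    "mean_of_axes",
    "imu_only_positions",
    "vision_only_positions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensorStreams:
    """Aligned per-joint IMU and vision position streams.

    ``imu`` and ``vision`` have shape (T, J, 3); ``available`` (T, J) flags
    the vision samples that exist; ``truth`` is optional ground truth for
    evaluation.  Vision entries where ``available`` is False are ignored.
    """

    times: np.ndarray
    imu: np.ndarray
    vision: np.ndarray
    available: np.ndarray
    truth: np.ndarray | None = None
    joints: tuple = JOINTS

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float).reshape(-1)
        imu = np.asarray(self.imu, float)
        vis = np.asarray(self.vision, float)
        av = np.asarray(self.available, bool)
        J = len(self.joints)
        if imu.shape != (t.size, J, 3) or vis.shape != imu.shape:
            raise ValueError(
                f"imu/vision must be (T={t.size}, J={J}, 3); got {imu.shape}, {vis.shape}"
            )
        if av.shape != (t.size, J):
            raise ValueError(f"available must be (T, J), got {av.shape}")
        truth = self.truth
        if truth is not None:
            truth = np.asarray(truth, float)
            if truth.shape != imu.shape:
                raise ValueError(f"truth must match imu shape, got {truth.shape}")
        for name, arr in (
            ("times", t), ("imu", imu), ("vision", vis),
            ("available", av), ("truth", truth),
        ):
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "joints", tuple(self.joints))

    @property
    def n_steps(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if self.times.size > 1 else 0.0


@dataclass(frozen=True)
class FusionConfig:
    """All pipeline tunables.

    Measurement variances reflect each branch's total error budget: the
    vision branch its white noise (0.02 m), the IMU branch its white noise
    *plus* the drift a position solution integrated from inertial attitudes
    typically accumulates over a segment (~0.05 m for minute-scale records
    at a 0.01 m/sqrt(s) drift rate).  Budgeting only the 5 mm white jitter
    would let the IMM mistake the drifting branch for the trustworthy one
    purely through its sharper likelihood density.  ``q`` is the
    white-acceleration spectral density; 1 m^2/s^3 suits limb
    accelerations of order 1 m/s^2 with sub-second correlation.

    ``elm_hidden`` is deliberately compact: the pipeline's networks map
    3-D positions lying on a low-dimensional motion manifold, and a large
    random-feature bank solved by exact pseudoinverse develops large
    mutually-cancelling output weights whose cancellation fails once the
    drifting IMU input leaves that manifold during an outage (the
    output-weight norm grows steeply with the hidden size and is the
    diagnostic to watch).  32 features sit on a wide stability plateau
    while fitting the mapping to the vision noise floor.
    """

    dt: float = 0.01
    n_axes: int = 3
    q: float = 1.0
    r_imu: float = 0.055**2
    r_vision: float = 0.02**2
    r_elm: float = 0.02**2
    horizon: int = 10
    vel_var: float = 1.0
    imm: IMMConfig = field(default_factory=IMMConfig)
    elm_hidden: int = 32
    elm_activation: str = "sigmoid"
    elm_seed: int = 0
    min_train_len: int = 50
    quantile: float = 0.9

    def model(self, r: float) -> CVModel:
        return CVModel(self.dt, self.n_axes, self.q, r)

    @property
    def fir(self) -> FIRConfig:
        return FIRConfig(self.horizon)


def _runs(mask: np.ndarray):
    """Contiguous (start, stop, value) runs of a boolean vector."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate([[0], edges, [mask.size]])
    return [
        (int(a), int(b), bool(mask[a])) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def _branch_positions(z: np.ndarray, model: CVModel, cfg: FusionConfig, method: str) -> np.ndarray:
    """Filtered position series of one sensor branch (FIR or KF)."""
    if method == "fir":
        means = fir_filter_series(z, model, cfg.fir, cfg.vel_var)
    else:
        means = KFFilter(model, cfg.vel_var).step_series(z)
    return means[:, 0::2]


def imm_rts_fuse(
    z1: np.ndarray, z2: np.ndarray, cfg: FusionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """IMM over two measurement streams followed by RTS smoothing.

    ``z1`` is the IMU-branch series, ``z2`` the vision-branch series, both
    (T, n_axes).  Returns the smoothed positions (T, n_axes) and the model
    probability trace (T, 2) with columns (IMU model, vision model).
    """
    models = (cfg.model(cfg.r_imu), cfg.model(cfg.r_vision))
    means, covs, mu_trace = imm_filter_series(z1, z2, models, cfg.imm, cfg.vel_var)
    sm, _ = rts_smooth_arrays(means, covs, cfg.model(cfg.r_vision))
    return sm[:, 0::2], mu_trace


def _new_filter3(cfg: FusionConfig, method: str):
    model = cfg.model(cfg.r_elm)
    if method == "fir":
        return FIRFilter(model, cfg.fir, cfg.vel_var)
    return KFFilter(model, cfg.vel_var)


def _joint_seed(cfg: FusionConfig, joint_index: int, which: int) -> int:
    return (cfg.elm_seed + 1009 * joint_index + 500_009 * which) % (2**31 - 1)


def _envelope(Y: np.ndarray, margin: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Per-output clamp range: training range widened by ``margin`` of its span.

    A random-feature network is unreliable outside its training range,
    while joint positions (and residual corrections) live in a bounded
    workspace; predictions are clamped to this envelope.
    """
    lo, hi = Y.min(axis=0), Y.max(axis=0)
    pad = margin * (hi - lo) + 1e-9
    return lo - pad, hi + pad


@dataclass
class _JointModels:
    elm1: ELMModel
    elm2: ELMModel
    filter3: object  # FIRFilter | KFFilter, live state
    elm1_range: tuple = None  # (lo, hi) clamp for ELM 1 outputs
    elm2_range: tuple = None  # (lo, hi) clamp for ELM 2 corrections
    input_range: tuple = None  # (lo, hi) training-domain guard on ELM 1 inputs

    def predict_position(self, imu: np.ndarray) -> np.ndarray:
        """Clamped ELM 1 mapping of IMU positions.

        Inputs are first projected onto the training input box so the
        network is only evaluated where it was fitted.
        """
        u = elm_predict(self.elm1, np.clip(imu, *self.input_range))
        return np.clip(u, *self.elm1_range)

    def predict_correction(self, u: np.ndarray) -> np.ndarray:
        """Clamped ELM 2 residual correction."""
        c = elm_predict(self.elm2, u)
        return np.clip(c, *self.elm2_range)


@dataclass
class TrainedFusion:
    """Per-joint ELM 1/2 models plus FIR-3 terminal state, serialisable."""

    joints: dict
    config: FusionConfig
    method: str = "fir"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "config": _config_to_dict(self.config),
            "joints": {
                name: {
                    "elm1": elm_to_dict(jm.elm1),
                    "elm2": elm_to_dict(jm.elm2),
                    "elm1_range": [np.asarray(r).tolist() for r in jm.elm1_range],
                    "elm2_range": [np.asarray(r).tolist() for r in jm.elm2_range],
                    "input_range": [np.asarray(r).tolist() for r in jm.input_range],
                    "filter3": jm.filter3.snapshot(),
                }
                for name, jm in self.joints.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedFusion":
        cfg = _config_from_dict(d["config"])
        method = d["method"]
        joints = {}
        for name, jd in d["joints"].items():
            f3 = _new_filter3(cfg, method)
            f3.restore(jd["filter3"])
            joints[name] = _JointModels(
                elm_from_dict(jd["elm1"]),
                elm_from_dict(jd["elm2"]),
                f3,
                tuple(np.asarray(r, float) for r in jd["elm1_range"]),
                tuple(np.asarray(r, float) for r in jd["elm2_range"]),
                tuple(np.asarray(r, float) for r in jd["input_range"]),
            )
        return cls(joints, cfg, method)

    def save(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "TrainedFusion":
        import json
        from pathlib import Path

        return cls.from_dict(json.loads(Path(path).read_text()))


def _config_to_dict(cfg: FusionConfig) -> dict:
    return {
        "dt": cfg.dt, "n_axes": cfg.n_axes, "q": cfg.q,
        "r_imu": cfg.r_imu, "r_vision": cfg.r_vision, "r_elm": cfg.r_elm,
        "horizon": cfg.horizon, "vel_var": cfg.vel_var,
        "gamma": cfg.imm.gamma.tolist(), "mu0": cfg.imm.mu0.tolist(),
        "elm_hidden": cfg.elm_hidden, "elm_activation": cfg.elm_activation,
        "elm_seed": cfg.elm_seed, "min_train_len": cfg.min_train_len,
        "quantile": cfg.quantile,
    }


def _config_from_dict(d: dict) -> FusionConfig:
    d = dict(d)
    imm = IMMConfig(np.asarray(d.pop("gamma")), np.asarray(d.pop("mu0")))
    known = set(FusionConfig.__dataclass_fields__) - {"imm"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown fusion-config keys: {sorted(unknown)}")
    return FusionConfig(imm=imm, **d)


def _train_joint_segment(
    imu: np.ndarray,
    vis: np.ndarray,
    cfg: FusionConfig,
    method: str,
    joint_index: int,
    filter3,
) -> tuple[np.ndarray, _JointModels]:
    """Training-stage pass over one fully-available segment of one joint."""
    z1 = _branch_positions(imu, cfg.model(cfg.r_imu), cfg, method)
    z2 = _branch_positions(vis, cfg.model(cfg.r_vision), cfg, method)
    fused, _ = imm_rts_fuse(z1, z2, cfg)

    elm1 = elm_train(
        imu, vis, cfg.elm_hidden, _joint_seed(cfg, joint_index, 1), cfg.elm_activation
    )
    elm1_range = _envelope(vis)
    input_range = _envelope(imu, margin=0.0)
    elm1_out = np.clip(elm_predict(elm1, imu), *elm1_range)
    if filter3 is None:
        filter3 = _new_filter3(cfg, method)
    f3_pos = filter3.step_series(elm1_out)[:, 0::2]
    target = fused - f3_pos
    elm2 = elm_train(
        elm1_out,
        target,
        cfg.elm_hidden,
        _joint_seed(cfg, joint_index, 2),
        cfg.elm_activation,
    )
    return fused, _JointModels(
        elm1, elm2, filter3, elm1_range, _envelope(target), input_range
    )


def run_training_stage(
    streams: SensorStreams, cfg: FusionConfig | None = None, method: str = "fir"
) -> tuple[np.ndarray, TrainedFusion]:
    """Training-stage fusion over a record with vision available throughout.

    Returns the RTS-smoothed IMM positions (T, J, 3) and the trained
    per-joint models (ELM 1, ELM 2, FIR-3 terminal state).
    """
    cfg = cfg or FusionConfig(dt=streams.dt or 0.01)
    if not np.all(streams.available):
        raise ValueError(
            "training stage requires vision availability at every step; "
            "split the record into contiguous available segments (see run_full)"
        )
    T, J = streams.n_steps, len(streams.joints)
    fused = np.empty((T, J, 3))
    joints = {}
    for j, name in enumerate(streams.joints):
        fused[:, j], jm = _train_joint_segment(
            streams.imu[:, j], streams.vision[:, j], cfg, method, j, None
        )
        joints[name] = jm
    return fused, TrainedFusion(joints, cfg, method)


def run_prediction_stage(streams: SensorStreams, trained: TrainedFusion) -> np.ndarray:
    """Outage-stage estimates: FIR 3 on ELM 1's output, plus ELM 2 correction.

    Advances each joint's FIR-3 filter state in place; reload a saved
    :class:`TrainedFusion` to repeat a prediction from the same state.
    """
    T, J = streams.n_steps, len(streams.joints)
    out = np.empty((T, J, 3))
    for j, name in enumerate(streams.joints):
        if name not in trained.joints:
            raise KeyError(f"joint {name!r} has no trained models")
        jm = trained.joints[name]
        u = jm.predict_position(streams.imu[:, j])
        corr = jm.predict_correction(u)
        out[:, j] = jm.filter3.step_series(u)[:, 0::2] + corr
    return out


def run_full(
    streams: SensorStreams, cfg: FusionConfig | None = None, method: str = "fir"
) -> tuple[np.ndarray, "EvaluationReport | None"]:
    """Per-joint switching between the training and prediction paths.

    Each joint's availability mask is segmented independently; available
    segments produce the IMM+RTS output and (when long enough) refresh the
    ELM models, outage segments take the ELM-corrected FIR-3 path with the
    most recently trained models.
    """
    cfg = cfg or FusionConfig(dt=streams.dt or 0.01)
    T, J = streams.n_steps, len(streams.joints)
    out = np.empty((T, J, 3))
    for j, name in enumerate(streams.joints):
        mask = streams.available[:, j]
        if not mask.any():
            warnings.warn(
                f"joint {name!r} has no vision data at all; "
                "running the prediction path on raw IMU positions"
            )
        trained_j: _JointModels | None = None
        filter3 = None
        for start, stop, avail in _runs(mask):
            imu = streams.imu[start:stop, j]
            vis = streams.vision[start:stop, j]
            if avail:
                if stop - start >= cfg.min_train_len:
                    fused, trained_j = _train_joint_segment(
                        imu, vis, cfg, method, j, filter3
                    )
                    filter3 = trained_j.filter3
                    out[start:stop, j] = fused
                else:
                    # too short to retrain: fuse only, keep FIR 3 warm
                    z1 = _branch_positions(imu, cfg.model(cfg.r_imu), cfg, method)
                    z2 = _branch_positions(vis, cfg.model(cfg.r_vision), cfg, method)
                    out[start:stop, j], _ = imm_rts_fuse(z1, z2, cfg)
                    if filter3 is not None:
                        feed = (
                            trained_j.predict_position(imu)
                            if trained_j is not None
                            else imu
                        )
                        filter3.step_series(feed)
            else:
                if filter3 is None:
                    filter3 = _new_filter3(cfg, method)
                if trained_j is not None:
                    u = trained_j.predict_position(imu)
                    corr = trained_j.predict_correction(u)
                else:
                    logger.warning(
                        "joint %s: vision outage before any training segment; "
                        "bridging with raw IMU positions", name,
                    )
                    u, corr = imu, 0.0
                out[start:stop, j] = filter3.step_series(u)[:, 0::2] + corr
    report = None
    if streams.truth is not None:
        report = compute_report(out, streams.truth, cfg.quantile, streams.joints)
    return out, report


def run_baseline_elm_kf(
    streams: SensorStreams, cfg: FusionConfig | None = None
) -> tuple[np.ndarray, "EvaluationReport | None"]:
    """The ELM/KF baseline: the full scheme with every FIR replaced by a KF."""
    return run_full(streams, cfg, method="kf")


def imu_only_positions(streams: SensorStreams) -> np.ndarray:
    """The raw IMU-derived positions (drifting), for comparison."""
    return streams.imu.copy()


def vision_only_positions(streams: SensorStreams) -> np.ndarray:
    """Vision positions with outages bridged by holding the last sample."""
    out = streams.vision.copy()
    for j in range(out.shape[1]):
        mask = streams.available[:, j]
        if not mask.any():
            continue
        idx = np.where(mask, np.arange(mask.size), -1)
        idx = np.maximum.accumulate(idx)
        idx[idx < 0] = int(np.argmax(mask))  # leading gap: backfill first sample
        out[:, j] = out[idx, j]
    return out


# ---------------------------------------------------------------------------
# Evaluation


def mean_of_axes(axis_rmse) -> np.ndarray:
    """Arithmetic mean of the per-axis RMSEs (the tables' "Mean" column)."""
    return np.mean(np.asarray(axis_rmse, float), axis=-1)


def improvement_percent(a: float, b: float) -> float:
    """Relative improvement 100·(a-b)/a of method b over baseline a."""
    return 100.0 * (a - b) / a


@dataclass(frozen=True)
class EvaluationReport:
    """Per-joint, per-axis RMSEs plus the error-CDF quantile readout.

    ``mean_rmse`` is the arithmetic mean of the three axis RMSEs;
    ``cdf_at_q`` is the empirical ``quantile``-quantile of the per-step
    Euclidean position error (linear interpolation between order
    statistics).
    """

    joints: tuple
    axis_rmse: np.ndarray  # (J, 3), metres
    mean_rmse: np.ndarray  # (J,), metres
    cdf_at_q: np.ndarray  # (J,), metres
    quantile: float = 0.9

    def __post_init__(self) -> None:
        ar = np.asarray(self.axis_rmse, float)
        mr = np.asarray(self.mean_rmse, float)
        cq = np.asarray(self.cdf_at_q, float)
        if np.any(ar < 0):
            raise ValueError("RMSE must be non-negative")
        if not np.allclose(mr, mean_of_axes(ar), atol=1e-12, equal_nan=True):
            raise ValueError("mean_rmse must be the mean of the axis RMSEs")
        object.__setattr__(self, "axis_rmse", ar)
        object.__setattr__(self, "mean_rmse", mr)
        object.__setattr__(self, "cdf_at_q", cq)
        object.__setattr__(self, "joints", tuple(self.joints))

    @property
    def overall_mean_rmse(self) -> float:
        return float(self.mean_rmse.mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "joint": list(self.joints),
                "x_rmse": self.axis_rmse[:, 0],
                "y_rmse": self.axis_rmse[:, 1],
                "z_rmse": self.axis_rmse[:, 2],
                "mean_rmse": self.mean_rmse,
                "cdf_at_q": self.cdf_at_q,
                "quantile": self.quantile,
            }
        )


def compute_report(
    estimates: np.ndarray,
    truth: np.ndarray,
    quantile: float = 0.9,
    joints: tuple | None = None,
    select: np.ndarray | None = None,
) -> EvaluationReport:
    """Per-axis RMSE, mean-of-axes RMSE and error-CDF quantile vs truth.

    ``select`` optionally restricts the evaluation to a boolean (T,) or
    (T, J) step selection (e.g. outage windows only).
    """
    est = np.asarray(estimates, float)
    tru = np.asarray(truth, float)
    if est.ndim == 2:
        est = est[:, None, :]
        tru = tru[:, None, :]
    if est.shape != tru.shape:
        raise ValueError(f"estimates {est.shape} and truth {tru.shape} differ")
    T, J, _ = est.shape
    if joints is None:
        joints = tuple(f"joint_{j}" for j in range(J))
    if len(joints) != J:
        raise ValueError("joint name count does not match estimate columns")
    if select is None:
        sel = np.ones((T, J), bool)
    else:
        sel = np.asarray(select, bool)
        if sel.ndim == 1:
            sel = np.broadcast_to(sel[:, None], (T, J))
        if sel.shape != (T, J):
            raise ValueError(f"select must be (T,) or (T, J), got {sel.shape}")
    err = est - tru
    axis_rmse = np.empty((J, 3))
    cdf = np.empty(J)
    for j in range(J):
        e = err[sel[:, j], j, :]
        if e.size == 0:
            axis_rmse[j] = np.nan
            cdf[j] = np.nan
            continue
        axis_rmse[j] = np.sqrt(np.mean(e**2, axis=0))
        cdf[j] = np.quantile(np.linalg.norm(e, axis=1), quantile)
    return EvaluationReport(joints, axis_rmse, mean_of_axes(axis_rmse), cdf, quantile)
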