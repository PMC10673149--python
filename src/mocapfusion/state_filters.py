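"""Per-joint constant-velocity state estimators.

Three estimators over the same linear model: a Kalman filter, an iterative
unbiased finite-impulse-response (UFIR) filter operating on a sliding
window of the last N position measurements, and a fixed-interval
Rauch-Tung-Striebel smoother.

The state stacks position and velocity per axis, [Lx, vx, Ly, vy, ...];
the transition matrix is block-diagonal [[1, dt], [0, 1]] per axis and the
measurement matrix selects the positions.  Process noise follows a
white-acceleration model with spectral density ``q``; the UFIR filter uses
neither Q nor R for its mean estimate, which is what makes it robust to
misspecified noise statistics.

During the start-up "dead zone" (fewer than N samples seen) the window
cannot over-determine the state, and a Kalman filter substitutes for the
FIR output.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CVModel",
    "CVState",
    "FIRConfig",
    "initial_state",
    "kf_predict",
    "kf_update",
    "fir_filter_step",
    "fir_coefficient_matrix",
    "FIRFilter",
    "KFFilter",
    "kf_filter_series",
    "fir_filter_series",
    "rts_smooth",
    "rts_smooth_arrays",
]


@dataclass(frozen=True)
class CVModel:
    """Constant-velocity state-space model, decoupled per axis.

    Parameters
    ----------
    dt : sampling time (s).
    n_axes : number of spatial axes (2 or 3).
    q : white-acceleration spectral density (m^2/s^3).  Sets the process
        noise Q = q * [[dt^3/3, dt^2/2], [dt^2/2, dt]] per axis.
    r : measurement noise variance (m^2), scalar or per-axis array.
    """

    dt: float
    n_axes: int = 3
    q: float = 1.0
    r: float | tuple | np.ndarray = 1e-4

    def __post_init__(self) -> None:
        if self.dt < 0:
            raise ValueError(f"dt must be >= 0, got {self.dt}")
        if self.n_axes not in (1, 2, 3):
            raise ValueError(f"n_axes must be 1, 2 or 3, got {self.n_axes}")
        n, dt = self.n_axes, self.dt
        T = np.kron(np.eye(n), np.array([[1.0, dt], [0.0, 1.0]]))
        G = np.zeros((n, 2 * n))
        G[np.arange(n), 2 * np.arange(n)] = 1.0
        Qb = self.q * np.array([[dt**3 / 3, dt**2 / 2], [dt**2 / 2, dt]])
        Q = np.kron(np.eye(n), Qb)
        r = np.broadcast_to(np.asarray(self.r, float), (n,))
        if np.any(r < 0):
            raise ValueError("measurement variance r must be >= 0")
        R = np.diag(r)
        for name, arr in (("T", T), ("G", G), ("Q", Q), ("R", R)):
            object.__setattr__(self, name, arr)

    # populated in __post_init__; declared for type checkers
    T: np.ndarray = None  # type: ignore[assignment]
    G: np.ndarray = None  # type: ignore[assignment]
    Q: np.ndarray = None  # type: ignore[assignment]
    R: np.ndarray = None  # type: ignore[assignment]

    @property
    def state_dim(self) -> int:
        return 2 * self.n_axes


@dataclass(frozen=True)
class CVState:
    """State mean [pos, vel per axis] and covariance.

    For FIR outputs, ``cov`` holds the generalized noise power gain (GNPG)
    H of the gain recursion rather than an error covariance.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, float).reshape(-1)
        P = np.asarray(self.cov, float)
        if P.shape != (m.size, m.size):
            raise ValueError(f"cov shape {P.shape} does not match state size {m.size}")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", P)

    @property
    def position(self) -> np.ndarray:
        return self.mean[0::2]

    @property
    def velocity(self) -> np.ndarray:
        return self.mean[1::2]


def initial_state(z, model: CVModel, vel_var: float = 1.0) -> CVState:
    """State initialised at the first measurement with zero velocity.

    Position variance is the measurement variance; velocity variance is
    ``vel_var`` (m^2/s^2), loose by default.
    """
    z = np.asarray(z, float).reshape(model.n_axes)
    mean = np.zeros(model.state_dim)
    mean[0::2] = z
    diag = np.empty(model.state_dim)
    diag[0::2] = np.diag(model.R)
    diag[1::2] = vel_var
    return CVState(mean, np.diag(diag))


def _sym(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def kf_predict(state: CVState, model: CVModel) -> CVState:
    """One-step time update: mean <- T mean, P <- T P Tᵀ + Q."""
    T = model.T
    return CVState(T @ state.mean, _sym(T @ state.cov @ T.T + model.Q))


def kf_update(state: CVState, z, model: CVModel) -> CVState:
    """Measurement update with position observation z."""
    z = np.asarray(z, float).reshape(model.n_axes)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"non-finite measurement: {z!r}")
    G, P = model.G, state.cov
    S = G @ P @ G.T + model.R
    try:
        K = np.linalg.solve(S, G @ P).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate config
        raise np.linalg.LinAlgError(f"singular innovation covariance: {exc}") from exc
    mean = state.mean + K @ (z - G @ state.mean)
    P_new = _sym((np.eye(model.state_dim) - K @ G) @ P)
    return CVState(mean, P_new)


@dataclass(frozen=True)
class FIRConfig:
    """FIR horizon N (window length, samples) and batch-init sample count D.

    D position samples determine the position+velocity state exactly
    (D = 2 by default); the window must over-determine it: N > D.
    """

    horizon: int = 10
    state_samples: int = 2

    def __post_init__(self) -> None:
        if self.state_samples < 2:
            raise ValueError("state_samples must be >= 2 for position+velocity")
        if self.horizon <= self.state_samples:
            raise ValueError(
                f"horizon N={self.horizon} must exceed state_samples D={self.state_samples}"
            )


def _init_observation_stack(model: CVModel, D: int) -> np.ndarray:
    """Rows G·T^{-(D-1-i)} mapping the state at sample D-1 to samples i < D."""
    Tinv = np.linalg.inv(model.T)
    return np.vstack(
        [model.G @ np.linalg.matrix_power(Tinv, D - 1 - i) for i in range(D)]
    )


def fir_filter_step(window, model: CVModel, cfg: FIRConfig) -> CVState:
    """Iterative UFIR estimate at the newest time of a full N-sample window.

    The state is initialised by exact batch least squares on the first D
    position samples of the window, the GNPG H from the corresponding
    normal matrix; the remaining window samples are absorbed one at a time
    through the recursion

        x⁻ = T x;  H = (GᵀG + (T H Tᵀ)⁻¹)⁻¹;  K = H Gᵀ;
        x  = x⁻ + K (z - G x⁻).

    Returns the estimate at the window's newest sample, with ``cov`` = H.
    """
    z = np.asarray(window, float)
    if z.ndim == 1:
        z = z[:, None]
    N, D = cfg.horizon, cfg.state_samples
    if z.shape != (N, model.n_axes):
        raise ValueError(
            f"window must be (N={N}, n_axes={model.n_axes}), got {z.shape}"
        )
    T, G = model.T, model.G
    C = _init_observation_stack(model, D)
    x, *_ = np.linalg.lstsq(C, z[:D].reshape(-1), rcond=None)
    H = np.linalg.inv(C.T @ C)
    for jj in range(D, N):
        x = T @ x
        H = np.linalg.inv(G.T @ G + np.linalg.inv(T @ H @ T.T))
        K = H @ G.T
        x = x + K @ (z[jj] - G @ x)
    return CVState(x, _sym(H))


def fir_coefficient_matrix(model: CVModel, cfg: FIRConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact linear form of :func:`fir_filter_step`.

    The UFIR gain sequence does not depend on the data, so the window
    estimate is a fixed linear map of the stacked window measurements.
    Returns ``(M, H)`` with M of shape (state_dim, N*n_axes) such that
    ``x = M @ window.reshape(-1)``, and H the terminal GNPG.
    """
    N, D = cfg.horizon, cfg.state_samples
    n = model.n_axes
    T, G = model.T, model.G
    C = _init_observation_stack(model, D)
    M = np.zeros((model.state_dim, N * n))
    M[:, : D * n] = np.linalg.pinv(C)
    H = np.linalg.inv(C.T @ C)
    for jj in range(D, N):
        M = T @ M
        H = np.linalg.inv(G.T @ G + np.linalg.inv(T @ H @ T.T))
        K = H @ G.T
        E = np.zeros((n, N * n))
        E[:, jj * n : (jj + 1) * n] = np.eye(n)
        M = M + K @ (E - G @ M)
    return M, _sym(H)


class KFFilter:
    """Stateful Kalman filter; initialises on the first measurement."""

    def __init__(self, model: CVModel, vel_var: float = 1.0):
        self.model = model
        self.vel_var = vel_var
        self.state: CVState | None = None
        self.count = 0

    def step(self, z) -> CVState:
        self.count += 1
        if self.state is None:
            self.state = initial_state(z, self.model, self.vel_var)
        else:
            self.state = kf_update(kf_predict(self.state, self.model), z, self.model)
        return self.state

    def step_series(self, zs) -> np.ndarray:
        """Advance through a whole (T, n_axes) series; returns state means (T, d).

        Same filter as repeated :meth:`step`, with the per-step object
        plumbing flattened out for long records.
        """
        z = np.atleast_2d(np.asarray(zs, float))
        T_len = z.shape[0]
        d = self.model.state_dim
        out = np.empty((T_len, d))
        i = 0
        if self.state is None:
            if T_len == 0:
                return out
            out[0] = self.step(z[0]).mean
            i = 1
        x, P = self.state.mean, self.state.cov
        T_mat, Q, R = self.model.T, self.model.Q, self.model.R
        pos = slice(0, d, 2)
        for t in range(i, T_len):
            x = T_mat @ x
            P = T_mat @ P @ T_mat.T + Q
            GP = P[pos, :]
            K = np.linalg.solve(GP[:, pos] + R, GP).T
            x = x + K @ (z[t] - x[pos])
            P = P - K @ GP
            P = (P + P.T) / 2.0
            out[t] = x
        self.state = CVState(x, P)
        self.count += T_len - i
        return out

    def snapshot(self) -> dict:
        return {
            "count": self.count,
            "mean": None if self.state is None else self.state.mean.tolist(),
            "cov": None if self.state is None else self.state.cov.tolist(),
        }

    def restore(self, snap: dict) -> None:
        self.count = snap["count"]
        if snap["mean"] is not None:
            self.state = CVState(np.array(snap["mean"]), np.array(snap["cov"]))


class FIRFilter:
    """Stateful iterative UFIR filter with a Kalman dead zone.

    While fewer than N samples have been seen the window cannot
    over-determine the state and the output is that of an internal Kalman
    filter, bit-for-bit.  From the N-th sample on, the output is the UFIR
    estimate over the most recent N measurements.
    """

    def __init__(self, model: CVModel, cfg: FIRConfig, vel_var: float = 1.0):
        self.model = model
        self.cfg = cfg
        self._kf = KFFilter(model, vel_var)
        self._window: deque = deque(maxlen=cfg.horizon)
        self._M, self._H = fir_coefficient_matrix(model, cfg)
        self.count = 0

    def step(self, z) -> CVState:
        z = np.asarray(z, float).reshape(self.model.n_axes)
        self._window.append(z)
        self.count += 1
        if self.count < self.cfg.horizon:
            return self._kf.step(z)
        w = np.concatenate(self._window)
        return CVState(self._M @ w, self._H)

    def step_series(self, zs) -> np.ndarray:
        """Advance through a whole (T, n_axes) series; returns state means (T, d).

        Dead-zone samples go through the per-step Kalman path; full-window
        samples apply the fixed UFIR coefficients to a sliding window.
        """
        z = np.atleast_2d(np.asarray(zs, float))
        T_len = z.shape[0]
        out = np.empty((T_len, self.model.state_dim))
        i = 0
        while i < T_len and self.count + 1 < self.cfg.horizon:
            out[i] = self.step(z[i]).mean
            i += 1
        if i < T_len:
            N = self.cfg.horizon
            prev = (
                np.array(self._window)
                if len(self._window)
                else np.empty((0, self.model.n_axes))
            )
            full = np.concatenate([prev, z[i:]], axis=0)
            win = np.lib.stride_tricks.sliding_window_view(full, N, axis=0)
            stacked = win.transpose(0, 2, 1).reshape(win.shape[0], -1)
            out[i:] = stacked[-(T_len - i) :] @ self._M.T
            self.count += T_len - i
            for row in full[-N:]:
                self._window.append(row)
        return out

    def snapshot(self) -> dict:
        return {
            "count": self.count,
            "window": [w.tolist() for w in self._window],
            "kf": self._kf.snapshot(),
        }

    def restore(self, snap: dict) -> None:
        self.count = snap["count"]
        self._window.clear()
        for w in snap["window"]:
            self._window.append(np.asarray(w, float))
        self._kf.restore(snap["kf"])


def kf_filter_series(zs, model: CVModel, vel_var: float = 1.0) -> list[CVState]:
    """Run a Kalman filter over a (T, n_axes) measurement series."""
    f = KFFilter(model, vel_var)
    return [f.step(z) for z in np.atleast_2d(np.asarray(zs, float))]


def fir_filter_series(zs, model: CVModel, cfg: FIRConfig, vel_var: float = 1.0) -> np.ndarray:
    """UFIR state means over a (T, n_axes) series, shape (T, state_dim).

    Dead-zone outputs (first N-1 samples) come from the Kalman filter; the
    rest are the fixed-coefficient UFIR window estimates, vectorised over
    time.
    """
    z = np.asarray(zs, float)
    if z.ndim == 1:
        z = z[:, None]
    T_len = z.shape[0]
    N = cfg.horizon
    out = np.empty((T_len, model.state_dim))
    kf = KFFilter(model, vel_var)
    for t in range(min(N - 1, T_len)):
        out[t] = kf.step(z[t]).mean
    if T_len >= N:
        M, _ = fir_coefficient_matrix(model, cfg)
        win = np.lib.stride_tricks.sliding_window_view(z, N, axis=0)  # (T-N+1, n, N)
        stacked = win.transpose(0, 2, 1).reshape(T_len - N + 1, -1)
        out[N - 1 :] = stacked @ M.T
    return out


def rts_smooth_arrays(
    means: np.ndarray, covs: np.ndarray, model: CVModel
) -> tuple[np.ndarray, np.ndarray]:
    """Array-based fixed-interval RTS pass over (T, d) means and (T, d, d) covs."""
    T_mat, Q = model.T, model.Q
    n = means.shape[0]
    if n == 0:
        raise ValueError("need at least one filtered state")
    sm = means.copy()
    sc = covs.copy()
    for t in range(n - 2, -1, -1):
        x, P = means[t], covs[t]
        x_pred = T_mat @ x
        P_pred = _sym(T_mat @ P @ T_mat.T + Q)
        try:
            A = np.linalg.solve(P_pred, T_mat @ P).T
        except np.linalg.LinAlgError:
            import logging

            logging.getLogger(__name__).warning(
                "singular predicted covariance in RTS pass; regularising"
            )
            ridge = 1e-12 * np.eye(P_pred.shape[0])
            A = np.linalg.solve(P_pred + ridge, T_mat @ P).T
        sm[t] = x + A @ (sm[t + 1] - x_pred)
        sc[t] = _sym(P + A @ (sc[t + 1] - P_pred) @ A.T)
    return sm, sc


def rts_smooth(filtered: Sequence[CVState], model: CVModel) -> list[CVState]:
    """Fixed-interval Rauch-Tung-Striebel smoother.

    The last state is returned unchanged; earlier states are corrected by
    the standard backward pass.  A singular predicted covariance is
    regularised with a small ridge and logged.
    """
    means = np.array([s.mean for s in filtered])
    covs = np.array([s.cov for s in filtered])
    sm, sc = rts_smooth_arrays(means, covs, model)
    return [CVState(m, P) for m, P in zip(sm, sc)]
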