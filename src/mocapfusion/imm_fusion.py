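"""Interacting-multiple-model (IMM) fusion of the IMU and vision branches.

A two-model bank runs one constant-velocity filter per sensor branch:
model 1 is updated with the IMU-derived position stream, model 2 with the
vision-derived stream.  Each cycle mixes the model states through a Markov
transition matrix, updates every model with its own measurement, scores
the models by their Gaussian innovation likelihoods, updates the model
probabilities, and combines the bank into a single output state with a
spread-of-means covariance term.

Because the two models self-consistently track their own streams, it is
the *mixing* step that exposes a drifting branch: mixing pulls each model
prior toward the combined estimate, so a stream that wanders away from the
consensus produces growing innovations and a shrinking model probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .state_filters import CVModel, CVState, kf_predict, kf_update

__all__ = [
    "IMMConfig",
    "IMMState",
    "imm_mix",
    "model_likelihood",
    "update_probabilities",
    "imm_combine",
    "imm_step",
    "imm_filter_series",
    "LIKELIHOOD_FLOOR",
]

#: Floor applied to model likelihoods before normalisation, preventing an
#: all-zero underflow from destroying the probability update.
LIKELIHOOD_FLOOR = 1e-300


@dataclass(frozen=True)
class IMMConfig:
    """Markov transition matrix Γ (row-stochastic) and initial probabilities μ₀."""

    gamma: np.ndarray = field(
        default_factory=lambda: np.array([[0.95, 0.05], [0.05, 0.95]])
    )
    mu0: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, float)
        m = np.asarray(self.mu0, float).reshape(-1)
        if g.shape != (m.size, m.size):
            raise ValueError(f"gamma shape {g.shape} does not match mu0 size {m.size}")
        if np.any(g < 0) or not np.allclose(g.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("gamma rows must be non-negative and sum to 1")
        if np.any(m < 0) or not np.isclose(m.sum(), 1.0, atol=1e-10):
            raise ValueError("mu0 must be non-negative and sum to 1")
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "mu0", m)

    @property
    def n_models(self) -> int:
        return self.mu0.size


@dataclass(frozen=True)
class IMMState:
    """Model probabilities and per-model filter states after one cycle."""

    mu: np.ndarray
    states: tuple
    likelihoods: np.ndarray | None = None

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, float).reshape(-1)
        if np.any(mu < -1e-12) or not np.isclose(mu.sum(), 1.0, atol=1e-9):
            raise ValueError(f"model probabilities must be in [0,1] and sum to 1: {mu}")
        if len(self.states) != mu.size:
            raise ValueError("one filter state required per model")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "states", tuple(self.states))


def imm_mix(state: IMMState, cfg: IMMConfig) -> tuple[list[CVState], np.ndarray]:
    """Interaction step: blend the model states under the Markov prior.

    Returns the mixed per-model states and the predicted model
    probabilities c̄ with c̄_m = Σ_i Γ_im μ_i.  The mixed covariances carry
    the spread-of-means term.  A model whose predicted probability
    degenerates to zero keeps its own (unmixed) state.
    """
    gamma, mu = cfg.gamma, state.mu
    cbar = gamma.T @ mu
    mixed = []
    for m in range(cfg.n_models):
        if cbar[m] <= 0:
            mixed.append(state.states[m])
            continue
        w = gamma[:, m] * mu / cbar[m]
        mean = sum(w[i] * state.states[i].mean for i in range(cfg.n_models))
        cov = sum(
            w[i]
            * (
                state.states[i].cov
                + np.outer(state.states[i].mean - mean, state.states[i].mean - mean)
            )
            for i in range(cfg.n_models)
        )
        mixed.append(CVState(mean, cov))
    return mixed, cbar


def model_likelihood(v, S) -> float:
    """Gaussian innovation likelihood Λ = (2π)^{-n/2} |S|^{-1/2} exp(-½ vᵀS⁻¹v)."""
    v = np.atleast_1d(np.asarray(v, float))
    S = np.atleast_2d(np.asarray(S, float))
    n = v.size
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("innovation covariance is not positive definite")
    maha = float(v @ np.linalg.solve(S, v))
    if maha < 0:
        raise np.linalg.LinAlgError("innovation covariance is not positive definite")
    return float(np.exp(-0.5 * (n * np.log(2 * np.pi) + logdet + maha)))


def update_probabilities(likelihoods, cbar) -> tuple[np.ndarray, float]:
    """Posterior model probabilities μ_m = Λ_m c̄_m / c with c = Σ Λ_m c̄_m."""
    lam = np.asarray(likelihoods, float)
    cbar = np.asarray(cbar, float)
    if np.any(lam < 0):
        raise ValueError("likelihoods must be non-negative")
    lam = np.maximum(lam, LIKELIHOOD_FLOOR)
    c = float(lam @ cbar)
    if c <= 0:
        import logging

        logging.getLogger(__name__).warning(
            "all model likelihoods vanished; falling back to predicted probabilities"
        )
        return cbar / cbar.sum(), 0.0
    return lam * cbar / c, c


def imm_combine(states: Sequence[CVState], mu) -> CVState:
    """Probability-weighted combination with spread-of-means covariance."""
    mu = np.asarray(mu, float)
    mean = sum(mu[m] * states[m].mean for m in range(len(states)))
    cov = sum(
        mu[m] * (states[m].cov + np.outer(states[m].mean - mean, states[m].mean - mean))
        for m in range(len(states))
    )
    return CVState(mean, cov)


def imm_step(
    prev: IMMState,
    z_imu,
    z_vision,
    model: CVModel | Sequence[CVModel],
    cfg: IMMConfig,
) -> tuple[IMMState, CVState]:
    """One full IMM cycle: mix, per-model predict/update, reweight, combine.

    ``model`` may be a single :class:`CVModel` shared by both branches or a
    pair (IMU-branch model, vision-branch model) differing in their
    measurement noise.  Both measurements must be present; during a vision
    outage the caller must take the prediction path instead.
    """
    if z_vision is None or z_imu is None:
        raise ValueError(
            "imm_step requires both measurement streams; use the outage "
            "prediction path when vision is unavailable"
        )
    models = (model, model) if isinstance(model, CVModel) else tuple(model)
    if len(models) != cfg.n_models:
        raise ValueError("need one model per IMM branch")
    zs = (
        np.asarray(z_imu, float).reshape(models[0].n_axes),
        np.asarray(z_vision, float).reshape(models[1].n_axes),
    )
    mixed, cbar = imm_mix(prev, cfg)
    new_states, lams = [], np.empty(cfg.n_models)
    for m, (mdl, z) in enumerate(zip(models, zs)):
        pred = kf_predict(mixed[m], mdl)
        S = mdl.G @ pred.cov @ mdl.G.T + mdl.R
        v = z - mdl.G @ pred.mean
        lams[m] = model_likelihood(v, S)
        new_states.append(kf_update(pred, z, mdl))
    mu, _ = update_probabilities(lams, cbar)
    combined = imm_combine(new_states, mu)
    return IMMState(mu, tuple(new_states), lams), combined


def imm_filter_series(
    z1: np.ndarray,
    z2: np.ndarray,
    models,
    cfg: IMMConfig,
    vel_var: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the full IMM cycle over two aligned measurement series.

    Semantically identical to initialising each model at its branch's
    first sample and calling :func:`imm_step` per step (the unit tests
    assert this), but vectorised into flat array arithmetic for long
    records.  Returns combined means (T, d), covariances (T, d, d) and
    the model-probability trace (T, 2).
    """
    from .state_filters import initial_state

    z1 = np.atleast_2d(np.asarray(z1, float))
    z2 = np.atleast_2d(np.asarray(z2, float))
    if z1.shape != z2.shape:
        raise ValueError("measurement series must be aligned")
    m1, m2 = models if not isinstance(models, CVModel) else (models, models)
    n = m1.n_axes
    d = m1.state_dim
    pos = slice(0, d, 2)  # measurement picks the position components
    T_len = z1.shape[0]
    gamma, mu = cfg.gamma, cfg.mu0.copy()
    T_mat, Q = m1.T, m1.Q
    Rs = (m1.R, m2.R)
    zs = (z1, z2)
    log2pi = n * np.log(2 * np.pi)

    s1, s2 = initial_state(z1[0], m1, vel_var), initial_state(z2[0], m2, vel_var)
    x = [s1.mean, s2.mean]
    P = [s1.cov, s2.cov]

    means = np.empty((T_len, d))
    covs = np.empty((T_len, d, d))
    mu_trace = np.empty((T_len, 2))

    def combine(out_t):
        xc = mu[0] * x[0] + mu[1] * x[1]
        dx0, dx1 = x[0] - xc, x[1] - xc
        Pc = mu[0] * (P[0] + np.outer(dx0, dx0)) + mu[1] * (P[1] + np.outer(dx1, dx1))
        means[out_t] = xc
        covs[out_t] = (Pc + Pc.T) / 2.0
        mu_trace[out_t] = mu

    combine(0)
    lam = np.empty(2)
    for t in range(1, T_len):
        cbar = gamma.T @ mu
        # mixing; a zero-probability model keeps its own state
        mx, mP = [], []
        for m in range(2):
            if cbar[m] <= 0:
                mx.append(x[m])
                mP.append(P[m])
                continue
            w = gamma[:, m] * mu / cbar[m]
            xm = w[0] * x[0] + w[1] * x[1]
            d0, d1 = x[0] - xm, x[1] - xm
            Pm = w[0] * (P[0] + np.outer(d0, d0)) + w[1] * (P[1] + np.outer(d1, d1))
            mx.append(xm)
            mP.append(Pm)
        # per-model predict + update + likelihood
        for m in range(2):
            xp = T_mat @ mx[m]
            Pp = T_mat @ mP[m] @ T_mat.T + Q
            Pp = (Pp + Pp.T) / 2.0
            GP = Pp[pos, :]  # G @ Pp
            S = GP[:, pos] + Rs[m]
            v = zs[m][t] - xp[pos]
            sol = np.linalg.solve(S, np.concatenate([GP, v[:, None]], axis=1))
            K = sol[:, :d].T
            alpha = sol[:, d]
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    "innovation covariance is not positive definite"
                )
            lam[m] = np.exp(-0.5 * (log2pi + logdet + float(v @ alpha)))
            x[m] = xp + K @ v
            Pn = Pp - K @ GP  # (I - K G) Pp with G a position selector
            P[m] = (Pn + Pn.T) / 2.0
        lam = np.maximum(lam, LIKELIHOOD_FLOOR)
        c = float(lam @ cbar)
        mu = lam * cbar / c if c > 0 else cbar / cbar.sum()
        combine(t)
    return means, covs, mu_trace
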