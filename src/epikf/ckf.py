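"""Constrained square-root cubature Kalman filter for joint state-parameter
estimation of the neural mass model.

The slow inhibitory gain B(t) is appended to the 11 model states as a
twelfth, random-walk component, and the filter tracks the full augmented
state from a single measured channel.  The excitability indicator is the
ratio ``I_B/A = x12 / A`` with the excitatory gain A held at its known
value.  Gaussian-weighted integrals are approximated with the 2n symmetric
third-degree cubature points, and the error covariance is propagated as a
lower-triangular square-root factor (QR-based triangularization) for
guaranteed positive semidefiniteness.

The "constrained" step projects the parameter component onto a feasible
interval after every measurement update, keeping the gain physiological
when the innovation sequence is momentarily uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import qr, solve_triangular

from .model import ModelParameters, N_MODEL_STATES, Segment

__all__ = [
    "N_AUGMENTED",
    "NoiseModel",
    "FilterConfig",
    "SqrtFilterState",
    "FilterTrace",
    "cubature_points",
    "triangularize",
    "discrete_dynamics",
    "augmented_derivatives",
    "time_update",
    "measurement_update",
    "apply_constraint",
    "run_filter",
    "summarize_iba",
]

N_AUGMENTED = N_MODEL_STATES + 1  # x12 carries B(t)


@dataclass
class NoiseModel:
    """Lower-triangular square-root factors of Q (process) and R (measurement)."""

    S_Q: np.ndarray
    S_R: np.ndarray

    def __post_init__(self) -> None:
        self.S_Q = np.atleast_2d(np.asarray(self.S_Q, dtype=float))
        self.S_R = np.atleast_2d(np.asarray(self.S_R, dtype=float))
        for name, M in (("S_Q", self.S_Q), ("S_R", self.S_R)):
            if not np.all(np.isfinite(M)):
                raise ValueError(f"{name} must be finite")
            if np.any(np.triu(M, 1) != 0):
                raise ValueError(f"{name} must be lower triangular")

    @classmethod
    def diagonal(cls, q_states: float, q_param: float, r_meas: float) -> "NoiseModel":
        """Diagonal noise: variance ``q_states`` on x1..x11, ``q_param`` on the
        gain random walk, ``r_meas`` on the measurement."""
        sq = np.sqrt(np.r_[np.full(N_MODEL_STATES, q_states), q_param])
        return cls(S_Q=np.diag(sq), S_R=np.array([[np.sqrt(r_meas)]]))


@dataclass
class FilterConfig:
    """Everything the filter needs besides the data.

    ``model`` supplies the constants; its ``A`` and ``G`` fields are the
    fixed gains.  ``measurement`` selects the observation function:
    ``"y"`` observes the recorder output C_S*x11 (AC-coupled EEG), ``"z"``
    observes the DC-preserved pyramidal potential x2-x3-x4.
    """

    model: ModelParameters = field(default_factory=ModelParameters)
    T: float = 1.0 / 480.0
    x12_bounds: tuple[float, float] = (0.0, 100.0)
    q_states: float = 1e-8
    q_param: float = 1e-2
    r_meas: float = 1e-2
    s0_scale: float = 1.0
    burn_in_fraction: float = 0.5
    measurement: str = "z"

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("sample period T must be positive")
        if self.model.A <= 0:
            raise ValueError("fixed excitatory gain A must be positive")
        lo, hi = self.x12_bounds
        if not (0 <= lo < hi):
            raise ValueError("x12 bounds must satisfy 0 <= lo < hi")
        if self.measurement not in ("z", "y"):
            raise ValueError("measurement must be 'z' or 'y'")

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel.diagonal(self.q_states, self.q_param, self.r_meas)

    def initial_state(self) -> "SqrtFilterState":
        x0 = np.zeros(N_AUGMENTED)
        x0[-1] = 0.5 * sum(self.x12_bounds)
        return SqrtFilterState(
            x_hat=x0, S=self.s0_scale * np.eye(N_AUGMENTED), k=0
        )

    @classmethod
    def for_segment(cls, seg: Segment, **kwargs) -> "FilterConfig":
        """Config matched to a segment's rate and observation kind."""
        kwargs.setdefault("measurement", "z" if seg.kind == "z" else "y")
        return cls(T=1.0 / seg.fs, **kwargs)


@dataclass
class SqrtFilterState:
    """Estimate plus lower-triangular square-root covariance factor."""

    x_hat: np.ndarray
    S: np.ndarray
    k: int = 0

    @property
    def covariance(self) -> np.ndarray:
        return self.S @ self.S.T


@dataclass
class FilterTrace:
    """Per-step filter output over one segment."""

    x_hat: np.ndarray  # (n_steps, 12)
    i_ba: np.ndarray  # x12 / A at every step
    innovation: np.ndarray
    fs: float
    config: FilterConfig

    def __len__(self) -> int:
        return len(self.i_ba)


def cubature_points(n_x: int) -> np.ndarray:
    """Third-degree spherical-radial cubature points, as columns.

    Returns an (n_x, 2*n_x) array holding +sqrt(n_x) and -sqrt(n_x) along
    each coordinate axis; every point carries weight 1/(2*n_x).
    """
    if n_x < 1:
        raise ValueError("state dimension must be at least 1")
    eye = np.eye(n_x)
    return np.sqrt(n_x) * np.hstack([eye, -eye])


def triangularize(M: np.ndarray) -> np.ndarray:
    """Lower-triangular S with S @ S.T == M @ M.T, non-negative diagonal.

    Implemented as the transposed R factor of a QR decomposition of M.T.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    n, m = M.shape
    if m < n:
        raise ValueError(f"need at least as many columns as rows, got {M.shape}")
    R = qr(M.T, mode="economic")[1]
    S = R.T
    signs = np.sign(np.diag(S))
    signs[signs == 0] = 1.0
    return S * signs  # flip columns so the diagonal is non-negative


def augmented_derivatives(X: np.ndarray, u1: float, p: ModelParameters) -> np.ndarray:
    """Vector field of the 12-state augmented model, vectorized over columns.

    ``X`` is (12,) or (12, m).  Component 12 (the gain B) has zero drift:
    it evolves only through process noise, i.e. as a random walk after
    discretization.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[:, None]
    s = p.sigmoid
    S = lambda v: 2.0 * s.e_s / (1.0 + np.exp(s.h_s * (s.v_s - v)))
    x1, x2, x3, x4, x5, x6, x7, x8, x9, x10, x11, B = X
    A, G, a, b, g = p.A, p.G, p.a, p.b, p.g
    dX = np.empty_like(X)
    dX[0] = x6
    dX[1] = x7
    dX[2] = x8
    dX[3] = x9
    dX[4] = x10
    dX[5] = A * a * S(x2 - x3 - x4) - 2 * a * x6 - a * a * x1
    dX[6] = A * a * (u1 + p.C2 * S(p.C1 * x1)) - 2 * a * x7 - a * a * x2
    dX[7] = B * b * p.C4 * S(p.C3 * x1) - 2 * b * x8 - b * b * x3
    dX[8] = G * g * p.C7 * S(p.C5 * x1 - p.C6 * x5) - 2 * g * x9 - g * g * x4
    dX[9] = B * b * S(p.C3 * x1) - 2 * b * x10 - b * b * x5
    dX[10] = -0.5 * x11 + (x7 - x8 - x9)
    dX[11] = 0.0
    return dX[:, 0] if single else dX


def discrete_dynamics(
    X: np.ndarray, u1: float, cfg: FilterConfig
) -> np.ndarray:
    """One explicit-Euler step of the augmented dynamics at the sample period."""
    step = X + cfg.T * augmented_derivatives(X, u1, cfg.model)
    if not np.all(np.isfinite(step)):
        raise FloatingPointError("augmented dynamics produced non-finite state")
    return step


def measurement_function(X: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Observation map: recorder output (y) or DC-preserved potential (z)."""
    X = np.atleast_2d(np.asarray(X, dtype=float).T).T
    if cfg.measurement == "y":
        return cfg.model.C_S * X[10]
    return X[1] - X[2] - X[3]


def time_update(
    fstate: SqrtFilterState,
    u1: float,
    cfg: FilterConfig,
    noise: NoiseModel,
    dynamics: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SqrtFilterState:
    """Prediction step: propagate the cubature points through the dynamics.

    The centered propagated points, scaled by 1/sqrt(m), are concatenated
    with S_Q and re-triangularized to form the predicted factor.
    """
    n = fstate.x_hat.size
    xi = cubature_points(n)
    m = xi.shape[1]
    X = fstate.x_hat[:, None] + fstate.S @ xi
    f = dynamics if dynamics is not None else (lambda pts: discrete_dynamics(pts, u1, cfg))
    Xp = f(X)
    if not np.all(np.isfinite(Xp)):
        bad = int(np.argwhere(~np.isfinite(Xp).all(axis=0))[0, 0])
        raise FloatingPointError(f"cubature point {bad} propagated to a non-finite state")
    x_pred = Xp.mean(axis=1)
    chi = (Xp - x_pred[:, None]) / np.sqrt(m)
    S_pred = triangularize(np.hstack([chi, noise.S_Q]))
    return SqrtFilterState(x_hat=x_pred, S=S_pred, k=fstate.k)


def measurement_update(
    pred: SqrtFilterState,
    y_k: float,
    cfg: FilterConfig,
    noise: NoiseModel,
    observation: Callable[[np.ndarray], np.ndarray] | None = None,
    constrain: bool = True,
) -> tuple[SqrtFilterState, float]:
    """Correction step; returns the posterior state and the innovation.

    The Kalman gain is formed by two triangular solves against the
    innovation factor S_yy (no explicit inverse), and the posterior factor
    by re-triangularization of the gain-deflated deviations.
    """
    n = pred.x_hat.size
    xi = cubature_points(n)
    m = xi.shape[1]
    X = pred.x_hat[:, None] + pred.S @ xi
    h = observation if observation is not None else (lambda pts: measurement_function(pts, cfg))
    Y = np.atleast_2d(h(X))
    y_hat = Y.mean(axis=1)
    Yc = (Y - y_hat[:, None]) / np.sqrt(m)
    S_yy = triangularize(np.hstack([Yc, noise.S_R]))
    if np.any(np.abs(np.diag(S_yy)) < 1e-12):
        raise np.linalg.LinAlgError(
            "innovation covariance factor is numerically singular"
        )
    chi = (X - pred.x_hat[:, None]) / np.sqrt(m)
    P_xy = chi @ Yc.T
    # W = P_xy (S_yy S_yy^T)^-1 via two triangular solves
    W = solve_triangular(
        S_yy, solve_triangular(S_yy, P_xy.T, lower=True), lower=True, trans="T"
    ).T
    innovation = float(np.atleast_1d(y_k)[0] - y_hat[0])
    x_new = pred.x_hat + (W * innovation).ravel()
    S_new = triangularize(np.hstack([chi - W @ Yc, W @ noise.S_R]))
    out = SqrtFilterState(x_hat=x_new, S=S_new, k=pred.k + 1)
    if constrain:
        out.x_hat = apply_constraint(out.x_hat, cfg)
    return out, innovation


def apply_constraint(x: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Project the gain component onto its feasible interval (simple clipping)."""
    out = np.asarray(x, dtype=float).copy()
    lo, hi = cfg.x12_bounds
    out[-1] = min(max(out[-1], lo), hi)
    return out


def run_filter(seg: Segment, cfg: FilterConfig | None = None) -> FilterTrace:
    """Run the filter over one segment and return the full trace.

    The input u1 is held at its mean (the filter does not know the noise
    realization); the process-noise model absorbs the difference.
    """
    if cfg is None:
        cfg = FilterConfig.for_segment(seg)
    if abs(cfg.T * seg.fs - 1.0) > 1e-9:
        raise ValueError(
            f"segment rate {seg.fs} Hz inconsistent with filter period T={cfg.T}"
        )
    noise = cfg.noise
    state = cfg.initial_state()
    u1 = cfg.model.input_mean
    n = len(seg)
    A_fixed = cfg.model.A
    x_hist = np.empty((n, N_AUGMENTED))
    innov = np.empty(n)
    for k, y_k in enumerate(seg.samples):
        try:
            pred = time_update(state, u1, cfg, noise)
            state, innov[k] = measurement_update(pred, y_k, cfg, noise)
        except (FloatingPointError, np.linalg.LinAlgError) as err:
            raise RuntimeError(f"filter failed at sample {k}: {err}") from err
        x_hist[k] = state.x_hat
    return FilterTrace(
        x_hat=x_hist, i_ba=x_hist[:, -1] / A_fixed, innovation=innov,
        fs=seg.fs, config=cfg,
    )


def summarize_iba(trace: FilterTrace, burn_in_fraction: float | None = None) -> float:
    """Segment-level excitability summary: mean I_B/A after filter burn-in."""
    if len(trace) == 0:
        raise ValueError("cannot summarize an empty trace")
    frac = trace.config.burn_in_fraction if burn_in_fraction is None else burn_in_fraction
    if not 0 <= frac < 1:
        raise ValueError("burn-in fraction must be in [0, 1)")
    k0 = int(np.floor(frac * len(trace)))
    return float(trace.i_ba[k0:].mean())
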