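"""Generative model with attractor dynamics and its unscented-Kalman inversion.

The generative model states that the decision state follows the Hopfield
dynamics with additive process noise,

    z_t = z_{t-dt} + dt * f(z_{t-dt}) + dt * w_t,   w_t ~ N(0, (q^2/dt) I),

(so the effective per-step transition-noise covariance is ``q^2 * dt * I``),
and that observations interpolate the prototype feature vectors through a
shallow sigmoid of the state,

    x_t = M @ sigmoid_out(z_t) + v_t,   v_t ~ N(0, r^2 I).

Inverting this model online is a nonlinear filtering problem; it is solved
with a non-augmented unscented Kalman filter (additive noise), which yields
the posterior Gaussian over the decision state together with the Kalman
gain and the state-observation cross-covariance, the model's locus of
top-down gain modulation.

All filter functions are written batch-first: means ``(B, N)``, covariances
``(B, N, N)``. A single trial is the ``B = 1`` case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .attractor import (
    HopfieldParams,
    find_neutral_state,
    find_stable_fixed_points,
    hopfield_drift,
    sigmoid,
)

__all__ = [
    "UtParams",
    "BattmConfig",
    "Belief",
    "Prediction",
    "state_transition",
    "observation_map",
    "unscented_transform",
    "ukf_update",
    "ukf_step",
]


@dataclass(frozen=True)
class UtParams:
    """Scaled unscented-transform parameters.

    ``kappa`` defaults to ``3 - D`` where ``D`` is the sigma-point
    dimension (the filter state dimension in the non-augmented filter).
    """

    alpha: float = 0.01
    beta: float = 2.0
    kappa: float | None = None

    def resolved_kappa(self, dim: int) -> float:
        return (3.0 - dim) if self.kappa is None else self.kappa

    def weights(self, dim: int) -> tuple[float, np.ndarray, np.ndarray]:
        """Returns (scale lambda+D, mean weights, covariance weights)."""
        kappa = self.resolved_kappa(dim)
        lam = self.alpha**2 * (dim + kappa) - dim
        c = dim + lam
        wm = np.full(2 * dim + 1, 1.0 / (2.0 * c))
        wc = wm.copy()
        wm[0] = lam / c
        wc[0] = lam / c + (1.0 - self.alpha**2 + self.beta)
        return c, wm, wc


@dataclass(frozen=True)
class BattmConfig:
    """Decision-maker parameters of the Bayesian attractor model.

    Parameters
    ----------
    hopfield : HopfieldParams
        Constants of the attractor dynamics shared with the pure baseline.
    M : ndarray
        Prototype matrix, one feature-vector column per alternative.
    r : float
        Sensory uncertainty — the observation-noise SD the decision maker
        expects; sets ``R = r^2 I``.
    q : float
        Dynamics uncertainty — expected state-noise magnitude; sets
        ``Q = (q^2/dt) I`` and governs decision flexibility vs stability.
    p0 : float
        Initial state uncertainty; the trial prior is ``N(mu_0, p0^2 I)``.
    dt_ms : float
        Filter step, milliseconds.
    lambda_thresh : float
        Confidence bound: a decision is made when the posterior density at
        a stable fixed point reaches this value (a density, not a
        probability — values above 1 are legitimate).
    T0_ms : float
        Non-decision time, always contained in reported reaction times.
        Depending on the experiment it either delays the start of
        accumulation or models the motor latency after the internal
        decision (see :func:`battm.decision.run_trials`).
    timeout_ms : float
        Trials with no threshold crossing by this time count as timeouts.
    out_slope, out_centre : float
        Parameters of the observation-interpolation sigmoid (shallower and
        centred at ``g/2`` so it is near-linear between fixed points).
    time_unit_ms : float
        Wall-clock duration of one unit of dynamics time. The Hopfield
        rate constant ``k`` is per unit of dynamics time, so one filter
        step advances the dynamics by ``dt_ms / time_unit_ms`` time units.
        The default (50 ms) is the package's temporal calibration of the
        dimensionless attractor dynamics; see docs/methods.md.
    """

    hopfield: HopfieldParams = field(default_factory=HopfieldParams)
    M: np.ndarray = field(
        default_factory=lambda: np.array([[0.71, -0.71], [0.71, -0.71]])
    )
    r: float = 2.4
    q: float = 0.5
    p0: float = 5.0
    dt_ms: float = 4.0
    lambda_thresh: float = 0.02
    T0_ms: float = 200.0
    timeout_ms: float = 1000.0
    out_slope: float = 0.7
    out_centre: float | None = None
    time_unit_ms: float = 50.0
    ut: UtParams = field(default_factory=UtParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "M", np.asarray(self.M, dtype=float))
        for name in ("r", "q", "p0", "dt_ms", "lambda_thresh", "time_unit_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.M.shape[1] != self.hopfield.n_alt:
            raise ValueError("prototype matrix M does not match n_alt")
        if self.out_centre is None:
            object.__setattr__(self, "out_centre", self.hopfield.g / 2.0)

    @property
    def dt_model(self) -> float:
        """Step length in units of dynamics time."""
        return self.dt_ms / self.time_unit_ms

    @property
    def n_alt(self) -> int:
        return self.hopfield.n_alt

    @property
    def n_features(self) -> int:
        return self.M.shape[0]

    @property
    def Q_step(self) -> np.ndarray:
        """Effective per-step transition-noise covariance ``q^2 dt I``."""
        return self.q**2 * self.dt_model * np.eye(self.n_alt)

    @property
    def R(self) -> np.ndarray:
        return self.r**2 * np.eye(self.n_features)

    @property
    def P0(self) -> np.ndarray:
        return self.p0**2 * np.eye(self.n_alt)

    def neutral_state(self) -> np.ndarray:
        return find_neutral_state(self.hopfield)

    def stable_fixed_points(self) -> np.ndarray:
        return find_stable_fixed_points(self.hopfield)


@dataclass(frozen=True)
class Belief:
    """Gaussian posterior over the decision state at one time step."""

    mean: np.ndarray
    cov: np.ndarray
    t_ms: float = 0.0


@dataclass(frozen=True)
class Prediction:
    """One-step-ahead predictions of state and observation."""

    z_pred: np.ndarray
    P_pred: np.ndarray
    x_pred: np.ndarray
    S_pred: np.ndarray  # predicted observation covariance
    cross_cov: np.ndarray  # state x observation


def state_transition(
    z: np.ndarray,
    cfg: BattmConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One Euler step of the generative dynamics, optionally with noise.

    Without ``rng`` this is the deterministic drift step used inside the
    filter; with ``rng`` a transition-noise draw with per-step covariance
    ``q^2 dt I`` is added (sampling from the generative model).
    """
    z = np.asarray(z, dtype=float)
    out = z + cfg.dt_model * hopfield_drift(z, cfg.hopfield)
    if rng is not None:
        out = out + cfg.q * np.sqrt(cfg.dt_model) * rng.standard_normal(z.shape)
    return out


def observation_map(z: np.ndarray, cfg: BattmConfig) -> np.ndarray:
    """Predicted mean observation ``M @ sigmoid_out(z)`` for states ``(..., N)``."""
    s = sigmoid(np.asarray(z, dtype=float), cfg.out_slope, cfg.out_centre)
    return s @ cfg.M.T


def _chol_with_jitter(cov: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Batched Cholesky; on failure add scaled-identity jitter up to 3 times."""
    eye = np.eye(cov.shape[-1])
    for attempt in range(4):
        try:
            return np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            if attempt == 3:
                raise np.linalg.LinAlgError(
                    "covariance not positive definite after jitter retries"
                )
            cov = cov + (jitter * 10**attempt) * eye


def unscented_transform(
    mean: np.ndarray,
    cov: np.ndarray,
    mapping: Callable[[np.ndarray], np.ndarray],
    ut: UtParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Propagate a Gaussian through ``mapping`` with the scaled UT.

    Parameters
    ----------
    mean : ndarray (B, D) or (D,)
    cov : ndarray (B, D, D) or (D, D)
    mapping : callable
        Applied to sigma points of shape (..., D); must return (..., E).
    ut : UtParams
        Transform parameters; defaults as in :class:`UtParams`.

    Returns
    -------
    (mean', cov', cross_cov)
        Transformed mean (B, E), covariance of transformed points
        (B, E, E) and input-output cross-covariance (B, D, E). Leading
        batch axis is dropped when the inputs were unbatched.
    """
    ut = ut or UtParams()
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    squeeze = mean.ndim == 1
    if squeeze:
        mean, cov = mean[None], cov[None]
    d = mean.shape[-1]
    c, wm, wc = ut.weights(d)
    root = np.sqrt(c) * _chol_with_jitter(cov)  # (B, D, D)
    # sigma points: mean, mean + columns, mean - columns
    cols = np.moveaxis(root, -1, -2)  # (B, D_cols, D)
    pts = np.concatenate(
        [mean[:, None, :], mean[:, None, :] + cols, mean[:, None, :] - cols],
        axis=1,
    )  # (B, 2D+1, D)
    y = np.asarray(mapping(pts), dtype=float)  # (B, 2D+1, E)
    y_mean = np.einsum("s,bse->be", wm, y)
    dy = y - y_mean[:, None, :]
    dz = pts - mean[:, None, :]
    y_cov = np.einsum("s,bse,bsf->bef", wc, dy, dy)
    cross = np.einsum("s,bsd,bse->bde", wc, dz, dy)
    if squeeze:
        return y_mean[0], y_cov[0], cross[0]
    return y_mean, y_cov, cross


def ukf_update(
    mean: np.ndarray,
    cov: np.ndarray,
    x: np.ndarray,
    transition: Callable[[np.ndarray], np.ndarray],
    observation: Callable[[np.ndarray], np.ndarray],
    Q: np.ndarray,
    R: np.ndarray,
    ut: UtParams | None = None,
) -> tuple[np.ndarray, np.ndarray, Prediction, np.ndarray, np.ndarray]:
    """One generic additive-noise UKF predict-update cycle (batched).

    Returns ``(mean', cov', Prediction, gain K, prediction error eps)``.
    The posterior covariance is re-symmetrised after the update.
    """
    mean = np.asarray(mean, dtype=float)
    squeeze = mean.ndim == 1
    if squeeze:
        mean, cov, x = mean[None], np.asarray(cov)[None], np.asarray(x)[None]
    cov = np.asarray(cov, dtype=float)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite observation")

    z_pred, P_ut, _ = unscented_transform(mean, cov, transition, ut)
    P_pred = P_ut + Q
    P_pred = 0.5 * (P_pred + np.swapaxes(P_pred, -1, -2))
    x_pred, S_ut, cross = unscented_transform(z_pred, P_pred, observation, ut)
    S = S_ut + R
    S = 0.5 * (S + np.swapaxes(S, -1, -2))
    # K = cross @ S^-1  (S symmetric PD)
    K = np.swapaxes(np.linalg.solve(S, np.swapaxes(cross, -1, -2)), -1, -2)
    eps = x - x_pred
    new_mean = z_pred + np.einsum("bde,be->bd", K, eps)
    new_cov = P_pred - np.einsum("bde,bef,bgf->bdg", K, S, K)
    new_cov = 0.5 * (new_cov + np.swapaxes(new_cov, -1, -2))
    pred = Prediction(z_pred, P_pred, x_pred, S, cross)
    if squeeze:
        pred = Prediction(z_pred[0], P_pred[0], x_pred[0], S[0], cross[0])
        return new_mean[0], new_cov[0], pred, K[0], eps[0]
    return new_mean, new_cov, pred, K, eps


def ukf_step(
    belief: Belief, x: np.ndarray, cfg: BattmConfig
) -> tuple[Belief, Prediction, np.ndarray, np.ndarray]:
    """One filtering step of the Bayesian attractor model.

    Predicts through the attractor dynamics (adding ``Q_step``) and the
    observation interpolation (adding ``R``), then corrects with the
    Kalman gain ``K = C S^-1`` built from the state-observation
    cross-covariance.

    Returns ``(new belief, prediction, gain, prediction error)``.
    """
    new_mean, new_cov, pred, K, eps = ukf_update(
        belief.mean,
        belief.cov,
        x,
        transition=lambda z: state_transition(z, cfg),
        observation=lambda z: observation_map(z, cfg),
        Q=cfg.Q_step,
        R=cfg.R,
        ut=cfg.ut,
    )
    return Belief(new_mean, new_cov, belief.t_ms + cfg.dt_ms), pred, K, eps
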