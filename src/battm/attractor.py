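"""Winner-take-all Hopfield dynamics used as the decision-level attractor.

The decision state ``z`` holds one activity per choice alternative. The
dynamics

    dz/dt = k * (L @ sigmoid(z) + b_lin * (g * 1 - z)),   L = b_lat * (I - J)

(``J`` the all-ones matrix) combines lateral inhibition between alternatives
with a linear pull towards the goal level ``g``. With the stability condition
``o = g`` and ``b_lat / b_lin = 2 g`` it has one stable fixed point per
alternative, located close to ``g * e_m``, plus an unstable equal-activity
equilibrium on the diagonal that serves as the neutral starting state of a
trial.

This module also provides the "pure" attractor baseline, in which noisy
evidence is injected directly into the state instead of arriving through
Bayesian inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

__all__ = [
    "HopfieldParams",
    "FixedPointSet",
    "sigmoid",
    "hopfield_drift",
    "hopfield_jacobian",
    "find_stable_fixed_points",
    "find_neutral_state",
    "fixed_point_set",
    "pure_attractor_trial",
]


@dataclass(frozen=True)
class HopfieldParams:
    """Constants of the Hopfield attractor dynamics.

    Parameters
    ----------
    k : float
        Rate constant (1/s); sets the overall speed of the dynamics.
    g : float
        Goal-state level; stable fixed points have one component near ``g``.
    r_sig : float
        Slope of the logistic sigmoid applied to the state.
    o : float
        Centre of the sigmoid; stability requires ``o == g``.
    b_lat : float
        Strength of lateral inhibition between alternatives.
    b_lin : float
        Strength of the linear goal attractor; stability requires
        ``b_lat / b_lin == 2 * g``.
    n_alt : int
        Number of decision alternatives ``N``.
    """

    k: float = 4.0
    g: float = 10.0
    r_sig: float = 1.0
    o: float = 10.0
    b_lat: float = 1.7
    b_lin: float = field(default=1.7 / 20.0)
    n_alt: int = 2

    def __post_init__(self) -> None:
        if self.n_alt < 2:
            raise ValueError("need at least two alternatives")
        for name in ("k", "g", "r_sig", "b_lat", "b_lin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def satisfies_stability_condition(self) -> bool:
        """Whether ``o == g`` and ``b_lat / b_lin == 2 g`` (guarantees the
        one-winner fixed points are stable)."""
        return np.isclose(self.o, self.g) and np.isclose(
            self.b_lat / self.b_lin, 2.0 * self.g
        )

    @property
    def lateral_matrix(self) -> np.ndarray:
        """``L = b_lat * (I - J)`` with ``J`` the all-ones matrix."""
        n = self.n_alt
        return self.b_lat * (np.eye(n) - np.ones((n, n)))


@dataclass(frozen=True)
class FixedPointSet:
    """Stable fixed points (one per alternative) and the neutral state."""

    stable: np.ndarray  # (N, N); row m is phi_m
    neutral: np.ndarray  # (N,)

    def phi(self, m: int) -> np.ndarray:
        return self.stable[m]


def sigmoid(z: np.ndarray, slope: float, centre: float) -> np.ndarray:
    """Elementwise logistic ``1 / (1 + exp(-slope * (z - centre)))``.

    Saturates without overflow for arbitrarily large ``|z|``.
    """
    return expit(slope * (np.asarray(z, dtype=float) - centre))


def hopfield_drift(z: np.ndarray, params: HopfieldParams) -> np.ndarray:
    """Velocity ``dz/dt`` of the Hopfield dynamics.

    Accepts a single state vector ``(N,)`` or a batch ``(..., N)``.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != params.n_alt:
        raise ValueError(
            f"state has {z.shape[-1]} components, expected {params.n_alt}"
        )
    s = sigmoid(z, params.r_sig, params.o)
    # L @ s with L = b_lat (I - J):  b_lat * (s - sum(s))
    lat = params.b_lat * (s - s.sum(axis=-1, keepdims=True))
    return params.k * (lat + params.b_lin * (params.g - z))


def hopfield_jacobian(z: np.ndarray, params: HopfieldParams) -> np.ndarray:
    """Analytic Jacobian of :func:`hopfield_drift` at a single state."""
    z = np.asarray(z, dtype=float)
    s = sigmoid(z, params.r_sig, params.o)
    ds = params.r_sig * s * (1.0 - s)
    L = params.lateral_matrix
    return params.k * (L * ds[None, :] - params.b_lin * np.eye(params.n_alt))


def find_stable_fixed_points(
    params: HopfieldParams, tol: float = 1e-12
) -> np.ndarray:
    """Locate the N stable one-winner fixed points by root refinement.

    Each point is found by Newton iteration seeded at ``g * e_m``; the
    m-th component of ``phi_m`` ends up slightly below ``g`` and all other
    components near 0.

    Returns
    -------
    ndarray of shape (N, N)
        Row ``m`` is ``phi_m``.

    Raises
    ------
    RuntimeError
        If the root search fails to converge or a located point is not
        attracting (some Jacobian eigenvalue has non-negative real part).
    """
    n = params.n_alt
    points = np.empty((n, n))
    for m in range(n):
        z0 = params.g * np.eye(n)[m]
        sol = optimize.root(
            hopfield_drift,
            z0,
            args=(params,),
            jac=hopfield_jacobian,
            method="hybr",
            tol=tol,
        )
        drift_norm = float(np.max(np.abs(hopfield_drift(sol.x, params))))
        if not sol.success or drift_norm > 1e-8:
            raise RuntimeError(
                f"fixed-point refinement failed for alternative {m}: "
                f"{sol.message} (|drift|_max = {drift_norm:.3g})"
            )
        eig = np.linalg.eigvals(hopfield_jacobian(sol.x, params))
        if np.any(eig.real >= 0):
            raise RuntimeError(
                f"point found for alternative {m} is not stable "
                f"(eigenvalues {eig})"
            )
        points[m] = sol.x
    return points


def _diagonal_drift(c: float, params: HopfieldParams) -> float:
    """Common drift component of the state ``c * 1`` (all equal)."""
    s = float(sigmoid(np.array([c]), params.r_sig, params.o)[0])
    return params.k * (
        -params.b_lat * (params.n_alt - 1) * s
        + params.b_lin * (params.g - c)
    )


def find_neutral_state(params: HopfieldParams) -> np.ndarray:
    """Equal-activity unstable equilibrium used as the trial prior mean.

    On the diagonal ``z = c * 1`` the drift reduces to a scalar function of
    ``c``; its root in ``[0, g]`` is bracketed and solved by Brent's method.
    The returned point is verified to be unstable off the diagonal.
    """
    lo, hi = 0.0, params.g
    flo, fhi = _diagonal_drift(lo, params), _diagonal_drift(hi, params)
    if flo * fhi > 0:
        raise RuntimeError(
            f"no diagonal equilibrium bracketed in [0, {params.g}] "
            f"(drift {flo:.3g} at 0, {fhi:.3g} at g)"
        )
    c = optimize.brentq(_diagonal_drift, lo, hi, args=(params,), xtol=1e-14)
    mu0 = np.full(params.n_alt, c)
    eig = np.linalg.eigvals(hopfield_jacobian(mu0, params))
    if not np.any(eig.real > 0):
        raise RuntimeError(
            f"diagonal equilibrium at c={c:.6g} is not unstable "
            f"(eigenvalues {eig})"
        )
    return mu0


def fixed_point_set(params: HopfieldParams) -> FixedPointSet:
    """Stable fixed points and neutral state for ``params``."""
    return FixedPointSet(
        stable=find_stable_fixed_points(params),
        neutral=find_neutral_state(params),
    )


def pure_attractor_trial(
    input_level: float,
    noise_sd: float,
    schedule: list[tuple[int, float]],
    dt_ms: float = 4.0,
    seed: int | np.random.Generator | None = None,
    params: HopfieldParams | None = None,
    z0: np.ndarray | None = None,
    time_unit_ms: float = 50.0,
) -> np.ndarray:
    """Simulate the pure attractor baseline by Euler iteration.

    The evidence input ``I_t`` adds ``dt * input_level + v_t`` (with
    ``v_t ~ N(0, noise_sd**2)``) to the component of the currently true
    alternative and 0 elsewhere, so speed and asymptote depend directly on
    the input strength — the property the Bayesian variant removes.

    Parameters
    ----------
    input_level : float
        Deterministic evidence magnitude ``I`` (per unit time).
    noise_sd : float
        Per-step evidence noise SD (the reference experiments use 0.2).
    schedule : list of (alternative, duration_ms)
        Which alternative generates input, and for how long.
    dt_ms : float
        Euler step in milliseconds.
    seed : int, Generator or None
        Source of the evidence noise.
    params : HopfieldParams, optional
        Dynamics constants; defaults are used when omitted.
    z0 : ndarray, optional
        Initial state; defaults to the neutral equilibrium.
    time_unit_ms : float
        Wall-clock duration of one unit of dynamics time (the rate
        constant ``k`` is per unit of dynamics time); matches the
        Bayesian model's temporal calibration so that architecture is the
        only difference between the two.

    Returns
    -------
    ndarray of shape (T + 1, N)
        State trajectory including the initial state.
    """
    if params is None:
        params = HopfieldParams()
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    rng = np.random.default_rng(seed)
    dt = dt_ms / time_unit_ms

    truth: list[int] = []
    for alt, dur_ms in schedule:
        truth.extend([alt] * int(round(dur_ms / dt_ms)))
    n_steps = len(truth)

    z = (
        find_neutral_state(params).copy()
        if z0 is None
        else np.asarray(z0, dtype=float).copy()
    )
    traj = np.empty((n_steps + 1, params.n_alt))
    traj[0] = z
    for t in range(n_steps):
        inp = np.zeros(params.n_alt)
        inp[truth[t]] = dt * input_level + (
            rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        )
        z = z + dt * hopfield_drift(z, params) + inp
        traj[t + 1] = z
    return traj
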