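"""Fitting behavioural summaries: pseudo-likelihood, DRAM MCMC, K' scaling.

The model cannot predict accuracy and mean reaction time analytically, so
each candidate parameter pair (noise level ``s``, sensory uncertainty
``r``) is scored by simulating trials and comparing the simulated summary
statistics with the observed ones through a Gaussian discrepancy

    D(s, r) = (A - A_hat)^2 / sigma_A^2 + (RT - RT_hat)^2 / sigma_RT^2
              + P(s, r),

with ad-hoc scales ``sigma_A = 0.05`` and ``sigma_RT = 10 ms``. The
penalty ``P`` walls off pathological regions: parameter pairs where more
than half of the simulated trials time out, and the overshoot regime
where ``r`` falls below the straight line through (s=1.45, r=0.47) and
(s=80, r=3.66) in log-log coordinates, both penalised with values above
10,000.

The discrepancy is embedded (as ``exp(-D/2)``-shaped likelihood) in an
adaptive Metropolis sampler with one delayed-rejection stage (DRAM) over
``(log s, log r)`` with wide Gaussian priors, a hard constraint
``s > 0.1`` and a fresh simulation seed per proposal (noisy Metropolis).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .decision import simulate_condition
from .stimulus import StimulusSpec
from .ukf import BattmConfig

__all__ = [
    "BehaviouralSummary",
    "PenaltySpec",
    "FitResult",
    "discrepancy",
    "simulate_summary",
    "mcmc_fit",
    "retained_indices",
    "fit_kprime",
    "load_coherence_table",
]

SIGMA_A = 0.05
SIGMA_RT_MS = 10.0


def load_coherence_table() -> pd.DataFrame:
    """Fitted (coherence, r, s) values per condition, shipped as a fixture.

    Columns: ``coherence`` (percent), ``r`` (sensory uncertainty),
    ``s`` (noise level).
    """
    ref = importlib.resources.files("battm") / "data" / "table2.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass(frozen=True)
class BehaviouralSummary:
    """Observed summary of one condition: accuracy and mean RT."""

    condition: str
    accuracy: float
    mean_rt_ms: float
    n_trials: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.mean_rt_ms < 0:
            raise ValueError("mean RT must be non-negative")


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty geometry for the discrepancy function.

    ``line_r`` / ``line_s`` are the two endpoints of the overshoot
    boundary, a straight line in log-log (s, r) coordinates. Parameter
    pairs with ``r`` below the line — too little sensory uncertainty for
    the noise level, which drives state overshoots — are penalised, as
    are pairs where the timeout fraction exceeds ``timeout_threshold``.
    """

    timeout_threshold: float = 0.5
    floor: float = 10_000.0
    line_r: tuple[float, float] = (0.47, 3.66)
    line_s: tuple[float, float] = (1.45, 80.0)

    def overshoot_boundary_r(self, s: float) -> float:
        """Sensory uncertainty on the boundary line at noise level ``s``."""
        lr = np.log(np.asarray(self.line_r))
        ls = np.log(np.asarray(self.line_s))
        slope = (lr[1] - lr[0]) / (ls[1] - ls[0])
        return float(np.exp(lr[0] + slope * (np.log(s) - ls[0])))

    def in_overshoot_region(self, s: float, r: float) -> bool:
        return r < self.overshoot_boundary_r(s)

    def value(self, s: float, r: float, timeout_fraction: float) -> float:
        """Zero in the admissible region, > ``floor`` otherwise (graded)."""
        pen = 0.0
        if timeout_fraction > self.timeout_threshold:
            pen += self.floor * (
                1.0 + timeout_fraction - self.timeout_threshold
            )
        bound = self.overshoot_boundary_r(s)
        if r < bound:
            pen += self.floor * (1.0 + np.log(bound / r))
        return pen


def simulate_summary(
    s: float,
    r: float,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    cfg_base: BattmConfig | None = None,
    trial_ms: float = 1100.0,
) -> tuple[float, float, float]:
    """Simulated (accuracy, mean RT of responses, timeout fraction) at (s, r).

    Single-decision trials with the remaining model parameters taken from
    ``cfg_base``; accuracy is correct/decided, mean RT is over all decided
    trials (all responses) and includes the non-decision time.
    """
    cfg = replace(cfg_base or BattmConfig(), r=float(r))
    spec = StimulusSpec(
        noise_level=float(s), schedule=((0, trial_ms),),
        dt_ms=cfg.dt_ms, frame_ms=cfg.dt_ms,
    )
    batch = simulate_condition(spec, cfg, n_sim, seed=seed, stop_early=True)
    dec = batch.decided
    acc = batch.accuracy(true_alt=0)
    rt = float(np.mean(batch.rt_ms[dec])) if np.any(dec) else np.nan
    return acc, rt, batch.timeout_fraction()


def discrepancy(
    s: float,
    r: float,
    summary: BehaviouralSummary,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    cfg_base: BattmConfig | None = None,
    penalty: PenaltySpec | None = None,
) -> float:
    """Penalised Gaussian discrepancy between model and observed summary."""
    if s <= 0 or r <= 0:
        raise ValueError("s and r must be positive")
    penalty = penalty or PenaltySpec()
    acc, rt, tfrac = simulate_summary(s, r, n_sim, seed, cfg_base)
    pen = penalty.value(s, r, tfrac)
    if not np.isfinite(rt):
        # nothing decided: dominated by the timeout penalty
        return pen if pen > 0 else penalty.floor
    return (
        (summary.accuracy - acc) ** 2 / SIGMA_A**2
        + (summary.mean_rt_ms - rt) ** 2 / SIGMA_RT_MS**2
        + pen
    )


def retained_indices(
    chain_len: int = 3000, burn: int = 499, thin: int = 5
) -> np.ndarray:
    """Indices kept by the retention rule: drop the first ``burn`` samples,
    keep every ``thin``-th of the rest (3000/499/5 retains 501)."""
    return np.arange(burn, chain_len, thin)


@dataclass
class FitResult:
    """Posterior samples and diagnostics of one condition's fit."""

    samples: pd.DataFrame  # columns log_s, log_r, discrepancy, pred_* ...
    best: dict  # parameters and stats of the minimum-discrepancy sample
    acceptance_rate: float
    chain: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_retained(self) -> int:
        return len(self.samples)


def _log_prior(log_s: float, log_r: float, prior_sd: float = 10.0) -> float:
    return -0.5 * (log_s**2 + log_r**2) / prior_sd**2


def mcmc_fit(
    summary: BehaviouralSummary,
    chain_len: int = 3000,
    burn: int = 499,
    thin: int = 5,
    n_sim: int = 1000,
    seed: int | None = None,
    cfg_base: BattmConfig | None = None,
    penalty: PenaltySpec | None = None,
    init: tuple[float, float] | None = None,
    proposal_sd: float = 0.3,
    adapt_interval: int = 100,
    dr_scale: float = 0.2,
    s_min: float = 0.1,
) -> FitResult:
    """Fit (s, r) to a behavioural summary with DRAM over log-parameters.

    Adaptive Metropolis: the Gaussian proposal covariance starts diagonal
    with SD ``proposal_sd`` and is re-estimated from the chain history
    every ``adapt_interval`` iterations (scaled by 2.38^2/d). Each
    rejected first-stage proposal triggers one delayed-rejection stage
    with the proposal shrunk by ``dr_scale``. Priors are wide Gaussians
    on (log s, log r) with SD 10, plus the hard constraint ``s > s_min``.
    The stochastic objective is re-simulated with a fresh child seed per
    proposal.

    Returns a :class:`FitResult` with the retained samples
    (burn/thinning rule), the best (minimum-discrepancy) sample and the
    full chain for diagnostics.
    """
    rng = np.random.default_rng(seed)
    d = 2
    cov = np.eye(d) * proposal_sd**2
    eps_reg = 1e-6 * np.eye(d)

    def log_target(x: np.ndarray) -> tuple[float, float]:
        s, r = float(np.exp(x[0])), float(np.exp(x[1]))
        if s <= s_min:
            return -np.inf, np.inf
        disc = discrepancy(
            s, r, summary, n_sim=n_sim,
            seed=np.random.default_rng(rng.integers(2**31)),
            cfg_base=cfg_base, penalty=penalty,
        )
        return -0.5 * disc + _log_prior(x[0], x[1]), disc

    if init is None:
        x = np.array([np.log(4.0), np.log(2.0)])
    else:
        x = np.array([np.log(init[0]), np.log(init[1])])
    lp, disc = log_target(x)
    if not np.isfinite(lp):
        raise ValueError("initial point violates the s > s_min constraint")

    chain = np.empty((chain_len, d))
    discs = np.empty(chain_len)
    n_accept = 0

    def q_logpdf(a: np.ndarray, b: np.ndarray, C: np.ndarray) -> float:
        diff = a - b
        Ci = np.linalg.inv(C)
        _, logdet = np.linalg.slogdet(C)
        return -0.5 * (diff @ Ci @ diff + logdet)

    for i in range(chain_len):
        L = np.linalg.cholesky(cov + eps_reg)
        y1 = x + L @ rng.standard_normal(d)
        lp1, disc1 = log_target(y1)
        log_a1 = min(0.0, lp1 - lp)
        if np.log(rng.random()) < log_a1:
            x, lp, disc = y1, lp1, disc1
            n_accept += 1
        else:
            # one delayed-rejection stage with a shrunk proposal
            y2 = x + dr_scale * (L @ rng.standard_normal(d))
            lp2, disc2 = log_target(y2)
            if np.isfinite(lp2):
                log_a1_rev = min(0.0, lp1 - lp2)
                num = (
                    lp2
                    + q_logpdf(y1, y2, cov + eps_reg)
                    + np.log1p(-np.exp(min(log_a1_rev, -1e-12)))
                )
                den = (
                    lp
                    + q_logpdf(y1, x, cov + eps_reg)
                    + np.log1p(-np.exp(min(log_a1, -1e-12)))
                )
                if np.log(rng.random()) < num - den:
                    x, lp, disc = y2, lp2, disc2
                    n_accept += 1
        chain[i] = x
        discs[i] = disc
        if (i + 1) % adapt_interval == 0 and i > 2 * d:
            emp = np.cov(chain[: i + 1].T)
            cov = (2.38**2 / d) * emp + eps_reg

    keep = retained_indices(chain_len, burn, thin)
    samples = pd.DataFrame(
        {
            "log_s": chain[keep, 0],
            "log_r": chain[keep, 1],
            "s": np.exp(chain[keep, 0]),
            "r": np.exp(chain[keep, 1]),
            "discrepancy": discs[keep],
        }
    )
    ibest = int(samples["discrepancy"].idxmin())
    best = samples.loc[ibest].to_dict()
    return FitResult(
        samples=samples,
        best=best,
        acceptance_rate=n_accept / chain_len,
        chain=pd.DataFrame(
            {"log_s": chain[:, 0], "log_r": chain[:, 1], "discrepancy": discs}
        ),
    )


def fit_kprime(
    pairs: pd.DataFrame | np.ndarray,
    max_coherence: float | None = None,
) -> float:
    """Least-squares estimate of K' in the scaling law ``r^2 = K'/c``.

    ``pairs`` holds coherence (percent, must be > 0) and sensory
    uncertainty ``r`` per condition — a DataFrame with columns
    ``coherence`` and ``r`` or an array of (c, r) rows. Minimising
    ``sum_i (r_i^2 - K'/c_i)^2`` gives the closed form
    ``K' = sum(r_i^2 / c_i) / sum(1 / c_i^2)``. ``max_coherence``
    optionally restricts the fit to low and intermediate difficulties,
    where the scaling law holds best.
    """
    if isinstance(pairs, pd.DataFrame):
        c = pairs["coherence"].to_numpy(dtype=float)
        r = pairs["r"].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        c, r = arr[:, 0], arr[:, 1]
    mask = c > 0
    if max_coherence is not None:
        mask &= c <= max_coherence
    c, r = c[mask], r[mask]
    if len(c) == 0:
        raise ValueError("no usable (coherence, r) pairs (need coherence > 0)")
    return float(np.sum(r**2 / c) / np.sum(1.0 / c**2))
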