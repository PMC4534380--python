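"""Confidence computation, threshold criterion and trial execution.

Confidence in alternative ``i`` is the posterior density of the decision
state evaluated at the stable fixed point ``phi_i`` — a density, not a
probability, so values above 1 are legitimate. A decision is triggered the
first time any alternative's confidence reaches the bound ``lambda``;
filtering nevertheless continues to the end of the stimulus so that
post-decision confidence (read out 100 ms after the crossing, i.e. during
the motor part of the non-decision time) and re-decision measures are
available from the same trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimulus import StimulusTrace, make_stimulus_batch, StimulusSpec
from .ukf import BattmConfig, Belief, ukf_update, state_transition, observation_map

__all__ = [
    "confidence",
    "gaussian_density_at",
    "TrialRecord",
    "TrialBatch",
    "run_trial",
    "run_trials",
    "simulate_condition",
    "redecision_fraction",
    "post_decision_confidence",
]


def gaussian_density_at(
    mean: np.ndarray, cov: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Density of N(mean, cov) at each row of ``points``, batched.

    ``mean`` (B, N) or (N,), ``cov`` (B, N, N) or (N, N), ``points``
    (K, N). Returns (B, K) (or (K,) unbatched).
    """
    mean = np.asarray(mean, dtype=float)
    squeeze = mean.ndim == 1
    if squeeze:
        mean, cov = mean[None], np.asarray(cov)[None]
    cov = np.asarray(cov, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = mean.shape[-1]
    diffs = points[None, :, :] - mean[:, None, :]  # (B, K, N)
    cov_inv = np.linalg.inv(cov)
    maha = np.einsum("bkn,bnm,bkm->bk", diffs, cov_inv, diffs)
    det = np.linalg.det(cov)
    if np.any(det <= 0):
        raise np.linalg.LinAlgError("posterior covariance is singular")
    norm = (2.0 * np.pi) ** (n / 2.0) * np.sqrt(det)
    dens = np.exp(-0.5 * maha) / norm[:, None]
    return dens[0] if squeeze else dens


def confidence(belief: Belief, phi: np.ndarray) -> float | np.ndarray:
    """Posterior density of the decision state at fixed point(s) ``phi``."""
    out = gaussian_density_at(belief.mean, belief.cov, phi)
    return float(out[0]) if np.ndim(phi) == 1 else out


@dataclass
class TrialRecord:
    """Full per-step traces of one trial."""

    choice: int | None
    rt_ms: float | None
    cross_step: int | None
    timeout: bool
    means: np.ndarray  # (T, N)
    covs: np.ndarray  # (T, N, N)
    confidence: np.ndarray  # (T, K)
    gain: np.ndarray  # (T, N, F)
    cross_cov: np.ndarray  # (T, N, F)
    prediction_error: np.ndarray  # (T, F)
    post_decision_confidence: float | None
    post_conf_truncated: bool
    stimulus: StimulusTrace | None
    cfg: BattmConfig

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.confidence.shape[0]) + 1) * self.cfg.dt_ms

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-step table (state, uncertainty, confidence, gain, cross-cov)."""
        t, n = self.means.shape
        f = self.prediction_error.shape[1]
        cols: dict[str, np.ndarray] = {"t_ms": self.times_ms}
        for i in range(n):
            cols[f"z{i + 1}"] = self.means[:, i]
            cols[f"P{i + 1}{i + 1}"] = self.covs[:, i, i]
            cols[f"conf{i + 1}"] = self.confidence[:, i]
        for i in range(n):
            for j in range(f):
                cols[f"K{i + 1}{j + 1}"] = self.gain[:, i, j]
                cols[f"C{i + 1}{j + 1}"] = self.cross_cov[:, i, j]
        for j in range(f):
            cols[f"eps{j + 1}"] = self.prediction_error[:, j]
        return pd.DataFrame(cols)


@dataclass
class TrialBatch:
    """Vectorised results for a batch of trials sharing one configuration."""

    choice: np.ndarray  # (B,), -1 where no crossing occurred
    rt_ms: np.ndarray  # (B,), nan where no crossing occurred
    cross_step: np.ndarray  # (B,), step index of the crossing, -1 if none
    timeout: np.ndarray  # (B,) bool: no crossing by timeout_ms
    confidence: np.ndarray  # (B, T, K); zero beyond n_steps_run
    post_decision_confidence: np.ndarray  # (B,), nan where undecided
    post_conf_truncated: np.ndarray  # (B,) bool
    truth: np.ndarray  # (T,)
    n_steps_run: int
    cfg: BattmConfig
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def decided(self) -> np.ndarray:
        """Trials with a threshold crossing at or before the timeout."""
        return (self.choice >= 0) & ~self.timeout

    def correct(self, true_alt: int | None = None) -> np.ndarray:
        """Correctness of decided trials against the (final) true alternative."""
        target = self.truth[-1] if true_alt is None else true_alt
        return self.choice == target

    def accuracy(self, true_alt: int | None = None) -> float:
        """Fraction correct among decided (non-timeout) trials."""
        dec = self.decided
        if not np.any(dec):
            return np.nan
        return float(np.mean(self.correct(true_alt)[dec]))

    def mean_rt_correct(self, true_alt: int | None = None) -> float:
        sel = self.decided & self.correct(true_alt)
        if not np.any(sel):
            return np.nan
        return float(np.mean(self.rt_ms[sel]))

    def timeout_fraction(self) -> float:
        return float(np.mean(self.timeout))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "choice": self.choice,
                "rt_ms": self.rt_ms,
                "timeout": self.timeout,
                "post_decision_confidence": self.post_decision_confidence,
            }
        )


def run_trials(
    observations: np.ndarray,
    truth: np.ndarray,
    cfg: BattmConfig,
    collect_traces: bool = False,
    stop_early: bool = False,
    extra_ms: float = 100.0,
    t0_mode: str = "dead_time",
) -> TrialBatch:
    """Filter a batch of stimulus streams and apply the decision criterion.

    The belief is initialised as ``N(mu_0, p0^2 I)``. At every step the
    confidence of each alternative is computed; the first step at which
    any confidence reaches ``lambda_thresh`` fixes choice and reaction
    time. Ties are broken towards the larger density, exact ties towards
    the lower alternative index.

    The non-decision time ``T0`` enters in one of two ways:

    ``t0_mode="dead_time"``
        Filtering starts only after ``T0`` of stimulus time has elapsed
        (sensory latency); the reaction time is the crossing time and
        therefore includes ``T0``. This is the convention of the
        single-decision (speed-accuracy and fitting) experiments.
    ``t0_mode="onset"``
        Filtering starts at stimulus onset and ``T0`` is added to the
        crossing time as motor latency. Used for re-decision and gain
        analyses, where the criterion is evaluated over the whole trial.

    With ``stop_early`` the step loop ends once every trial has crossed
    and the post-decision read-out horizon (``extra_ms`` after the last
    crossing) is covered — appropriate for accuracy/RT summaries; full
    re-decision analyses need the complete run.
    """
    if t0_mode not in ("dead_time", "onset"):
        raise ValueError("t0_mode must be 'dead_time' or 'onset'")
    obs = np.asarray(observations, dtype=float)
    if obs.ndim == 2:
        obs = obs[None]
    B, T, _ = obs.shape
    truth = np.asarray(truth, dtype=int)
    phi = cfg.stable_fixed_points()
    mu0 = cfg.neutral_state()
    K_alt = phi.shape[0]

    n_dead = int(round(cfg.T0_ms / cfg.dt_ms)) if t0_mode == "dead_time" else 0
    rt_offset = 0.0 if t0_mode == "dead_time" else cfg.T0_ms
    extra_steps = int(round(extra_ms / cfg.dt_ms))
    timeout_step = int(round(cfg.timeout_ms / cfg.dt_ms))

    mean = np.tile(mu0, (B, 1))
    cov = np.tile(cfg.P0, (B, 1, 1))

    conf = np.zeros((B, T, K_alt))
    prior_conf = gaussian_density_at(mean, cov, phi)  # (B, K)
    cross_idx = np.full(B, -1, dtype=int)

    if collect_traces:
        n, f = cfg.n_alt, cfg.n_features
        traces = {
            "mean": np.zeros((B, T, n)),
            "cov": np.zeros((B, T, n, n)),
            "gain": np.zeros((B, T, n, f)),
            "cross_cov": np.zeros((B, T, n, f)),
            "prediction_error": np.zeros((B, T, f)),
        }
    else:
        traces = {}

    transition = lambda z: state_transition(z, cfg)  # noqa: E731
    obs_map = lambda z: observation_map(z, cfg)  # noqa: E731
    Q, R, ut = cfg.Q_step, cfg.R, cfg.ut

    n_steps_run = T
    for t in range(T):
        if t < n_dead:
            conf[:, t, :] = prior_conf
            if collect_traces:
                traces["mean"][:, t] = mean
                traces["cov"][:, t] = cov
            continue
        mean, cov, pred, K, eps = ukf_update(
            mean, cov, obs[:, t, :], transition, obs_map, Q, R, ut
        )
        conf[:, t, :] = gaussian_density_at(mean, cov, phi)
        if collect_traces:
            traces["mean"][:, t] = mean
            traces["cov"][:, t] = cov
            traces["gain"][:, t] = K
            traces["cross_cov"][:, t] = pred.cross_cov
            traces["prediction_error"][:, t] = eps
        newly = (cross_idx < 0) & (conf[:, t, :].max(axis=1) >= cfg.lambda_thresh)
        cross_idx[newly] = t
        if stop_early and not collect_traces and np.all(cross_idx >= 0):
            if t >= cross_idx.max() + extra_steps:
                n_steps_run = t + 1
                break

    crossed = cross_idx >= 0
    choice = np.full(B, -1, dtype=int)
    rt = np.full(B, np.nan)
    if np.any(crossed):
        idx = cross_idx[crossed]
        choice[crossed] = np.argmax(conf[crossed, idx, :], axis=1)
        rt[crossed] = (idx + 1) * cfg.dt_ms + rt_offset
    timeout = ~crossed | (rt > cfg.timeout_ms)

    post_conf = np.full(B, np.nan)
    post_trunc = np.zeros(B, dtype=bool)
    if np.any(crossed):
        tgt = cross_idx[crossed] + extra_steps
        last = n_steps_run - 1
        post_trunc[crossed] = tgt > last
        tgt = np.minimum(tgt, last)
        post_conf[crossed] = conf[crossed, tgt, choice[crossed]]

    return TrialBatch(
        choice=choice,
        rt_ms=rt,
        cross_step=cross_idx,
        timeout=timeout,
        confidence=conf,
        post_decision_confidence=post_conf,
        post_conf_truncated=post_trunc,
        truth=truth,
        n_steps_run=n_steps_run,
        cfg=cfg,
        traces=traces,
    )


def run_trial(
    stimulus: StimulusTrace, cfg: BattmConfig, t0_mode: str = "dead_time"
) -> TrialRecord:
    """Run one trial with full per-step traces.

    The filter itself is deterministic; all randomness lives in the
    stimulus.
    """
    batch = run_trials(
        stimulus.observations,
        stimulus.truth,
        cfg,
        collect_traces=True,
        t0_mode=t0_mode,
    )
    crossed = batch.choice[0] >= 0
    return TrialRecord(
        choice=int(batch.choice[0]) if crossed else None,
        rt_ms=float(batch.rt_ms[0]) if crossed else None,
        cross_step=int(batch.cross_step[0]) if crossed else None,
        timeout=bool(batch.timeout[0]),
        means=batch.traces["mean"][0],
        covs=batch.traces["cov"][0],
        confidence=batch.confidence[0],
        gain=batch.traces["gain"][0],
        cross_cov=batch.traces["cross_cov"][0],
        prediction_error=batch.traces["prediction_error"][0],
        post_decision_confidence=(
            float(batch.post_decision_confidence[0]) if crossed else None
        ),
        post_conf_truncated=bool(batch.post_conf_truncated[0]),
        stimulus=stimulus,
        cfg=cfg,
    )


def simulate_condition(
    spec: StimulusSpec,
    cfg: BattmConfig,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
    **kwargs,
) -> TrialBatch:
    """Draw ``n_trials`` stimuli from ``spec`` and run them through the model."""
    obs, truth = make_stimulus_batch(spec, n_trials, seed)
    return run_trials(obs, truth, cfg, **kwargs)


def redecision_fraction(
    record: TrialRecord | TrialBatch, truth: np.ndarray | None = None
) -> float | np.ndarray:
    """Fraction of trial time the criterion holds for the current truth.

    At each step the confidence of the *currently generating* alternative
    is compared against ``lambda``; the denominator is the full trial
    (including the initial non-decision dead time, during which the prior
    confidence applies).
    """
    if isinstance(record, TrialBatch):
        conf = record.confidence[:, : record.n_steps_run, :]
        truth_seq = record.truth if truth is None else np.asarray(truth, int)
        if record.n_steps_run != record.confidence.shape[1]:
            raise ValueError("trial was stopped early; rerun without stop_early")
        sel = conf[:, np.arange(conf.shape[1]), truth_seq]
        return np.mean(sel >= record.cfg.lambda_thresh, axis=1)
    truth_seq = (
        record.stimulus.truth if truth is None else np.asarray(truth, int)
    )
    sel = record.confidence[np.arange(len(truth_seq)), truth_seq]
    return float(np.mean(sel >= record.cfg.lambda_thresh))


def post_decision_confidence(
    record: TrialRecord, extra_ms: float = 100.0
) -> tuple[float, bool]:
    """Confidence in the chosen alternative ``extra_ms`` after the crossing.

    Filtering has continued on the same stimulus, modelling the motor
    delay between the internal decision and the overt response. Returns
    ``(density, truncated)``; ``truncated`` flags read-outs clipped to the
    last available step because the decision fell too close to trial end.
    """
    if record.choice is None:
        raise ValueError("no decision occurred in this trial")
    tgt = record.cross_step + int(round(extra_ms / record.cfg.dt_ms))
    last = record.confidence.shape[0] - 1
    truncated = tgt > last
    tgt = min(tgt, last)
    return float(record.confidence[tgt, record.choice]), truncated
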