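"""Batch experiment runners: parameter maps, gain traces and model contrasts.

These functions reproduce the model's headline simulation analyses:

* the speed-accuracy map over stimulus noise ``s`` and sensory
  uncertainty ``r`` (single decisions),
* the re-decision map over ``r`` and dynamics uncertainty ``q``
  (switching stimuli, fraction of time in the correct decision state),
* within-trial gain/cross-covariance traces (top-down gain modulation),
* post-decision confidence as a function of motion coherence, and
* the contrast between the pure attractor baseline (fixed points drift
  with input strength) and the Bayesian model (fixed points invariant).

Every cell of a grid uses a deterministically derived child seed of the
master seed, so whole maps are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .attractor import pure_attractor_trial
from .decision import TrialBatch, redecision_fraction, run_trials, simulate_condition
from .stimulus import StimulusSpec, make_stimulus_batch
from .ukf import BattmConfig

__all__ = [
    "GridResult",
    "speed_accuracy_map",
    "redecision_map",
    "gain_trace_demo",
    "confidence_by_coherence",
    "pure_vs_battm_contrast",
    "SWITCH_SCHEDULE",
]

#: 800 ms of alternative 0 followed by 800 ms of alternative 1.
SWITCH_SCHEDULE: tuple[tuple[int, float], ...] = ((0, 800.0), (1, 800.0))


def _child_seeds(seed: int | None, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


@dataclass
class GridResult:
    """Per-cell behavioural metrics on a 2-D parameter grid.

    ``metrics`` maps metric name to an array of shape
    ``(len(row_values), len(col_values))``. Cells where more than half of
    the trials timed out are flagged in ``masked`` but their raw values
    are kept.
    """

    row_name: str
    row_values: np.ndarray
    col_name: str
    col_values: np.ndarray
    metrics: dict[str, np.ndarray]
    masked: np.ndarray
    n_trials: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rv in enumerate(self.row_values):
            for j, cv in enumerate(self.col_values):
                rec = {self.row_name: rv, self.col_name: cv,
                       "masked": bool(self.masked[i, j])}
                for name, arr in self.metrics.items():
                    rec[name] = arr[i, j]
                rows.append(rec)
        return pd.DataFrame(rows)


def speed_accuracy_map(
    s_grid: np.ndarray,
    r_grid: np.ndarray,
    q: float = 0.1,
    p0: float = 5.0,
    n_trials: int = 1000,
    trial_ms: float = 1100.0,
    seed: int | None = None,
    cfg_base: BattmConfig | None = None,
) -> GridResult:
    """Accuracy and mean correct RT over a noise x sensory-uncertainty grid.

    Single-decision trials of one alternative; accuracy counts correct
    among decided trials, mean RT is over correct trials only and
    includes the non-decision time. Cells with more than 50% timeouts
    (RT > 1000 ms) are flagged as masked.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    base = cfg_base or BattmConfig()
    acc = np.full((len(s_grid), len(r_grid)), np.nan)
    rt = np.full_like(acc, np.nan)
    tout = np.full_like(acc, np.nan)
    seeds = iter(_child_seeds(seed, len(s_grid) * len(r_grid)))
    for i, s in enumerate(s_grid):
        for j, r in enumerate(r_grid):
            cfg = replace(base, r=float(r), q=q, p0=p0)
            spec = StimulusSpec(
                noise_level=float(s),
                schedule=((0, trial_ms),),
                dt_ms=cfg.dt_ms,
                frame_ms=cfg.dt_ms,
            )
            batch = simulate_condition(
                spec, cfg, n_trials,
                seed=np.random.default_rng(next(seeds)),
                stop_early=True,
            )
            acc[i, j] = batch.accuracy(true_alt=0)
            rt[i, j] = batch.mean_rt_correct(true_alt=0)
            tout[i, j] = batch.timeout_fraction()
    return GridResult(
        row_name="s", row_values=s_grid,
        col_name="r", col_values=r_grid,
        metrics={"accuracy": acc, "mean_rt_correct_ms": rt,
                 "timeout_fraction": tout},
        masked=tout > 0.5,
        n_trials=n_trials, seed=seed,
    )


def redecision_map(
    r_grid: np.ndarray,
    q_grid: np.ndarray,
    s: float = 4.0,
    n_trials: int = 1000,
    schedule: tuple[tuple[int, float], ...] = SWITCH_SCHEDULE,
    seed: int | None = None,
    cfg_base: BattmConfig | None = None,
) -> GridResult:
    """Mean fraction of time in the correct decision state, over (r, q).

    Switching stimuli; the criterion is evaluated at every step of the
    full trial against the currently generating alternative. Filtering
    runs from stimulus onset (``t0_mode="onset"``).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    base = cfg_base or BattmConfig()
    frac = np.full((len(r_grid), len(q_grid)), np.nan)
    tout = np.full_like(frac, np.nan)
    seeds = iter(_child_seeds(seed, len(r_grid) * len(q_grid)))
    for i, r in enumerate(r_grid):
        for j, q in enumerate(q_grid):
            cfg = replace(base, r=float(r), q=float(q))
            spec = StimulusSpec(
                noise_level=s, schedule=schedule,
                dt_ms=cfg.dt_ms, frame_ms=cfg.dt_ms,
            )
            batch = simulate_condition(
                spec, cfg, n_trials,
                seed=np.random.default_rng(next(seeds)),
                t0_mode="onset",
            )
            frac[i, j] = float(np.mean(redecision_fraction(batch)))
            tout[i, j] = batch.timeout_fraction()
    return GridResult(
        row_name="r", row_values=r_grid,
        col_name="q", col_values=q_grid,
        metrics={"redecision_fraction": frac, "timeout_fraction": tout},
        masked=tout > 0.5,
        n_trials=n_trials, seed=seed,
    )


def gain_trace_demo(
    s: float = 4.0,
    r: float = 2.4,
    q: float = 0.5,
    n_trials: int = 100,
    schedule: tuple[tuple[int, float], ...] = SWITCH_SCHEDULE,
    seed: int | None = None,
    cfg_base: BattmConfig | None = None,
) -> pd.DataFrame:
    """Per-step gain and cross-covariance magnitudes on switch trials.

    Returns a tidy frame with, per trial and step, the Frobenius norms of
    the Kalman gain and of the state-observation cross-covariance. These
    peak while the posterior transits between fixed points and collapse
    once a decision has settled — the model's within-trial top-down gain
    modulation.
    """
    cfg = replace(cfg_base or BattmConfig(), r=r, q=q)
    spec = StimulusSpec(
        noise_level=s, schedule=schedule, dt_ms=cfg.dt_ms, frame_ms=cfg.dt_ms
    )
    obs, truth = make_stimulus_batch(spec, n_trials, seed)
    batch = run_trials(obs, truth, cfg, collect_traces=True, t0_mode="onset")
    gain = np.linalg.norm(batch.traces["gain"], axis=(2, 3))  # (B, T)
    cross = np.linalg.norm(batch.traces["cross_cov"], axis=(2, 3))
    B, T = gain.shape
    t_ms = (np.arange(T) + 1) * cfg.dt_ms
    return pd.DataFrame(
        {
            "trial": np.repeat(np.arange(B), T),
            "t_ms": np.tile(t_ms, B),
            "gain_norm": gain.ravel(),
            "crosscov_norm": cross.ravel(),
            "truth": np.tile(truth, B),
        }
    )


def switch_window_stats(
    traces: pd.DataFrame, switch_ms: float = 800.0, window_ms: float = 300.0
) -> pd.DataFrame:
    """Mean cross-covariance norm before vs after the stimulus switch.

    Compares the ``window_ms`` preceding the switch with the window
    following it, per trial.
    """
    pre = traces[
        (traces.t_ms > switch_ms - window_ms) & (traces.t_ms <= switch_ms)
    ]
    post = traces[
        (traces.t_ms > switch_ms) & (traces.t_ms <= switch_ms + window_ms)
    ]
    out = pd.DataFrame(
        {
            "pre_crosscov": pre.groupby("trial").crosscov_norm.mean(),
            "post_crosscov": post.groupby("trial").crosscov_norm.mean(),
        }
    )
    return out


def gain_crosscov_correlation(traces: pd.DataFrame) -> np.ndarray:
    """Per-trial Pearson correlation of gain and cross-covariance norms."""
    return (
        traces.groupby("trial")
        .apply(
            lambda d: np.corrcoef(d.gain_norm, d.crosscov_norm)[0, 1],
            include_groups=False,
        )
        .to_numpy()
    )


def confidence_by_coherence(
    table: pd.DataFrame,
    q: float = 0.5,
    n_trials: int = 2500,
    n_trials_zero: int | None = None,
    trial_ms: float = 1200.0,
    seed: int | None = None,
    cfg_base: BattmConfig | None = None,
) -> pd.DataFrame:
    """Post-decision confidence by signed coherence and correctness.

    ``table`` must have columns ``coherence``, ``s``, ``r`` (one row per
    coherence level, the behavioural mapping from task difficulty to
    stimulus noise and sensory uncertainty). For each signed coherence
    (negative = alternative 1, positive = alternative 0; the 0% level is
    split between both) single-decision trials are simulated and the
    confidence of the chosen alternative is read out 100 ms after the
    threshold crossing. Returns mean and standard error per signed
    coherence x correctness cell.
    """
    n_trials_zero = 2 * n_trials if n_trials_zero is None else n_trials_zero
    base = cfg_base or BattmConfig()
    rows = []
    seeds = iter(_child_seeds(seed, 2 * len(table)))
    for _, cond in table.iterrows():
        c = float(cond["coherence"])
        for sign, alt in ((+1, 0), (-1, 1)):
            if c == 0.0 and sign < 0:
                continue
            n = n_trials_zero if c == 0.0 else n_trials
            cfg = replace(base, r=float(cond["r"]), q=q)
            spec = StimulusSpec(
                noise_level=float(cond["s"]),
                schedule=((alt, trial_ms),),
                dt_ms=cfg.dt_ms,
                frame_ms=cfg.dt_ms,
            )
            batch = simulate_condition(
                spec, cfg, n,
                seed=np.random.default_rng(next(seeds)),
                stop_early=True,
            )
            dec = batch.decided
            correct = batch.correct(true_alt=alt)
            for is_corr in (True, False):
                sel = dec & (correct == is_corr)
                vals = batch.post_decision_confidence[sel]
                vals = vals[np.isfinite(vals)]
                rows.append(
                    {
                        "coherence": sign * c,
                        "correct": is_corr,
                        "n": int(sel.sum()),
                        "mean_confidence": float(np.mean(vals)) if len(vals) else np.nan,
                        "se_confidence": (
                            float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                            if len(vals) > 1
                            else np.nan
                        ),
                        "timeout_fraction": batch.timeout_fraction(),
                    }
                )
    return pd.DataFrame(rows)


def pure_vs_battm_contrast(
    input_levels: tuple[float, ...] = (20.0, 40.0, 80.0),
    uncertainty_settings: tuple[tuple[float, float], ...] = (
        (1.9, 0.5),
        (3.0, 0.5),
        (1.9, 1.0),
    ),
    s: float = 1.0,
    schedule: tuple[tuple[int, float], ...] = SWITCH_SCHEDULE,
    seed: int | None = None,
    cfg_base: BattmConfig | None = None,
) -> dict:
    """Trajectory bundles contrasting the two architectures on switch trials.

    For the pure attractor model the attained asymptotic state scales
    with the evidence input ``I``; for the Bayesian model the attained
    fixed point is the same across (r, q) settings — uncertainties change
    timing, not the state's destination.

    Returns a dict with ``pure`` (input level -> trajectory array) and
    ``battm`` ((r, q) -> posterior-mean array), plus summary scalars:
    ``pure_asymptote`` (state of the winning component just before the
    switch, per input level) and ``battm_attained`` (mean posterior
    state of the winning component over the last quarter of the
    pre-switch segment — the settled location, per setting).
    """
    base = cfg_base or BattmConfig()
    ss = np.random.SeedSequence(seed).spawn(2)
    pure = {}
    pure_asym = {}
    pre_steps = int(round(schedule[0][1] / base.dt_ms))
    rng_pure = np.random.default_rng(ss[0])
    for I in input_levels:
        traj = pure_attractor_trial(
            I, 0.2, list(schedule), dt_ms=base.dt_ms, seed=rng_pure,
            params=base.hopfield, time_unit_ms=base.time_unit_ms,
        )
        pure[I] = traj
        pure_asym[I] = float(traj[pre_steps, schedule[0][0]])

    # same observation stream for every uncertainty setting
    spec = StimulusSpec(
        noise_level=s, schedule=schedule, dt_ms=base.dt_ms, frame_ms=base.dt_ms
    )
    obs, truth = make_stimulus_batch(spec, 1, np.random.default_rng(ss[1]))
    battm = {}
    battm_attained = {}
    settle = slice(3 * pre_steps // 4, pre_steps)
    for r, q in uncertainty_settings:
        cfg = replace(base, r=float(r), q=float(q))
        batch = run_trials(obs, truth, cfg, collect_traces=True, t0_mode="onset")
        means = batch.traces["mean"][0]
        battm[(r, q)] = means
        battm_attained[(r, q)] = float(
            means[settle, schedule[0][0]].mean()
        )
    return {
        "pure": pure,
        "battm": battm,
        "pure_asymptote": pure_asym,
        "battm_attained": battm_attained,
    }
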