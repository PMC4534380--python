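"""Gaussian feature-vector stimulus streams (the "single dot" task).

Each decision alternative is a prototype feature vector; at stimulus time
the observer receives a dot position drawn from an isotropic Gaussian
centred on the prototype of the currently true alternative, with noise
level ``s``. Mid-trial category switches are expressed through the
schedule, which lists (alternative, duration) segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PROTOTYPES",
    "StimulusSpec",
    "StimulusTrace",
    "make_stimulus",
    "make_stimulus_batch",
]

#: Prototype feature vectors as columns: alternative 0 at [0.71, 0.71],
#: alternative 1 at [-0.71, -0.71] (opposite points near the unit circle).
DEFAULT_PROTOTYPES = np.array([[0.71, -0.71], [0.71, -0.71]])


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a stimulus stream.

    ``prototypes`` holds one column per alternative. ``frame_ms`` is how
    long each drawn dot position is held on screen; the default equals
    ``dt_ms`` so that every model step sees a fresh draw, which is the
    convention used for all quantitative experiments (a 40 ms frame
    reproduces the illustrative display convention instead).
    """

    prototypes: np.ndarray = field(
        default_factory=lambda: DEFAULT_PROTOTYPES.copy()
    )
    noise_level: float = 2.0
    schedule: tuple[tuple[int, float], ...] = ((0, 800.0),)
    frame_ms: float = 4.0
    dt_ms: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "prototypes", np.asarray(self.prototypes, dtype=float)
        )
        object.__setattr__(
            self, "schedule", tuple((int(a), float(d)) for a, d in self.schedule)
        )
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if self.dt_ms <= 0 or self.frame_ms <= 0:
            raise ValueError("dt_ms and frame_ms must be positive")
        ratio = self.frame_ms / self.dt_ms
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("frame_ms must be a positive multiple of dt_ms")
        if len(self.schedule) == 0:
            raise ValueError("schedule is empty")
        n_alt = self.prototypes.shape[1]
        for alt, dur in self.schedule:
            if not 0 <= alt < n_alt:
                raise ValueError(f"schedule refers to unknown alternative {alt}")
            if dur <= 0:
                raise ValueError("schedule durations must be positive")

    @property
    def n_alt(self) -> int:
        return self.prototypes.shape[1]

    @property
    def n_features(self) -> int:
        return self.prototypes.shape[0]

    @property
    def n_steps(self) -> int:
        total = sum(d for _, d in self.schedule)
        return int(round(total / self.dt_ms))

    def truth_sequence(self) -> np.ndarray:
        """Generating alternative at every model step, length ``n_steps``."""
        parts = [
            np.full(int(round(d / self.dt_ms)), a, dtype=int)
            for a, d in self.schedule
        ]
        return np.concatenate(parts)

    def with_(self, **changes) -> "StimulusSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class StimulusTrace:
    """A realised stimulus stream: observations plus ground truth."""

    observations: np.ndarray  # (T, n_features)
    truth: np.ndarray  # (T,), generating alternative per step
    spec: StimulusSpec
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return self.observations.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Time at the end of each step."""
        return (np.arange(self.n_steps) + 1) * self.spec.dt_ms

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "t_ms": self.times_ms,
            **{
                f"x{i + 1}": self.observations[:, i]
                for i in range(self.observations.shape[1])
            },
            "truth": self.truth,
        }
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: StimulusSpec) -> "StimulusTrace":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x")]
        return cls(
            observations=df[xcols].to_numpy(dtype=float),
            truth=df["truth"].to_numpy(dtype=int),
            spec=spec,
        )


def _draw_observations(
    spec: StimulusSpec, rng: np.random.Generator, batch: int | None
) -> np.ndarray:
    truth = spec.truth_sequence()
    steps_per_frame = int(round(spec.frame_ms / spec.dt_ms))
    n_frames = int(np.ceil(len(truth) / steps_per_frame))
    frame_truth = truth[::steps_per_frame][:n_frames]
    means = spec.prototypes.T[frame_truth]  # (n_frames, n_features)
    shape = (
        (n_frames, spec.n_features)
        if batch is None
        else (batch, n_frames, spec.n_features)
    )
    draws = means + spec.noise_level * rng.standard_normal(shape)
    # hold each frame for steps_per_frame model steps
    obs = np.repeat(draws, steps_per_frame, axis=-2)
    return obs[..., : len(truth), :]


def make_stimulus(
    spec: StimulusSpec, seed: int | np.random.Generator | None = None
) -> StimulusTrace:
    """Draw one stimulus stream.

    One fresh dot position per frame, from N(mu_i, s^2 I) where ``i`` is
    the scheduled alternative, held for ``frame_ms / dt_ms`` model steps.
    Bit-reproducible for a fixed integer seed.
    """
    rng = np.random.default_rng(seed)
    obs = _draw_observations(spec, rng, batch=None)
    return StimulusTrace(
        observations=obs,
        truth=spec.truth_sequence(),
        spec=spec,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def make_stimulus_batch(
    spec: StimulusSpec,
    n_trials: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_trials`` independent streams sharing one spec.

    Returns
    -------
    observations : ndarray (n_trials, T, n_features)
    truth : ndarray (T,)
        Shared ground-truth schedule.
    """
    rng = np.random.default_rng(seed)
    obs = _draw_observations(spec, rng, batch=n_trials)
    return obs, spec.truth_sequence()
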