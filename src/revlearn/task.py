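"""Anticorrelated two-armed probabilistic reversal task.

One of two options carries an 80% reward / 20% punishment probability;
the other option carries the inverted probabilities. The session is
divided into a stable pre-reversal phase, a reversal phase in which the
contingency switches several times, and a stable post-reversal phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASE_LABELS = ("pre", "reversal", "post")


class TaskConfigError(ValueError):
    """Raised when a task configuration is internally inconsistent."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the reversal-learning schedule.

    Defaults reproduce the standard 160-trial session: 55 stable trials,
    a 70-trial reversal phase in which the better option switches four
    times (at the phase onset and then after 15, 20 and 15 trials), and
    35 stable post-reversal trials.

    Attributes
    ----------
    n_trials
        Session length in trials.
    phase_lengths
        (pre, reversal, post) trial counts; must sum to ``n_trials``.
    reward_prob_correct
        Probability of reward when the better option is chosen; the
        other option rewards with the complementary probability.
    segment_lengths_reversal
        Lengths of the contingency segments inside the reversal phase.
        The contingency switches at the first trial of each segment;
        the last segment's contingency persists into the post phase.
    initial_correct_option
        Option index (0 or 1) that is better at session start.
    """

    n_trials: int = 160
    phase_lengths: tuple[int, int, int] = (55, 70, 35)
    reward_prob_correct: float = 0.80
    segment_lengths_reversal: tuple[int, ...] = (15, 20, 15, 20)
    initial_correct_option: int = 0

    def __post_init__(self) -> None:
        if sum(self.phase_lengths) != self.n_trials:
            raise TaskConfigError(
                f"phase_lengths {self.phase_lengths} sum to "
                f"{sum(self.phase_lengths)}, expected n_trials={self.n_trials}"
            )
        if sum(self.segment_lengths_reversal) != self.phase_lengths[1]:
            raise TaskConfigError(
                f"segment_lengths_reversal {self.segment_lengths_reversal} sum to "
                f"{sum(self.segment_lengths_reversal)}, expected reversal-phase "
                f"length {self.phase_lengths[1]}"
            )
        if not 0.0 < self.reward_prob_correct < 1.0:
            raise TaskConfigError(
                f"reward_prob_correct must lie in (0, 1), got "
                f"{self.reward_prob_correct}"
            )
        if self.initial_correct_option not in (0, 1):
            raise TaskConfigError(
                f"initial_correct_option must be 0 or 1, got "
                f"{self.initial_correct_option}"
            )


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial identity of the better option plus phase labels.

    ``reversal_trials`` lists the 1-based trial indices at which the
    better option changes; ``correct_option`` changes exactly there.
    """

    correct_option: np.ndarray
    phase: np.ndarray
    reversal_trials: tuple[int, ...]
    reward_prob_correct: float = 0.80
    config: TaskConfig | None = field(default=None, compare=False)

    @property
    def n_trials(self) -> int:
        return len(self.correct_option)

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a tidy table with 1-based ``trial`` column."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "phase": self.phase,
                "correct_option": self.correct_option,
            }
        )


def make_schedule(config: TaskConfig | None = None) -> TaskSchedule:
    """Build the deterministic reversal schedule for a configuration.

    The first contingency switch falls on the first trial of the
    reversal phase; each later segment boundary switches again. With the
    default configuration the switches land on trials 56, 71, 91 and 106
    (1-based) and the final segment's contingency persists through the
    post-reversal phase.
    """
    if config is None:
        config = TaskConfig()
    n = config.n_trials
    pre_len, rev_len, post_len = config.phase_lengths

    phase = np.repeat(PHASE_LABELS, [pre_len, rev_len, post_len])
    correct = np.empty(n, dtype=np.int64)
    correct[:pre_len] = config.initial_correct_option

    reversal_trials: list[int] = []
    current = config.initial_correct_option
    pos = pre_len  # 0-based index of the next segment start
    for seg_len in config.segment_lengths_reversal:
        current = 1 - current
        reversal_trials.append(pos + 1)  # 1-based
        correct[pos : pos + seg_len] = current
        pos += seg_len
    correct[pos:] = current  # post phase keeps last contingency

    return TaskSchedule(
        correct_option=correct,
        phase=phase,
        reversal_trials=tuple(reversal_trials),
        reward_prob_correct=config.reward_prob_correct,
        config=config,
    )


def sample_outcome(
    chosen: int, correct: int, p: float, rng: np.random.Generator
) -> int:
    """Draw a single outcome, +1 (win) or -1 (loss).

    Reward arrives with probability ``p`` when the chosen option is the
    currently better one, and with probability ``1 - p`` otherwise —
    the two options' outcome probabilities are perfectly anticorrelated.
    Consumes exactly one uniform draw.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"reward probability must lie in (0, 1), got {p}")
    p_reward = p if chosen == correct else 1.0 - p
    return 1 if rng.random() < p_reward else -1


def schedule_to_csv(schedule: TaskSchedule, path) -> None:
    """Write the schedule as CSV (columns: trial, phase, correct_option)."""
    schedule.to_frame().to_csv(path, index=False)
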