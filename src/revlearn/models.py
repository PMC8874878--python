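"""Reinforcement-learning models of reversal-task choice behavior.

Six delta-rule models form the model space, crossing the *updating*
factor (SU: only the chosen option's value is updated; DU: the unchosen
option is counter-updated with full weight; iDU: the counter-update is
scaled by an individual weight kappa in [0, 1]) with the *learning rate*
factor (one shared rate, or separate rates for rewards and punishments).
Choices follow a softmax on the two option values with inverse decision
noise beta. Outcomes are coded +1 (win) / -1 (loss), under which the
counter-update ``delta_uc = -R - Q_uc`` drives the two values toward
anticorrelation, matching the task's structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .task import TaskSchedule, sample_outcome

UPDATING_KINDS = ("SU", "DU", "iDU")


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the 3 x 2 model space."""

    updating: str
    n_learning_rates: int = 1

    def __post_init__(self) -> None:
        if self.updating not in UPDATING_KINDS:
            raise ValueError(f"unknown updating kind {self.updating!r}")
        if self.n_learning_rates not in (1, 2):
            raise ValueError("n_learning_rates must be 1 or 2")

    @property
    def name(self) -> str:
        return f"{self.updating}-{self.n_learning_rates}a"

    @property
    def free_params(self) -> tuple[str, ...]:
        """Names of the parameters this model actually fits."""
        rates = ("alpha",) if self.n_learning_rates == 1 else ("alpha_rew", "alpha_pun")
        kappa = ("kappa",) if self.updating == "iDU" else ()
        return rates + kappa + ("beta",)

    @property
    def fixed_kappa(self) -> float | None:
        """kappa implied by the updating kind (None when kappa is free)."""
        return {"SU": 0.0, "DU": 1.0, "iDU": None}[self.updating]


#: The six models, in canonical order.
MODEL_SPACE: tuple[ModelSpec, ...] = tuple(
    ModelSpec(updating=u, n_learning_rates=k)
    for k in (1, 2)
    for u in UPDATING_KINDS
)


def spec_from_name(name: str) -> ModelSpec:
    for spec in MODEL_SPACE:
        if spec.name == name:
            return spec
    raise ValueError(
        f"unknown model {name!r}; valid: {[s.name for s in MODEL_SPACE]}"
    )


@dataclass(frozen=True)
class ParamSet:
    """Native-space parameters of one model.

    ``alpha`` is used by one-rate models; ``alpha_rew``/``alpha_pun`` by
    two-rate models. ``kappa`` weights the unchosen-option update and is
    implicitly 0 for SU and 1 for DU. ``alpha_uc = kappa * alpha`` is the
    effective unchosen-option learning rate (derived, never stored).
    """

    alpha: float = 0.5
    alpha_rew: float = 0.5
    alpha_pun: float = 0.5
    kappa: float = 0.0
    beta: float = 1.0

    def effective_kappa(self, spec: ModelSpec) -> float:
        fixed = spec.fixed_kappa
        return self.kappa if fixed is None else fixed

    def learning_rate(self, outcome: int, spec: ModelSpec) -> float:
        """Rate applied on a trial with the given outcome (+1/-1)."""
        if spec.n_learning_rates == 1:
            return self.alpha
        return self.alpha_rew if outcome > 0 else self.alpha_pun

    def alpha_uc(self, spec: ModelSpec) -> float:
        """Effective unchosen-option rate kappa * alpha (one-rate models)."""
        base = self.alpha if spec.n_learning_rates == 1 else np.nan
        return self.effective_kappa(spec) * base

    def with_values(self, **kwargs) -> "ParamSet":
        return replace(self, **kwargs)


@dataclass
class ValueState:
    """Option values and trial counter of a delta-rule learner."""

    q: np.ndarray
    trial: int = 0

    @classmethod
    def initial(cls, q0: tuple[float, float] = (0.0, 0.0)) -> "ValueState":
        return cls(q=np.asarray(q0, dtype=float), trial=0)


@dataclass
class SessionData:
    """Observed (or simulated) behavior of one subject-session.

    ``choice`` and ``outcome`` are aligned to the schedule; trials with
    no response carry ``valid=False`` and sentinel values, contribute no
    likelihood, and trigger no value update.
    """

    schedule: TaskSchedule
    choice: np.ndarray  # option index, -1 where invalid
    outcome: np.ndarray  # +1/-1, 0 where invalid
    valid: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = self.schedule.n_trials
        if not (len(self.choice) == len(self.outcome) == len(self.valid) == n):
            raise ValueError("choice/outcome/valid lengths must match schedule")
        v = self.valid
        if np.any((self.choice[v] < 0) | (self.choice[v] > 1)):
            raise ValueError("valid trials must have choice in {0, 1}")
        if np.any(np.abs(self.outcome[v]) != 1):
            raise ValueError("valid trials must have outcome in {+1, -1}")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def update_values(
    state: ValueState,
    chosen: int,
    outcome: int,
    params: ParamSet,
    spec: ModelSpec,
) -> ValueState:
    """One delta-rule step: returns the post-trial value state.

    The chosen value moves toward the outcome by the applicable learning
    rate; the unchosen value moves toward the mirrored outcome by kappa
    times the same rate (kappa = 0 for SU, 1 for DU).
    """
    if outcome not in (1, -1):
        raise ValueError(f"outcome must be +1 or -1, got {outcome}")
    q = state.q.copy()
    lr = params.learning_rate(outcome, spec)
    kappa = params.effective_kappa(spec)
    un = 1 - chosen
    q[chosen] += lr * (outcome - q[chosen])
    if kappa != 0.0:
        q[un] += kappa * lr * (-outcome - q[un])
    return ValueState(q=q, trial=state.trial + 1)


def choice_probability(state: ValueState, beta: float) -> np.ndarray:
    """Softmax choice probabilities over the two options.

    Normalized, translation-invariant in the values, and uniform at
    beta = 0.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    d = beta * (state.q[0] - state.q[1])
    if d >= 0:
        p0 = 1.0 / (1.0 + math.exp(-d)) if d < 700 else 1.0
    else:
        e = math.exp(d)
        p0 = e / (1.0 + e)
    return np.array([p0, 1.0 - p0])


def _rates_for(params: ParamSet, spec: ModelSpec) -> tuple[float, float, float]:
    """(rate after win, rate after loss, effective kappa)."""
    if spec.n_learning_rates == 1:
        lr_win = lr_loss = params.alpha
    else:
        lr_win, lr_loss = params.alpha_rew, params.alpha_pun
    return lr_win, lr_loss, params.effective_kappa(spec)


def session_nll(
    data: SessionData,
    params: ParamSet,
    spec: ModelSpec,
    q0: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Negative log-likelihood of the observed choices under one model.

    Values update only on valid trials; invalid trials contribute zero
    log-likelihood. A session with no valid trial returns 0.0 with a
    warning.
    """
    if data.n_valid == 0:
        warnings.warn("session has zero valid trials; NLL defined as 0.0")
        return 0.0
    lr_win, lr_loss, kappa = _rates_for(params, spec)
    beta = params.beta
    q0_, q1_ = float(q0[0]), float(q0[1])
    choice = data.choice
    outcome = data.outcome
    valid = data.valid
    nll = 0.0
    for k in range(len(choice)):
        if not valid[k]:
            continue
        c = choice[k]
        # stable -log softmax: log(1 + exp(-beta * (q_c - q_uc)))
        d = beta * (q0_ - q1_) if c == 0 else beta * (q1_ - q0_)
        nll += math.log1p(math.exp(-d)) if d > -30 else -d
        r = outcome[k]
        lr = lr_win if r > 0 else lr_loss
        if c == 0:
            q0_ += lr * (r - q0_)
            if kappa != 0.0:
                q1_ += kappa * lr * (-r - q1_)
        else:
            q1_ += lr * (r - q1_)
            if kappa != 0.0:
                q0_ += kappa * lr * (-r - q0_)
    return nll


def simulate_agent(
    params: ParamSet,
    spec: ModelSpec,
    schedule: TaskSchedule,
    rng: np.random.Generator,
    q0: tuple[float, float] = (0.0, 0.0),
) -> SessionData:
    """Simulate one session of a softmax delta-rule agent on a schedule.

    Each trial the choice is drawn from the softmax, the outcome from the
    task's anticorrelated reward probabilities, and the values updated.
    Ties between equal values are resolved by the softmax draw itself
    (p = 0.5). Reproducible under a fixed generator state.
    """
    n = schedule.n_trials
    lr_win, lr_loss, kappa = _rates_for(params, spec)
    beta = params.beta
    p = schedule.reward_prob_correct
    correct = schedule.correct_option
    q0_, q1_ = float(q0[0]), float(q0[1])
    choices = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    for k in range(n):
        d = beta * (q0_ - q1_)
        if d >= 0:
            p_choose_0 = 1.0 / (1.0 + math.exp(-d)) if d < 700 else 1.0
        else:
            e = math.exp(d)
            p_choose_0 = e / (1.0 + e)
        c = 0 if rng.random() < p_choose_0 else 1
        r = sample_outcome(c, int(correct[k]), p, rng)
        choices[k] = c
        outcomes[k] = r
        lr = lr_win if r > 0 else lr_loss
        if c == 0:
            q0_ += lr * (r - q0_)
            if kappa != 0.0:
                q1_ += kappa * lr * (-r - q1_)
        else:
            q1_ += lr * (r - q1_)
            if kappa != 0.0:
                q0_ += kappa * lr * (-r - q0_)
    return SessionData(
        schedule=schedule,
        choice=choices,
        outcome=outcomes,
        valid=np.ones(n, dtype=bool),
    )
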