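"""Synthetic study cohorts for the reversal-learning pipeline.

Emulates the structure of a two-group, two-session, sham-controlled
stimulation study: one group receives anodal stimulation in its verum
session, the other cathodal, with session order counterbalanced across
subjects. Subject-level model parameters are drawn from truncated
Gaussians in native space around group-by-condition means; the default
means and SDs are those reported for the winning individually-weighted
double-update model (sham: alpha 0.44 +/- 0.16, kappa 0.33 +/- 0.12,
beta 5.98 +/- 3.00; anodal: alpha 0.47 +/- 0.19, kappa 0.41 +/- 0.15,
beta 5.58 +/- 2.33; cathodal condition generated like sham). Parameters
correlate across a subject's two sessions (Gaussian latent correlation,
default 0.7) to mimic test-retest stability. Ground-truth parameters
are retained for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import ModelSpec, ParamSet, SessionData, simulate_agent, spec_from_name
from .task import TaskConfig, make_schedule

GROUPS = ("a-tDCS", "c-tDCS")
CONDITIONS = ("sham", "verum")

_BOUNDS = {
    "alpha": (0.0, 1.0),
    "alpha_rew": (0.0, 1.0),
    "alpha_pun": (0.0, 1.0),
    "kappa": (0.0, 1.0),
    "beta": (0.0, np.inf),
}

_SHAM = {"alpha": (0.44, 0.16), "kappa": (0.33, 0.12), "beta": (5.98, 3.00)}
_ANODAL = {"alpha": (0.47, 0.19), "kappa": (0.41, 0.15), "beta": (5.58, 2.33)}


def _default_population() -> dict:
    return {
        ("a-tDCS", "sham"): dict(_SHAM),
        ("a-tDCS", "verum"): dict(_ANODAL),
        ("c-tDCS", "sham"): dict(_SHAM),
        ("c-tDCS", "verum"): dict(_SHAM),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic two-session cohort.

    ``population`` maps (group, condition) to {parameter: (mean, SD)}
    in native space. ``within_subject_corr`` is the latent Gaussian
    correlation of each parameter across a subject's two sessions.
    """

    n_per_group: tuple[int, int] = (30, 31)
    model: str = "iDU-1a"
    population: dict = field(default_factory=_default_population)
    within_subject_corr: float = 0.7
    missed_rate: float = 0.0
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.within_subject_corr <= 1.0:
            raise ValueError("within_subject_corr must lie in [-1, 1]")
        if not 0.0 <= self.missed_rate < 1.0:
            raise ValueError("missed_rate must lie in [0, 1)")
        spec = spec_from_name(self.model)
        for key, params in self.population.items():
            for name in spec.free_params:
                if name not in params:
                    raise ValueError(f"population {key} missing parameter {name!r}")
                mean, sd = params[name]
                lo, hi = _BOUNDS[name]
                if sd < 0:
                    raise ValueError(f"SD for {name} in {key} must be >= 0")
                if not lo < mean < hi:
                    raise ValueError(
                        f"mean {mean} for {name} in {key} outside bounds ({lo}, {hi})"
                    )

    @property
    def model_spec(self) -> ModelSpec:
        return spec_from_name(self.model)


def effect_injection(spec: CohortSpec, delta_kappa: float) -> CohortSpec:
    """Cohort spec with a controlled kappa shift as the only verum effect.

    Both groups' verum conditions are reset to their sham parameters;
    the anodal group's verum kappa mean is then shifted by
    ``delta_kappa``. ``delta_kappa = 0`` yields a condition-identical
    (null) generative process; 0.08 reproduces the reported sham 0.33 ->
    anodal 0.41 shift.
    """
    pop = {k: {p: tuple(v) for p, v in d.items()} for k, d in spec.population.items()}
    for g in GROUPS:
        pop[(g, "verum")] = dict(pop[(g, "sham")])
    mean, sd = pop[("a-tDCS", "verum")]["kappa"]
    new_mean = mean + delta_kappa
    lo, hi = _BOUNDS["kappa"]
    if not lo < new_mean < hi:
        raise ValueError(f"shifted kappa mean {new_mean} outside ({lo}, {hi})")
    pop[("a-tDCS", "verum")]["kappa"] = (new_mean, sd)
    return replace(spec, population=pop)


@dataclass
class SubjectRecord:
    """One synthetic subject: ground truth plus simulated sessions."""

    subject_id: str
    group: str
    condition_order: tuple[str, str]
    params: dict  # condition -> ParamSet (ground truth)
    sessions: dict  # condition -> SessionData


@dataclass
class CohortData:
    """A generated cohort with ground truth for recovery scoring."""

    spec: CohortSpec
    subjects: list

    def sessions_frame(self) -> pd.DataFrame:
        """Long-format session table (one row per subject x condition x trial)."""
        rows = []
        for subj in self.subjects:
            for cond in CONDITIONS:
                data = subj.sessions[cond]
                order = subj.condition_order.index(cond) + 1
                n = data.schedule.n_trials
                rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": subj.subject_id,
                            "group": subj.group,
                            "condition": cond,
                            "session_order": order,
                            "trial": np.arange(1, n + 1),
                            "choice": np.where(data.valid, data.choice, np.nan),
                            "outcome": np.where(data.valid, data.outcome, np.nan),
                            "correct_option": data.schedule.correct_option,
                            "phase": data.schedule.phase,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def ground_truth_frame(self) -> pd.DataFrame:
        """Tidy ground-truth parameters (one row per subject x condition)."""
        spec = self.spec.model_spec
        rows = []
        for subj in self.subjects:
            for cond in CONDITIONS:
                p = subj.params[cond]
                row = {
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "condition": cond,
                }
                row.update({name: getattr(p, name) for name in spec.free_params})
                rows.append(row)
        return pd.DataFrame(rows)


def _draw_correlated_pair(
    rng: np.random.Generator,
    mean_sd_a: tuple[float, float],
    mean_sd_b: tuple[float, float],
    corr: float,
    bounds: tuple[float, float],
    max_tries: int = 1000,
) -> tuple[float, float]:
    """Correlated truncated-Gaussian pair via latent-Gaussian rejection."""
    (ma, sa), (mb, sb) = mean_sd_a, mean_sd_b
    lo, hi = bounds
    for _ in range(max_tries):
        z1 = rng.standard_normal()
        z2 = corr * z1 + np.sqrt(max(1.0 - corr**2, 0.0)) * rng.standard_normal()
        va, vb = ma + sa * z1, mb + sb * z2
        if lo < va < hi and lo < vb < hi:
            return va, vb
    raise ValueError(
        f"infeasible truncation: means {ma}/{mb}, SDs {sa}/{sb} "
        f"rarely fall inside ({lo}, {hi})"
    )


def generate_cohort(spec: CohortSpec | None = None) -> CohortData:
    """Generate a full synthetic cohort from a cohort specification.

    Session order alternates with subject index within each group
    (counterbalancing); each session is simulated on a fresh default
    schedule with independently drawn outcomes. Fully reproducible from
    the master seed.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    model_spec = spec.model_spec
    schedule = make_schedule(spec.task)
    subjects: list[SubjectRecord] = []
    for g_idx, (group, n_group) in enumerate(zip(GROUPS, spec.n_per_group)):
        prefix = "a" if group == "a-tDCS" else "c"
        for i in range(n_group):
            order = ("sham", "verum") if i % 2 == 0 else ("verum", "sham")
            values: dict[str, dict[str, float]] = {c: {} for c in CONDITIONS}
            for name in model_spec.free_params:
                v_sham, v_verum = _draw_correlated_pair(
                    rng,
                    spec.population[(group, "sham")][name],
                    spec.population[(group, "verum")][name],
                    spec.within_subject_corr,
                    _BOUNDS[name],
                )
                values["sham"][name] = v_sham
                values["verum"][name] = v_verum
            params = {c: ParamSet(**values[c]) for c in CONDITIONS}
            sessions = {}
            for cond in order:  # simulate in administration order
                data = simulate_agent(params[cond], model_spec, schedule, rng)
                if spec.missed_rate > 0.0:
                    missed = rng.random(schedule.n_trials) < spec.missed_rate
                    data = SessionData(
                        schedule=schedule,
                        choice=np.where(missed, -1, data.choice),
                        outcome=np.where(missed, 0, data.outcome),
                        valid=data.valid & ~missed,
                    )
                sessions[cond] = data
            subjects.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    condition_order=order,
                    params=params,
                    sessions=sessions,
                )
            )
    return CohortData(spec=spec, subjects=subjects)
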