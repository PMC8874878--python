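"""Session-table I/O, run configuration, and the end-to-end pipeline.

The session CSV is long-format, one row per trial: ``subject_id, group,
condition, session_order, trial, choice, outcome, correct_option,
phase`` with the literal ``NA`` for missed responses (choice and
outcome must be missing together). The pipeline chains MAP fitting over
the model space, chance-level exclusion, random-effects model selection
(between groups, across conditions, pooled), parameter comparisons
focused on the unchosen-option learning rate, behavioral descriptives,
and posterior-predictive simulation.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .behavior import correct_choice_rate, paired_effect_sizes, stay_probabilities
from .bms import BMSResult, EvidenceMatrix, frequency_equality_test, pooled_selection, rfx_bms
from .cohort import CONDITIONS, GROUPS, CohortData
from .fitting import FitResult, PriorSpec, apply_chance_test, fit_map
from .models import MODEL_SPACE, SessionData, simulate_agent, spec_from_name
from .task import PHASE_LABELS, TaskSchedule

logger = logging.getLogger("revlearn")

SESSION_COLUMNS = (
    "subject_id",
    "group",
    "condition",
    "session_order",
    "trial",
    "choice",
    "outcome",
    "correct_option",
    "phase",
)


class SessionTableError(ValueError):
    """Schema or consistency violation in a session CSV."""


@dataclass
class SessionRecord:
    """One subject-session with its metadata."""

    subject_id: str
    group: str
    condition: str
    session_order: int
    data: SessionData


@dataclass
class RunConfig:
    """All pipeline settings; serialized into every results bundle."""

    models: tuple[str, ...] = tuple(s.name for s in MODEL_SPACE)
    n_restarts: int = 10
    fit_tol: float = 1e-6
    fit_seed: int = 0
    bms_alpha0: float = 1.0
    xp_draws: int = 1_000_000
    bms_seed: int = 0
    n_ppc_sims: int = 10_000
    ppc_seed: int = 0
    exclusion_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in self.models:
            spec_from_name(name)  # raises on unknown model

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d


def write_sessions(records_or_cohort, path) -> None:
    """Write sessions (a cohort or a list of SessionRecord) as CSV."""
    if isinstance(records_or_cohort, CohortData):
        df = records_or_cohort.sessions_frame()
    else:
        rows = []
        for rec in records_or_cohort:
            data = rec.data
            n = data.schedule.n_trials
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "group": rec.group,
                        "condition": rec.condition,
                        "session_order": rec.session_order,
                        "trial": np.arange(1, n + 1),
                        "choice": np.where(data.valid, data.choice, np.nan),
                        "outcome": np.where(data.valid, data.outcome, np.nan),
                        "correct_option": data.schedule.correct_option,
                        "phase": data.schedule.phase,
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
    out = df.copy()
    for col in ("choice", "outcome"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def _schedule_from_rows(sub: pd.DataFrame, key: tuple) -> TaskSchedule:
    correct = sub["correct_option"].to_numpy(dtype=np.int64)
    phase = sub["phase"].to_numpy(dtype=object)
    # phases must be contiguous blocks in canonical order
    seen = [p for i, p in enumerate(phase) if i == 0 or phase[i - 1] != p]
    if [p for p in PHASE_LABELS if p in seen] != seen or len(seen) != len(set(seen)):
        raise SessionTableError(f"session {key}: phase labels are not contiguous blocks")
    reversal_trials = tuple(
        int(i + 1) for i in range(1, len(correct)) if correct[i] != correct[i - 1]
    )
    return TaskSchedule(
        correct_option=correct,
        phase=np.asarray(phase, dtype=object),
        reversal_trials=reversal_trials,
    )


def read_sessions(path) -> list[SessionRecord]:
    """Read and validate a session CSV.

    Raises :class:`SessionTableError` with 1-based file line numbers on
    schema violations, NA mismatches between choice and outcome,
    non-contiguous trial indices, or duplicated trials.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False, dtype={"phase": str})
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SessionTableError(f"missing columns: {missing}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1

    bad = df["choice"].isna() != df["outcome"].isna()
    if bad.any():
        line = int(df.loc[bad, "_line"].iloc[0])
        raise SessionTableError(
            f"line {line}: choice and outcome must be NA together"
        )

    records = []
    for key, sub in df.groupby(["subject_id", "condition"], sort=False):
        dup = sub["trial"].duplicated()
        if dup.any():
            line = int(sub.loc[dup, "_line"].iloc[0])
            raise SessionTableError(f"line {line}: duplicate trial for session {key}")
        sub = sub.sort_values("trial")
        trials = sub["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(trials) + 1)):
            line = int(sub["_line"].iloc[0])
            raise SessionTableError(
                f"line {line}: session {key} trials are not contiguous from 1"
            )
        schedule = _schedule_from_rows(sub, key)
        valid = ~sub["choice"].isna().to_numpy()
        choice = np.where(valid, sub["choice"].fillna(-1).to_numpy(dtype=float), -1).astype(np.int64)
        outcome = np.where(valid, sub["outcome"].fillna(0).to_numpy(dtype=float), 0).astype(np.int64)
        try:
            data = SessionData(schedule=schedule, choice=choice, outcome=outcome, valid=valid)
        except ValueError as exc:
            line = int(sub["_line"].iloc[0])
            raise SessionTableError(f"line {line}: session {key}: {exc}") from exc
        records.append(
            SessionRecord(
                subject_id=str(key[0]),
                group=str(sub["group"].iloc[0]),
                condition=str(key[1]),
                session_order=int(sub["session_order"].iloc[0]),
                data=data,
            )
        )
    return records


# ---------------------------------------------------------------------------
# pipeline stages


def fit_all(
    records: list[SessionRecord],
    config: RunConfig,
    priors: PriorSpec | None = None,
) -> pd.DataFrame:
    """MAP-fit every model to every session.

    Returns a tidy frame: one row per subject x condition x model with
    the MAP estimates, NLL, log evidence and chance-fit test.
    """
    priors = priors or PriorSpec()
    rows = []
    for rec in records:
        for name in config.models:
            spec = spec_from_name(name)
            # per-session seeding keeps the pipeline order-invariant
            key = zlib.crc32(f"{rec.subject_id}|{rec.condition}|{name}".encode())
            fit = fit_map(
                rec.data,
                spec,
                priors,
                n_restarts=config.n_restarts,
                rng=np.random.default_rng([config.fit_seed, key]),
                tol=config.fit_tol,
            )
            apply_chance_test(fit, config.exclusion_alpha)
            row = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "condition": rec.condition,
                "model": name,
                "nll": fit.nll,
                "log_joint": fit.log_joint,
                "lme": fit.lme,
                "hessian_ok": fit.hessian_ok,
                "chance_p": fit.chance_p,
                "beats_chance": not fit.excluded_chance,
                "n_valid_trials": fit.n_valid_trials,
            }
            p = fit.map_params
            for pname in spec.free_params:
                row[pname] = getattr(p, pname)
            if "kappa" in spec.free_params and spec.n_learning_rates == 1:
                row["alpha_uc"] = p.kappa * p.alpha
            rows.append(row)
    return pd.DataFrame(rows)


def chance_excluded_subjects(fits: pd.DataFrame) -> list[str]:
    """Subjects with a session that no model fits better than chance."""
    excluded = []
    for subject, sub in fits.groupby("subject_id", sort=False):
        for _, sess in sub.groupby("condition", sort=False):
            if not sess["beats_chance"].any():
                excluded.append(str(subject))
                break
    return excluded


def evidence_matrix(fits: pd.DataFrame, condition: str | None = None) -> EvidenceMatrix:
    """Pivot fitted log evidences into a subjects x models matrix."""
    sub = fits if condition is None else fits[fits["condition"] == condition]
    models = list(dict.fromkeys(sub["model"]))
    pivot = sub.pivot_table(index="subject_id", columns="model", values="lme", aggfunc="sum")
    pivot = pivot[models].sort_index()
    return EvidenceMatrix(
        lme=pivot.to_numpy(),
        models=tuple(models),
        subjects=tuple(map(str, pivot.index)),
    )


def posterior_predictive(
    records: list[SessionRecord],
    fits: pd.DataFrame,
    model: str,
    n_sims: int,
    rng: int = 0,
) -> pd.DataFrame:
    """Simulate each session from its fitted parameters and summarize.

    For every subject-session, draws ``n_sims`` synthetic sessions from
    the fitted parameters of ``model`` on the session's own schedule and
    reports the mean simulated correct-choice rate, win-stay and
    lose-stay (the mean over simulations is the per-session summary).
    """
    base_seed = rng if isinstance(rng, int) else 0
    spec = spec_from_name(model)
    indexed = fits.set_index(["subject_id", "condition", "model"])
    rows = []
    for rec in records:
        fit_row = indexed.loc[(rec.subject_id, rec.condition, model)]
        params = _params_from_row(fit_row, spec)
        key = zlib.crc32(f"{rec.subject_id}|{rec.condition}".encode())
        rng = np.random.default_rng([base_seed, key])
        ws, ls, cc = [], [], []
        for _ in range(n_sims):
            sim = simulate_agent(params, spec, rec.data.schedule, rng)
            stay = stay_probabilities(sim)
            ws.append(stay.win_stay)
            ls.append(stay.lose_stay)
            cc.append(correct_choice_rate(sim).overall)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "condition": rec.condition,
                "sim_win_stay": float(np.nanmean(ws)),
                "sim_lose_stay": float(np.nanmean(ls)),
                "sim_correct": float(np.mean(cc)),
                "n_sims": n_sims,
            }
        )
    return pd.DataFrame(rows)


def _params_from_row(row, spec):
    from .models import ParamSet

    return ParamSet(**{p: float(row[p]) for p in spec.free_params})


def behavioral_table(records: list[SessionRecord]) -> pd.DataFrame:
    """Tidy behavioral descriptives: one row per subject x condition x phase."""
    rows = []
    for rec in records:
        perf = correct_choice_rate(rec.data)
        stay = stay_probabilities(rec.data, by_phase=True)
        for ph in PHASE_LABELS:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "condition": rec.condition,
                    "phase": ph,
                    "correct_rate": getattr(perf, ph if ph != "reversal" else "reversal"),
                    "win_stay": stay.by_phase[ph].win_stay,
                    "lose_stay": stay.by_phase[ph].lose_stay,
                }
            )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "condition": rec.condition,
                "phase": "overall",
                "correct_rate": perf.overall,
                "win_stay": stay.win_stay,
                "lose_stay": stay.lose_stay,
            }
        )
    return pd.DataFrame(rows)


def _paired_condition_test(values: pd.DataFrame, column: str, group: str) -> dict:
    """Paired sham-vs-verum comparison of one measure within one group."""
    sub = values[(values["group"] == group)]
    wide = sub.pivot_table(index="subject_id", columns="condition", values=column)
    wide = wide.dropna()
    if len(wide) < 2 or {"sham", "verum"} - set(wide.columns):
        return {"group": group, "measure": column, "n": int(len(wide))}
    sham, verum = wide["sham"].to_numpy(), wide["verum"].to_numpy()
    t = stats.ttest_rel(verum, sham)
    diff = verum - sham
    out = {
        "group": group,
        "measure": column,
        "n": int(len(wide)),
        "mean_sham": float(np.mean(sham)),
        "mean_verum": float(np.mean(verum)),
        "t": float(t.statistic),
        "p_t": float(t.pvalue),
    }
    if np.any(diff != 0):
        w = stats.wilcoxon(verum, sham)
        d, rb = paired_effect_sizes(sham, verum)
        out.update(
            {"wilcoxon_w": float(w.statistic), "p_wilcoxon": float(w.pvalue),
             "cohen_d": d, "rank_biserial": rb}
        )
    return out


def run_pipeline(
    records: list[SessionRecord],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    priors: PriorSpec | None = None,
) -> dict:
    """Run the full analysis on a set of sessions.

    Stages: MAP fitting of the model space -> chance-level exclusion ->
    evidence matrices -> model selection (between-groups equality,
    across-condition stability, pooled winner) -> parameter comparisons
    focused on the unchosen-option learning rate -> behavioral
    descriptives -> posterior-predictive simulation with the winning
    model. Returns a results bundle (dict of frames and summaries) and,
    if ``out_dir`` is given, writes it as CSV/JSON plus a run log.
    """
    config = config or RunConfig()
    t0 = time.time()
    bundle: dict = {"config": config.to_dict(), "version": __version__}
    stage = "fit"
    try:
        fits = fit_all(records, config, priors)
        bundle["fits"] = fits

        stage = "exclusion"
        excluded = chance_excluded_subjects(fits)
        bundle["excluded_subjects"] = excluded
        kept_fits = fits[~fits["subject_id"].isin(excluded)]
        kept_records = [r for r in records if r.subject_id not in excluded]

        stage = "model_selection"
        conditions = sorted(kept_fits["condition"].unique())
        bms_kwargs = dict(
            alpha0=config.bms_alpha0, xp_draws=config.xp_draws, rng=config.bms_seed
        )
        selection: dict = {}
        if len(conditions) == 2:
            ev1 = evidence_matrix(kept_fits, conditions[0])
            ev2 = evidence_matrix(kept_fits, conditions[1])
            selection["condition_stability_p_equal"] = frequency_equality_test(
                ev1, ev2, alpha0=config.bms_alpha0, rng=config.bms_seed
            )
            pooled = pooled_selection(ev1, ev2, **bms_kwargs)
        else:
            pooled = rfx_bms(evidence_matrix(kept_fits), **bms_kwargs)
        groups = sorted(kept_fits["group"].unique())
        if len(groups) == 2:
            ev_a = evidence_matrix(kept_fits[kept_fits["group"] == groups[0]])
            ev_b = evidence_matrix(kept_fits[kept_fits["group"] == groups[1]])
            selection["group_equality_p_equal"] = frequency_equality_test(
                ev_a, ev_b, alpha0=config.bms_alpha0, rng=config.bms_seed
            )
        selection["pooled"] = pooled.to_dict()
        selection["winner"] = pooled.winner
        bundle["selection"] = selection

        stage = "parameters"
        winner = pooled.winner
        wfits = kept_fits[kept_fits["model"] == winner]
        param_tests = []
        wspec = spec_from_name(winner)
        measures = list(wspec.free_params)
        if "alpha_uc" in wfits.columns and wfits["alpha_uc"].notna().any():
            measures.append("alpha_uc")
        for group in sorted(wfits["group"].unique()):
            for measure in measures:
                param_tests.append(_paired_condition_test(wfits, measure, group))
        bundle["parameter_tests"] = param_tests

        stage = "behavior"
        behav = behavioral_table(kept_records)
        bundle["behavior"] = behav
        overall = behav[behav["phase"] == "overall"]
        behavior_tests = [
            _paired_condition_test(overall, m, g)
            for g in sorted(overall["group"].unique())
            for m in ("lose_stay", "win_stay", "correct_rate")
        ]
        bundle["behavior_tests"] = behavior_tests

        stage = "posterior_predictive"
        ppc = posterior_predictive(
            kept_records, kept_fits, winner, config.n_ppc_sims, rng=config.ppc_seed
        )
        bundle["posterior_predictive"] = ppc
        bundle["ppc_tests"] = [
            _paired_condition_test(ppc, "sim_lose_stay", g)
            for g in sorted(ppc["group"].unique())
        ]
    except Exception as exc:
        bundle["failed_stage"] = stage
        if out_dir is not None:
            _write_bundle(bundle, out_dir, elapsed=time.time() - t0, failed=str(exc))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle["elapsed_s"] = time.time() - t0
    if out_dir is not None:
        _write_bundle(bundle, out_dir, elapsed=bundle["elapsed_s"])
    return bundle


def _write_bundle(bundle: dict, out_dir, elapsed: float, failed: str | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for key, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out / f"{key}.csv", index=False)
        else:
            summary[key] = value
    if failed is not None:
        summary["error"] = failed
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(out / "run.log", "w") as fh:
        fh.write(
            f"revlearn {__version__}\nelapsed_s: {elapsed:.1f}\n"
            f"config: {json.dumps(bundle.get('config', {}))}\n"
            + (f"FAILED: {failed}\n" if failed else "completed\n")
        )
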