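"""Behavioral descriptives and count-based tests.

Win-stay / lose-stay: the probability of repeating the previous choice
after a win or a loss, counted over consecutive pairs of valid trials;
a pair is attributed to the phase of its leading trial. Correct-choice
rates are per-phase proportions of choosing the currently better
option. Exact two-sided binomial tests (point-probability convention)
serve blinding checks; Pearson chi-square without continuity correction
serves 2x2 count comparisons; paired effect sizes cover Cohen's d on
differences and the matched rank-biserial correlation from the
signed-rank construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import SessionData
from .task import PHASE_LABELS


@dataclass(frozen=True)
class StayStats:
    """Feedback-conditioned stay behavior of one session."""

    win_stay: float
    lose_stay: float
    n_win_pairs: int
    n_lose_pairs: int
    by_phase: dict | None = None

    @property
    def defined(self) -> bool:
        return self.n_win_pairs > 0 and self.n_lose_pairs > 0


@dataclass(frozen=True)
class PhasePerformance:
    """Correct-choice proportions per phase and overall."""

    pre: float
    reversal: float
    post: float
    overall: float
    n_valid: dict | None = None


def _stay_counts(
    choice: np.ndarray, outcome: np.ndarray, valid: np.ndarray
) -> tuple[int, int, int, int]:
    """(win stays, win pairs, lose stays, lose pairs) over valid pairs."""
    lead = valid[:-1] & valid[1:]
    stay = (choice[:-1] == choice[1:]) & lead
    win = (outcome[:-1] > 0) & lead
    lose = (outcome[:-1] < 0) & lead
    return (
        int((stay & win).sum()),
        int(win.sum()),
        int((stay & lose).sum()),
        int(lose.sum()),
    )


def stay_probabilities(data: SessionData, by_phase: bool = False) -> StayStats:
    """Win-stay and lose-stay proportions of one session.

    A trial pair (k, k+1) contributes only when both trials are valid;
    "stay" means the same option was chosen on both; the conditioning
    outcome is the one on trial k. With ``by_phase``, pairs are grouped
    by the phase of the leading trial k. Proportions with no qualifying
    pairs are NaN (``defined`` is False).
    """
    ws, nw, ls, nl = _stay_counts(data.choice, data.outcome, data.valid)
    phases = None
    if by_phase:
        phases = {}
        for ph in PHASE_LABELS:
            mask = data.schedule.phase == ph
            # pairs whose leading trial k falls in this phase
            lead = data.valid[:-1] & data.valid[1:] & mask[:-1]
            stay = (data.choice[:-1] == data.choice[1:]) & lead
            win = (data.outcome[:-1] > 0) & lead
            lose = (data.outcome[:-1] < 0) & lead
            nwp, nlp = int(win.sum()), int(lose.sum())
            phases[ph] = StayStats(
                win_stay=float((stay & win).sum() / nwp) if nwp else float("nan"),
                lose_stay=float((stay & lose).sum() / nlp) if nlp else float("nan"),
                n_win_pairs=nwp,
                n_lose_pairs=nlp,
            )
    return StayStats(
        win_stay=ws / nw if nw else float("nan"),
        lose_stay=ls / nl if nl else float("nan"),
        n_win_pairs=nw,
        n_lose_pairs=nl,
        by_phase=phases,
    )


def correct_choice_rate(data: SessionData) -> PhasePerformance:
    """Proportion of valid trials on which the better option was chosen."""
    rates = {}
    counts = {}
    for ph in PHASE_LABELS:
        mask = (data.schedule.phase == ph) & data.valid
        n = int(mask.sum())
        counts[ph] = n
        if n == 0:
            rates[ph] = float("nan")
        else:
            rates[ph] = float(
                (data.choice[mask] == data.schedule.correct_option[mask]).mean()
            )
    n_all = data.n_valid
    overall = (
        float((data.choice[data.valid] == data.schedule.correct_option[data.valid]).mean())
        if n_all
        else float("nan")
    )
    return PhasePerformance(
        pre=rates["pre"],
        reversal=rates["reversal"],
        post=rates["post"],
        overall=overall,
        n_valid=counts,
    )


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value, point-probability convention.

    Sums the probability of every outcome whose point probability does
    not exceed that of the observed count ("minlike" rule).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def pearson_chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def paired_effect_sizes(x, y) -> tuple[float, float]:
    """Effect sizes for a matched comparison: (Cohen's d, rank-biserial r).

    Cohen's d is mean(y - x) / SD(y - x) (sample SD). The matched
    rank-biserial correlation ranks the nonzero |differences| and
    returns (sum of positive-signed ranks - negative) / total rank sum.
    All-zero differences give NaN for both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D samples, n >= 2")
    diff = y - x
    nz = diff[diff != 0]
    if len(nz) == 0:
        return float("nan"), float("nan")
    sd = np.std(diff, ddof=1)
    d = float(np.mean(diff) / sd) if sd > 0 else float("nan")
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    r = (w_pos - w_neg) / (w_pos + w_neg)
    return d, float(r)
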