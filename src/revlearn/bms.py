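"""Random-effects Bayesian model selection (RFX-BMS) over subjects.

The generating model is treated as a random effect: each subject's data
arise from one of K candidate models, drawn from population frequencies
r with a Dirichlet prior. A variational scheme alternates subject-wise
model responsibilities with Dirichlet pseudo-count updates and yields

* PP  — posterior expected model frequencies,
* XP  — probability that each model is the most frequent (Monte Carlo
  over the Dirichlet posterior),
* BOR — Bayesian omnibus risk, the posterior probability of the null
  hypothesis that all models are equally frequent, obtained from the
  free energies of the null and the alternative, and
* PXP — exceedance probabilities shrunk toward 1/K by the BOR:
  ``pxp = (1 - bor) * xp + bor / K``.

Group or condition frequency-equality tests compare the free energy of
a pooled model (shared frequencies) against the sum of per-group free
energies (independent frequencies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp


@dataclass(frozen=True)
class EvidenceMatrix:
    """Log model evidences, subjects x models."""

    lme: np.ndarray
    models: tuple[str, ...]
    subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        lme = np.asarray(self.lme, dtype=float)
        if lme.ndim != 2:
            raise ValueError("lme must be a 2-D subjects x models array")
        if lme.shape != (len(self.subjects), len(self.models)):
            raise ValueError("lme shape must match subject and model labels")
        if lme.shape[1] < 2:
            raise ValueError("need at least 2 models")
        if lme.shape[0] < 1:
            raise ValueError("need at least 1 subject")
        bad = np.argwhere(~np.isfinite(lme))
        if bad.size:
            n, k = bad[0]
            raise ValueError(
                f"non-finite log evidence for subject {self.subjects[n]!r}, "
                f"model {self.models[k]!r}"
            )
        object.__setattr__(self, "lme", lme)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceMatrix":
        """Build from a DataFrame (index: subjects, columns: models)."""
        return cls(
            lme=df.to_numpy(dtype=float),
            models=tuple(map(str, df.columns)),
            subjects=tuple(map(str, df.index)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lme, index=list(self.subjects), columns=list(self.models))


@dataclass(frozen=True)
class BMSResult:
    """Posterior over model frequencies and derived selection statistics."""

    models: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    pp: np.ndarray
    xp: np.ndarray
    pxp: np.ndarray
    bor: float
    free_energy: float
    responsibilities: np.ndarray  # subjects x models

    @property
    def winner(self) -> str:
        return self.models[int(np.argmax(self.pxp))]

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "pp": self.pp.tolist(),
            "xp": self.xp.tolist(),
            "pxp": self.pxp.tolist(),
            "bor": self.bor,
            "free_energy": self.free_energy,
        }


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL( Dir(alpha) || Dir(alpha0) )."""
    a_sum, a0_sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(a_sum)
        - gammaln(alpha).sum()
        - gammaln(a0_sum)
        + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(a_sum)))
    )


def _free_energy(
    lme: np.ndarray, u: np.ndarray, alpha: np.ndarray, alpha0: np.ndarray
) -> float:
    """Variational free energy of the random-effects model."""
    elog_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.sum(np.where(u > 0, u * np.log(u), 0.0))
    return float(
        np.sum(u * (lme + elog_r[None, :])) + entropy - _dirichlet_kl(alpha, alpha0)
    )


def _null_free_energy(lme: np.ndarray) -> float:
    """Exact log evidence of the null model (frequencies fixed at 1/K)."""
    n, k = lme.shape
    return float(np.sum(logsumexp(lme, axis=1) - math.log(k)))


def exceedance_probabilities(
    alpha: np.ndarray,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior.

    The argmax of independent Gamma(alpha_k, 1) draws has the same law
    as the argmax of the Dirichlet vector, so no normalization is
    needed. Seeded and reproducible.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = len(alpha)
    counts = np.zeros(k, dtype=np.int64)
    chunk = 200_000
    remaining = n_draws
    while remaining > 0:
        m = min(chunk, remaining)
        g = rng.standard_gamma(np.broadcast_to(alpha, (m, k)))
        counts += np.bincount(np.argmax(g, axis=1), minlength=k)
        remaining -= m
    return counts / n_draws


def rfx_bms(
    ev: EvidenceMatrix,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    xp_draws: int = 1_000_000,
    rng: np.random.Generator | int | None = 0,
) -> BMSResult:
    """Random-effects Bayesian model selection.

    Iterates responsibilities ``u_nk propto exp(lme_nk + E[log r_k])``
    and Dirichlet counts ``alpha_k = alpha0 + sum_n u_nk`` to a 1e-6
    change in alpha, then computes PP, sampled XP, BOR and PXP.
    """
    lme = ev.lme
    n, k = lme.shape
    a0 = np.full(k, float(alpha0))
    alpha = a0.copy()
    u = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    pp = alpha / alpha.sum()
    xp = exceedance_probabilities(alpha, n_draws=xp_draws, rng=rng)
    f1 = _free_energy(lme, u, alpha, a0)
    f0 = _null_free_energy(lme)
    # posterior probability of the null (equal-frequency) hypothesis
    bor = 1.0 / (1.0 + math.exp(min(max(f1 - f0, -700.0), 700.0)))
    pxp = (1.0 - bor) * xp + bor / k
    return BMSResult(
        models=ev.models,
        dirichlet_alpha=alpha,
        pp=pp,
        xp=xp,
        pxp=pxp,
        bor=bor,
        free_energy=f1,
        responsibilities=u,
    )


def _check_same_models(ev_a: EvidenceMatrix, ev_b: EvidenceMatrix) -> None:
    if ev_a.models != ev_b.models:
        raise ValueError(
            f"model sets differ: {ev_a.models} vs {ev_b.models}"
        )


def frequency_equality_test(
    ev_a: EvidenceMatrix,
    ev_b: EvidenceMatrix,
    alpha0: float = 1.0,
    **kwargs,
) -> float:
    """Posterior probability that two cohorts share model frequencies.

    Compares the free energy of a pooled random-effects model (one
    frequency vector for all subjects) against the sum of free energies
    of independent per-cohort models, assuming equal prior odds:
    ``P(shared) = 1 / (1 + exp(F_indep - F_pooled))``.
    """
    _check_same_models(ev_a, ev_b)
    pooled = EvidenceMatrix(
        lme=np.vstack([ev_a.lme, ev_b.lme]),
        models=ev_a.models,
        subjects=tuple(ev_a.subjects) + tuple(ev_b.subjects),
    )
    f_pooled = rfx_bms(pooled, alpha0=alpha0, xp_draws=1000, **kwargs).free_energy
    f_a = rfx_bms(ev_a, alpha0=alpha0, xp_draws=1000, **kwargs).free_energy
    f_b = rfx_bms(ev_b, alpha0=alpha0, xp_draws=1000, **kwargs).free_energy
    diff = min(max((f_a + f_b) - f_pooled, -700.0), 700.0)
    return 1.0 / (1.0 + math.exp(diff))


def pooled_selection(
    ev_condition_1: EvidenceMatrix,
    ev_condition_2: EvidenceMatrix,
    **kwargs,
) -> BMSResult:
    """BMS on per-subject evidence summed across matched conditions."""
    _check_same_models(ev_condition_1, ev_condition_2)
    if ev_condition_1.subjects != ev_condition_2.subjects:
        raise ValueError("subject sets must match across conditions")
    pooled = EvidenceMatrix(
        lme=ev_condition_1.lme + ev_condition_2.lme,
        models=ev_condition_1.models,
        subjects=ev_condition_1.subjects,
    )
    return rfx_bms(pooled, **kwargs)
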