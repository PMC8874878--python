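"""MAP estimation of model parameters with Laplace model evidence.

Parameters are fitted in an unconstrained space — logit for the
learning rates and kappa (native support (0, 1)), log for beta (native
support (0, inf)) — under independent Gaussian priors placed in that
space, with means at the transform of the native prior means and unit
variance. Optimization is multistart quasi-Newton (L-BFGS-B) from the
prior mean plus seeded Gaussian jitter. The log model evidence is the
Laplace approximation around the MAP; sessions whose best fit does not
beat chance-level choice prediction can be flagged for exclusion via an
exact binomial test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .models import ModelSpec, ParamSet, SessionData, session_nll

_EPS = 1e-12

#: transform attached to each native parameter
TRANSFORMS = {
    "alpha": "logit",
    "alpha_rew": "logit",
    "alpha_pun": "logit",
    "kappa": "logit",
    "beta": "log",
}

#: native-space prior means; variances are in unconstrained space
DEFAULT_PRIOR_MEANS = {
    "alpha": 0.5,
    "alpha_rew": 0.5,
    "alpha_pun": 0.5,
    "kappa": 0.1,
    "beta": 1.0,
}


def transform_param(name: str, value: float) -> float:
    """Native -> unconstrained (logit or log), clipping boundary values."""
    kind = TRANSFORMS[name]
    if kind == "logit":
        if not 0.0 < value < 1.0:
            warnings.warn(f"{name}={value} clipped to the open unit interval")
            value = min(max(value, _EPS), 1.0 - _EPS)
        return math.log(value / (1.0 - value))
    if value <= 0.0:
        warnings.warn(f"{name}={value} clipped to a positive value")
        value = _EPS
    return math.log(value)


def untransform_param(name: str, x: float) -> float:
    """Unconstrained -> native; inverse of :func:`transform_param`."""
    x = min(max(x, -700.0), 700.0)  # optimizer excursions must not overflow
    if TRANSFORMS[name] == "logit":
        if x >= 0:
            return 1.0 / (1.0 + math.exp(-x))
        e = math.exp(x)
        return e / (1.0 + e)
    return math.exp(x)


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors in unconstrained space, one per parameter.

    ``means`` are native-space prior means (transformed internally);
    ``variances`` apply in the unconstrained space.
    """

    means: dict = field(default_factory=lambda: dict(DEFAULT_PRIOR_MEANS))
    variances: dict = field(
        default_factory=lambda: {k: 1.0 for k in DEFAULT_PRIOR_MEANS}
    )

    def __post_init__(self) -> None:
        for name, var in self.variances.items():
            if var <= 0:
                raise ValueError(f"prior variance for {name} must be positive")

    def unconstrained_mean(self, name: str) -> float:
        return transform_param(name, self.means[name])

    def mean_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([self.unconstrained_mean(p) for p in spec.free_params])

    def variance_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([self.variances[p] for p in spec.free_params])

    def log_density(self, x: np.ndarray, spec: ModelSpec) -> float:
        """Log prior density at an unconstrained parameter vector."""
        mu = self.mean_vector(spec)
        var = self.variance_vector(spec)
        return float(
            -0.5 * np.sum((x - mu) ** 2 / var)
            - 0.5 * np.sum(np.log(2.0 * np.pi * var))
        )


def params_to_unconstrained(params: ParamSet, spec: ModelSpec) -> np.ndarray:
    return np.array(
        [transform_param(p, getattr(params, p)) for p in spec.free_params]
    )


def params_from_unconstrained(x: np.ndarray, spec: ModelSpec) -> ParamSet:
    values = {p: untransform_param(p, xi) for p, xi in zip(spec.free_params, x)}
    return ParamSet(**values)


@dataclass
class FitResult:
    """MAP fit of one model to one session."""

    spec: ModelSpec
    map_params: ParamSet
    x_map: np.ndarray  # unconstrained MAP
    nll: float
    log_joint: float  # -nll + log prior density at MAP (unconstrained space)
    lme: float  # Laplace log model evidence
    hessian_ok: bool
    n_restarts_used: int
    n_valid_trials: int
    chance_p: float | None = None
    excluded_chance: bool | None = None


def neg_log_joint(
    x: np.ndarray,
    data: SessionData,
    spec: ModelSpec,
    priors: PriorSpec,
) -> float:
    """Negative (log-likelihood + log prior) at an unconstrained point."""
    params = params_from_unconstrained(np.asarray(x, dtype=float), spec)
    return session_nll(data, params, spec) - priors.log_density(
        np.asarray(x, dtype=float), spec
    )


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def laplace_evidence(
    x_map: np.ndarray,
    log_joint_at_map: float,
    objective,
    n_valid_trials: int,
) -> tuple[float, bool]:
    """Laplace log model evidence around the MAP.

    ``lme = log_joint + (d/2) log 2*pi - 0.5 log det H`` with ``H`` the
    central-difference Hessian of the negative log-joint at the MAP. If
    ``H`` is not positive-definite (or not finite), falls back to a
    BIC-style quadratic penalty ``log_joint - (d/2) log n`` and reports
    ``hessian_ok = False``.
    """
    d = len(x_map)
    H = _numeric_hessian(objective, np.asarray(x_map, dtype=float))
    ok = bool(np.all(np.isfinite(H)))
    if ok:
        try:
            sign, logdet = np.linalg.slogdet(H)
            eigmin = np.linalg.eigvalsh(H).min()
            ok = sign > 0 and eigmin > 0 and np.isfinite(logdet)
        except np.linalg.LinAlgError:
            ok = False
    if ok:
        lme = log_joint_at_map + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet
    else:
        lme = log_joint_at_map - 0.5 * d * math.log(max(n_valid_trials, 1))
    return float(lme), ok


def fit_map(
    data: SessionData,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = 0,
    jitter_sd: float = 2.0,
    tol: float = 1e-6,
) -> FitResult:
    """Multistart MAP fit of one model to one session.

    Restart 1 starts at the prior mean; the others add seeded Gaussian
    jitter (SD ``jitter_sd``) in unconstrained space. The best local
    optimum over restarts is returned. Deterministic under a fixed seed.
    """
    if priors is None:
        priors = PriorSpec()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mu = priors.mean_vector(spec)
    d = len(mu)

    if data.n_valid == 0:
        # prior-dominated limit: MAP at the prior mean, no likelihood
        x = mu.copy()
        lj = priors.log_density(x, spec)
        obj = lambda z: -priors.log_density(np.asarray(z), spec)
        lme, ok = laplace_evidence(x, lj, obj, 0)
        return FitResult(
            spec=spec,
            map_params=params_from_unconstrained(x, spec),
            x_map=x,
            nll=0.0,
            log_joint=lj,
            lme=lme,
            hessian_ok=ok,
            n_restarts_used=0,
            n_valid_trials=0,
        )

    def objective(x: np.ndarray) -> float:
        return neg_log_joint(x, data, spec, priors)

    best = None
    failures = []
    for r in range(n_restarts):
        x0 = mu if r == 0 else mu + jitter_sd * rng.standard_normal(d)
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if not np.isfinite(res.fun):
            failures.append((r, res.message))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {failures}")

    x_map = best.x
    log_joint = -float(best.fun)
    nll = session_nll(data, params_from_unconstrained(x_map, spec), spec)
    lme, hess_ok = laplace_evidence(x_map, log_joint, objective, data.n_valid)
    return FitResult(
        spec=spec,
        map_params=params_from_unconstrained(x_map, spec),
        x_map=x_map,
        nll=nll,
        log_joint=log_joint,
        lme=lme,
        hessian_ok=hess_ok,
        n_restarts_used=n_restarts - len(failures),
        n_valid_trials=data.n_valid,
    )


def chance_fit_test(
    nll: float | FitResult,
    n_valid_trials: int | None = None,
    alpha_level: float = 0.05,
) -> tuple[float, bool]:
    """Does the model predict choices better than chance?

    The fraction of choices explained is ``f = exp(-nll / n)`` (the
    geometric-mean per-trial likelihood); ``k = round(f * n)`` successes
    in ``n`` trials are tested one-sided against chance 0.5 by an exact
    binomial test. Returns ``(p_value, excluded)`` with exclusion when
    ``p >= alpha_level``.
    """
    if isinstance(nll, FitResult):
        fit = nll
        nll = fit.nll
        n_valid_trials = fit.n_valid_trials if n_valid_trials is None else n_valid_trials
    if n_valid_trials is None or n_valid_trials <= 0:
        raise ValueError("n_valid_trials must be positive")
    f = math.exp(-nll / n_valid_trials)
    k = int(round(f * n_valid_trials))
    k = min(max(k, 0), n_valid_trials)
    p = stats.binomtest(k, n_valid_trials, 0.5, alternative="greater").pvalue
    return float(p), bool(p >= alpha_level)


def apply_chance_test(fit: FitResult, alpha_level: float = 0.05) -> FitResult:
    """Fill the chance-fit fields of a FitResult in place and return it."""
    p, excl = chance_fit_test(fit.nll, fit.n_valid_trials, alpha_level)
    fit.chance_p = p
    fit.excluded_chance = excl
    return fit
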