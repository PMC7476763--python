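"""MAP estimation and Laplace-approximate log model evidence.

Each model's free parameters are optimized in an unconstrained estimation
space (logit / log / identity per parameter) by multi-start quasi-Newton
minimization of the negative joint log posterior: choice log-likelihood plus
wager log-likelihood plus Gaussian log-priors. The log model evidence is the
Laplace approximation at the MAP,

    LME = log p(y, theta*) + (d/2) log(2 pi) - (1/2) log det H,

with H the numerical Hessian of the negative log posterior over the d free
parameters (central differences).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .hgf import FilterDivergenceError, filter_branches
from .params import ModelSpec, PriorSpec, to_native
from .response import data_loglik, predict_run
from .task import SubjectData, TaskSchedule

__all__ = [
    "OptimizerConfig",
    "FitResult",
    "joint_log_posterior",
    "map_fit",
    "log_model_evidence",
]

logger = logging.getLogger(__name__)

#: Large finite penalty returned when the filter diverges, optimizer-safe.
_DIVERGENCE_PENALTY = -1e10

_BOUNDS = {"logit": (-12.0, 12.0), "log": (-10.0, 10.0), "identity": (-30.0, 30.0)}


@dataclass(frozen=True)
class OptimizerConfig:
    """Multi-start quasi-Newton settings.

    Starts are the prior mean plus Gaussian jitter scaled by the prior SD
    (capped so that near-flat priors do not scatter starts into absurd
    regions). Deterministic given ``seed``.
    """

    n_starts: int = 10
    seed: int = 0
    maxiter: int = 500
    tol: float = 1e-6
    jitter_cap: float = 2.0


@dataclass
class FitResult:
    """MAP fit of one model to one subject."""

    model: str
    free_names: tuple[str, ...]
    x_est: np.ndarray                  # MAP in estimation space
    natives: dict[str, float]          # MAP in native space (free params)
    log_posterior: float               # joint log posterior at the MAP
    log_likelihood: float
    converged: bool
    lme: float | None = None
    diagnostics: dict = field(default_factory=dict)


def _prior_logpdf(x: np.ndarray, priors: list[PriorSpec]) -> float:
    lp = 0.0
    for xi, p in zip(x, priors):
        v = p.variance
        lp += -0.5 * math.log(2.0 * math.pi * v) - 0.5 * (xi - p.est_mean) ** 2 / v
    return lp


def _unpack(x: np.ndarray, names: tuple[str, ...],
            priors: dict[str, PriorSpec]) -> dict[str, float]:
    return {n: to_native(float(xi), priors[n].transform)
            for n, xi in zip(names, x)}


def joint_log_posterior(x_est: np.ndarray, data: SubjectData,
                        schedule: TaskSchedule, model: ModelSpec,
                        prior_spec: dict[str, PriorSpec] | None = None) -> float:
    """Joint log posterior of the free parameters (estimation space).

    Filter divergence during the trajectory computation returns a large
    negative sentinel instead of raising, so optimizers can recover.
    """
    priors = prior_spec or model.priors()
    names = tuple(n for n in priors if not priors[n].fixed)
    x = np.asarray(x_est, dtype=float)
    if x.shape != (len(names),):
        raise ValueError(f"expected {len(names)} free parameters {names}, "
                         f"got shape {x.shape}")
    free_natives = _unpack(x, names, priors)
    fixed = {n: priors[n].native_mean for n in priors if priors[n].fixed}
    values = {**fixed, **free_natives}
    perc, resp = model.build_params(values)

    lp = _prior_logpdf(x, [priors[n] for n in names])
    if len(data) == 0:
        return lp
    try:
        traj_a, traj_c = filter_branches(schedule.advice_accurate,
                                         schedule.outcome_color, perc)
        pred = predict_run(traj_a, traj_c, schedule.advice_color, resp,
                           model.response_variant)
        ll = data_loglik(data.choice, data.wager, pred, resp)
    except FilterDivergenceError as err:
        logger.debug("filter divergence during fit: %s", err)
        return _DIVERGENCE_PENALTY - float(np.sum(x * x))
    if not math.isfinite(ll):
        return _DIVERGENCE_PENALTY - float(np.sum(x * x))
    return ll + lp


def _loglik_at(values: dict[str, float], data: SubjectData,
               schedule: TaskSchedule, model: ModelSpec) -> float:
    perc, resp = model.build_params(values)
    traj_a, traj_c = filter_branches(schedule.advice_accurate,
                                     schedule.outcome_color, perc)
    pred = predict_run(traj_a, traj_c, schedule.advice_color, resp,
                       model.response_variant)
    return data_loglik(data.choice, data.wager, pred, resp)


def map_fit(data: SubjectData, schedule: TaskSchedule, model: ModelSpec,
            prior_spec: dict[str, PriorSpec] | None = None,
            optimizer: OptimizerConfig | None = None) -> FitResult:
    """Multi-start MAP fit of one model to one subject's responses."""
    if len(data) != len(schedule):
        raise ValueError("responses are not aligned to the schedule")
    opt = optimizer or OptimizerConfig()
    priors = prior_spec or model.priors()
    names = tuple(n for n in priors if not priors[n].fixed)

    if not names:
        values = {n: priors[n].native_mean for n in priors}
        ll = _loglik_at(values, data, schedule, model)
        return FitResult(model=model.name, free_names=(), x_est=np.empty(0),
                         natives={}, log_posterior=ll, log_likelihood=ll,
                         converged=True, lme=ll,
                         diagnostics={"n_starts": 0, "fully_fixed": True})

    mean = np.array([priors[n].est_mean for n in names])
    sd = np.array([min(math.sqrt(priors[n].variance), opt.jitter_cap)
                   for n in names])
    bounds = [_BOUNDS[priors[n].transform] for n in names]

    def neg(x):
        return -joint_log_posterior(x, data, schedule, model, priors)

    rng = np.random.default_rng(opt.seed)
    starts = [mean] + [mean + sd * rng.standard_normal(len(names))
                       for _ in range(opt.n_starts - 1)]

    best = None
    n_ok = 0
    for x0 in starts:
        res = minimize(neg, np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": opt.maxiter, "ftol": opt.tol})
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        return FitResult(model=model.name, free_names=names,
                         x_est=mean.copy(), natives=_unpack(mean, names, priors),
                         log_posterior=-math.inf, log_likelihood=-math.inf,
                         converged=False,
                         diagnostics={"n_starts": opt.n_starts, "n_converged": 0,
                                      "fit_failure": True})

    x_map = best.x
    natives = _unpack(x_map, names, priors)
    fixed = {n: priors[n].native_mean for n in priors if priors[n].fixed}
    try:
        ll = _loglik_at({**fixed, **natives}, data, schedule, model)
    except FilterDivergenceError:
        ll = -math.inf
    fit = FitResult(model=model.name, free_names=names, x_est=x_map,
                    natives=natives, log_posterior=-best.fun,
                    log_likelihood=ll, converged=bool(best.success or n_ok > 0),
                    diagnostics={"n_starts": opt.n_starts, "n_converged": n_ok,
                                 "iterations": int(best.nit)})
    fit.lme = log_model_evidence(lambda x: -neg(x), x_map, -best.fun, len(names),
                                 diagnostics=fit.diagnostics)
    return fit


def log_model_evidence(log_posterior_fn, x_map: np.ndarray, logpost_max: float,
                       n_free: int, step: float = 1e-3,
                       diagnostics: dict | None = None) -> float:
    """Laplace approximation of the log model evidence.

    ``log_posterior_fn`` maps an estimation-space vector to the joint log
    posterior. With zero free parameters the evidence is the log-likelihood
    at the fixed parameters (no Occam term). A non-positive-definite Hessian
    is regularized by flooring its eigenvalues, flagged in ``diagnostics``.
    """
    if n_free == 0:
        return logpost_max
    x = np.asarray(x_map, dtype=float)
    d = n_free
    H = np.empty((d, d))
    f0 = -log_posterior_fn(x)

    def f(y):
        return -log_posterior_fn(y)

    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * step**2)

    eigvals = np.linalg.eigvalsh(0.5 * (H + H.T))
    if np.any(eigvals <= 0):
        eigvals = np.maximum(eigvals, 1e-6)
        if diagnostics is not None:
            diagnostics["hessian_regularized"] = True
    logdet = float(np.sum(np.log(eigvals)))
    return logpost_max + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet
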