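"""Maximum-likelihood fitting of single densities and two-component
mixtures for the normal and SNP families.

Four fitters share the conventions:

* free-parameter counts for AIC: single normal 2, single SNP ``2 + K``,
  normal mixture 5, SNP mixture ``2 (2 + K) + 1`` (``a_0 = 1`` is fixed);
* components are relabeled after fitting so the early component has the
  smaller mode;
* all randomness flows from ``config.seed``;
* with ``config.truncation = (lo, hi)`` each component density is
  renormalized to the window inside the likelihood, so mixing weights
  refer to the latent (pre-truncation-rejection) component membership.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np
from scipy import optimize

from . import densities as dens
from .densities import NormalParams, SNPParams
from .errors import (
    ConvergenceWarning,
    DegenerateDataError,
    DegenerateFitError,
    ModeWarning,
    ParameterError,
)

__all__ = [
    "FitConfig",
    "MixtureParams",
    "FitResult",
    "fit_single_normal",
    "fit_single_snp",
    "fit_mixture_normal_em",
    "fit_mixture_snp",
    "mixture_logpdf",
    "mixture_pdf",
]

ComponentParams = Union[NormalParams, SNPParams]


@dataclass(frozen=True)
class FitConfig:
    """Knobs shared by all fitters."""

    degree: int = 2
    n_random_starts: int = 10
    tol: float = 1e-8
    max_iter: int = 1000
    sigma_floor: float = 0.5
    truncation: Optional[Tuple[float, float]] = None
    seed: int = 1


@dataclass(frozen=True)
class MixtureParams:
    """Two-component mixture; ``pi_early`` weights the early component."""

    comp_early: ComponentParams
    comp_late: ComponentParams
    pi_early: float

    def __post_init__(self):
        if not (0.0 < self.pi_early < 1.0):
            raise ParameterError(
                f"pi_early must lie in (0, 1), got {self.pi_early}"
            )
        if type(self.comp_early) is not type(self.comp_late):
            raise ParameterError("components must share a family")

    @property
    def pi_late(self) -> float:
        return 1.0 - self.pi_early


@dataclass(frozen=True)
class FitResult:
    model: str
    params: Union[ComponentParams, MixtureParams]
    loglik: float
    k: int
    converged: bool
    n_starts_used: int = 1
    iterations: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


def _log_trunc_mass(params, truncation):
    lo, hi = truncation
    mass = float(dens.cdf(hi, params) - dens.cdf(lo, params))
    if mass <= 0:
        return -np.inf
    return math.log(mass)


def single_loglik(ages, params, truncation=None) -> float:
    ll = float(np.sum(dens.logpdf(ages, params)))
    if truncation is not None:
        ll -= ages.size * _log_trunc_mass(params, truncation)
    return ll


def mixture_logpdf(x, params: MixtureParams, truncation=None):
    la = np.log(params.pi_early) + dens.logpdf(x, params.comp_early)
    lb = np.log(params.pi_late) + dens.logpdf(x, params.comp_late)
    if truncation is not None:
        la = la - _log_trunc_mass(params.comp_early, truncation)
        lb = lb - _log_trunc_mass(params.comp_late, truncation)
    return np.logaddexp(la, lb)


def mixture_pdf(x, params: MixtureParams, truncation=None):
    return np.exp(mixture_logpdf(x, params, truncation))


def mixture_loglik(ages, params: MixtureParams, truncation=None) -> float:
    return float(np.sum(mixture_logpdf(ages, params, truncation)))


def _component_mode(params) -> float:
    return params.mode


def _order_components(comp_a, comp_b, pi_a) -> MixtureParams:
    """Relabel so the early component has the smaller mode; ties go to
    the heavier component (with a warning)."""
    mode_a, mode_b = _component_mode(comp_a), _component_mode(comp_b)
    if mode_a < mode_b:
        return MixtureParams(comp_a, comp_b, pi_a)
    if mode_b < mode_a:
        return MixtureParams(comp_b, comp_a, 1.0 - pi_a)
    warnings.warn(
        "component modes are equal; early label assigned to the "
        "heavier component",
        ModeWarning,
        stacklevel=3,
    )
    if pi_a >= 0.5:
        return MixtureParams(comp_a, comp_b, pi_a)
    return MixtureParams(comp_b, comp_a, 1.0 - pi_a)


def _check_ages(ages, min_n):
    ages = np.asarray(ages, dtype=float).ravel()
    if ages.size < min_n:
        raise DegenerateDataError(
            f"need at least {min_n} ages, got {ages.size}"
        )
    if not np.all(np.isfinite(ages)):
        raise DegenerateDataError("ages contain non-finite values")
    return ages


# ---------------------------------------------------------------------------
# single normal


def fit_single_normal(ages, config: FitConfig = FitConfig()) -> FitResult:
    """Closed-form normal MLE (``sigma`` is the 1/n estimator); switches
    to numerical ML when a truncation window is configured."""
    ages = _check_ages(ages, 2)
    mu = float(np.mean(ages))
    sigma = float(np.std(ages))  # ML (1/n) estimator
    if sigma <= 0:
        raise DegenerateDataError("all ages identical: degenerate variance")
    if config.truncation is None:
        params = NormalParams(mu, sigma)
        return FitResult(
            model="single_normal",
            params=params,
            loglik=single_loglik(ages, params),
            k=2,
            converged=True,
        )

    def nll(theta):
        p = NormalParams(theta[0], math.exp(theta[1]))
        return -single_loglik(ages, p, config.truncation)

    res = optimize.minimize(
        nll,
        x0=[mu, math.log(max(sigma, config.sigma_floor))],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    params = NormalParams(float(res.x[0]), float(math.exp(res.x[1])))
    return FitResult(
        model="single_normal",
        params=params,
        loglik=-float(res.fun),
        k=2,
        converged=bool(res.success),
        iterations=int(res.nit),
    )


# ---------------------------------------------------------------------------
# single SNP


def _snp_from_theta(theta, degree):
    mu = float(theta[0])
    sigma = float(math.exp(theta[1]))
    coeffs = (1.0, *map(float, theta[2 : 2 + degree]))
    return SNPParams(mu, sigma, coeffs)


def _theta_from_snp(p: SNPParams):
    return np.array([p.mu, math.log(p.sigma), *p.coeffs[1:]], dtype=float)


def fit_single_snp(ages, degree: Optional[int] = None,
                   config: FitConfig = FitConfig()) -> FitResult:
    """Multi-start numerical ML for the single SNP density.

    The normal MLE with zero higher-order coefficients is always one of
    the starts, so the fitted log-likelihood never falls below the
    nested single-normal fit.
    """
    if degree is None:
        degree = config.degree
    if not 0 <= degree <= dens.MAX_DEGREE:
        raise ParameterError(f"degree must be in [0, {dens.MAX_DEGREE}]")
    ages = _check_ages(ages, degree + 3)
    base = fit_single_normal(ages, replace(config, truncation=None))
    if degree == 0:
        params = SNPParams(base.params.mu, base.params.sigma, (1.0,))
        if config.truncation is None:
            return FitResult(
                model="single_snp",
                params=params,
                loglik=single_loglik(ages, params),
                k=2,
                converged=True,
            )

    def nll(theta):
        try:
            p = _snp_from_theta(theta, degree)
        except (ParameterError, OverflowError):
            return np.inf
        ll = single_loglik(ages, p, config.truncation)
        return np.inf if not np.isfinite(ll) else -ll

    rng = np.random.default_rng([config.seed, 11])
    mu0, sd0 = base.params.mu, base.params.sigma
    theta0 = np.array([mu0, math.log(sd0)] + [0.0] * degree)
    starts = [theta0]
    if degree >= 1:
        # skew-probing starts: a nonzero a_1 plants a density zero, so
        # the optimizer cannot cross a_1 = 0 from the normal MLE start
        for s in (0.7, -0.7):
            probe = np.array(
                [mu0 - s * sd0, math.log(0.85 * sd0), s]
                + [0.0] * (degree - 1)
            )
            starts.append(probe)
    for _ in range(config.n_random_starts):
        jitter = np.concatenate(
            [
                rng.normal(0, 0.5 * sd0, 1),  # mu, years
                rng.normal(0, 0.25, 1),       # log sigma
                rng.normal(0, 0.6, degree),   # polynomial coeffs
            ]
        )
        starts.append(theta0 + jitter)

    log_floor = math.log(config.sigma_floor)
    bounds = [(None, None), (log_floor, 12.0)] + [(None, None)] * degree
    best_theta, best_nll = theta0, nll(theta0)
    n_used, iters, converged = 0, 0, False
    for theta in starts:
        n_used += 1
        res = optimize.minimize(
            nll, theta, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": 1e-12},
        )
        iters += int(res.nit)
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best_theta = float(res.fun), res.x
        converged = converged or bool(res.success)
    if not converged:
        warnings.warn(
            "single-SNP fit: no start converged; best attempt returned",
            ConvergenceWarning,
            stacklevel=2,
        )
    params = _snp_from_theta(best_theta, degree)
    return FitResult(
        model="single_snp",
        params=params,
        loglik=-float(best_nll),
        k=2 + degree,
        converged=converged,
        n_starts_used=n_used,
        iterations=iters,
    )


# ---------------------------------------------------------------------------
# normal mixture via EM


class _Collapse(Exception):
    pass


def _em_from_responsibilities(ages, gamma, config, trace=None):
    """Run EM to convergence from initial responsibilities.

    Returns (mu, sd, pi1, loglik, n_iter, converged). The E/M updates
    guarantee a non-decreasing log-likelihood; ``trace``, if a list, is
    appended with the per-iteration log-likelihood sequence.
    """
    n = ages.size
    prev_ll = -np.inf
    for it in range(1, config.max_iter + 1):
        # M-step
        w = gamma.sum(axis=0)
        if np.any(w < 1e-10):
            raise _Collapse
        pi1 = w[0] / n
        mu = (gamma * ages[:, None]).sum(axis=0) / w
        var = (gamma * (ages[:, None] - mu) ** 2).sum(axis=0) / w
        sd = np.sqrt(var)
        if np.any(sd < config.sigma_floor):
            raise _Collapse
        # E-step + loglik
        comp = np.column_stack(
            [
                np.log(pi1) + dens.normal_logpdf(ages, NormalParams(mu[0], sd[0])),
                np.log(1 - pi1) + dens.normal_logpdf(ages, NormalParams(mu[1], sd[1])),
            ]
        )
        norm = np.logaddexp(comp[:, 0], comp[:, 1])
        ll = float(norm.sum())
        gamma = np.exp(comp - norm[:, None])
        if trace is not None:
            trace.append(ll)
        if np.isfinite(prev_ll) and (
            abs(ll - prev_ll) <= config.tol * (abs(prev_ll) + 1.0)
        ):
            return mu, sd, pi1, ll, it, True
        prev_ll = ll
    return mu, sd, pi1, prev_ll, config.max_iter, False


def _em_starts(ages, config):
    """Initial responsibilities: quantile splits at the 30th/50th/70th
    percentiles plus seeded random partitions."""
    rng = np.random.default_rng([config.seed, 23])
    n = ages.size
    starts = []
    for q in (30, 50, 70):
        cut = np.percentile(ages, q)
        hard = (ages <= cut).astype(float)
        if 0 < hard.sum() < n:
            gamma = np.column_stack([0.9 * hard + 0.05, 0.95 - 0.9 * hard])
            starts.append(gamma)
    for _ in range(config.n_random_starts):
        p = rng.uniform(0.05, 0.95, size=n)
        starts.append(np.column_stack([p, 1.0 - p]))
    return starts


def fit_mixture_normal_em(ages, config: FitConfig = FitConfig()) -> FitResult:
    """Two-component normal mixture by multi-start EM.

    With a truncation window the EM solution (untruncated likelihood)
    seeds a direct Nelder-Mead maximization of the truncated
    likelihood.
    """
    ages = _check_ages(ages, 10)
    if np.std(ages) <= 0:
        raise DegenerateDataError("all ages identical: degenerate variance")
    best = None
    n_used, iters_total, any_converged = 0, 0, False
    for gamma in _em_starts(ages, config):
        n_used += 1
        try:
            mu, sd, pi1, ll, it, conv = _em_from_responsibilities(
                ages, gamma, config
            )
        except _Collapse:
            continue
        iters_total += it
        any_converged = any_converged or conv
        if best is None or ll > best[3]:
            best = (mu, sd, pi1, ll, conv)
    if best is None:
        raise DegenerateFitError(
            "all EM starts collapsed below the sigma floor"
        )
    mu, sd, pi1, ll, conv = best
    pi1 = float(np.clip(pi1, 1e-9, 1 - 1e-9))

    if config.truncation is not None:
        theta0 = np.array(
            [mu[0], math.log(sd[0]), mu[1], math.log(sd[1]),
             math.log(pi1 / (1 - pi1))]
        )

        def nll(theta):
            try:
                p = MixtureParams(
                    NormalParams(theta[0], math.exp(theta[1])),
                    NormalParams(theta[2], math.exp(theta[3])),
                    1.0 / (1.0 + math.exp(-theta[4])),
                )
            except (ParameterError, OverflowError):
                return np.inf
            v = mixture_loglik(ages, p, config.truncation)
            return np.inf if not np.isfinite(v) else -v

        res = optimize.minimize(
            nll, theta0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 5000},
        )
        iters_total += int(res.nit)
        mu = np.array([res.x[0], res.x[2]])
        sd = np.exp([res.x[1], res.x[3]])
        pi1 = 1.0 / (1.0 + math.exp(-res.x[4]))
        ll = -float(res.fun)
        any_converged = bool(res.success)

    params = _order_components(
        NormalParams(float(mu[0]), float(sd[0])),
        NormalParams(float(mu[1]), float(sd[1])),
        pi1,
    )
    if not any_converged:
        warnings.warn(
            "normal-mixture EM: no start converged; best attempt returned",
            ConvergenceWarning,
            stacklevel=2,
        )
    return FitResult(
        model="mixture_normal",
        params=params,
        loglik=ll,
        k=5,
        converged=any_converged,
        n_starts_used=n_used,
        iterations=iters_total,
    )


# ---------------------------------------------------------------------------
# SNP mixture by direct numerical ML


def _mix_from_theta(theta, degree):
    d = degree
    c1 = _snp_from_theta(theta[0 : 2 + d], d)
    c2 = _snp_from_theta(theta[2 + d : 4 + 2 * d], d)
    pi = 1.0 / (1.0 + math.exp(-float(theta[-1])))
    pi = min(max(pi, 1e-12), 1 - 1e-12)
    return MixtureParams(c1, c2, pi)


def fit_mixture_snp(ages, degree: Optional[int] = None,
                    config: FitConfig = FitConfig()) -> FitResult:
    """Two-component SNP mixture by multi-start quasi-Newton ML on the
    unconstrained scale (log sigma, logit pi).

    Starts include (a) the normal-mixture EM solution with zero
    higher-order coefficients and (b) a split of the single-SNP fit, so
    the result is never worse than either nested model (up to optimizer
    slack).
    """
    if degree is None:
        degree = config.degree
    if not 0 <= degree <= dens.MAX_DEGREE:
        raise ParameterError(f"degree must be in [0, {dens.MAX_DEGREE}]")
    ages = _check_ages(ages, 2 * (degree + 3))
    d = degree

    def nll(theta):
        try:
            p = _mix_from_theta(theta, d)
        except (ParameterError, OverflowError):
            return np.inf
        v = mixture_loglik(ages, p, config.truncation)
        return np.inf if not np.isfinite(v) else -v

    em = fit_mixture_normal_em(ages, config)
    e, l = em.params.comp_early, em.params.comp_late
    theta_em = np.concatenate(
        [
            [e.mu, math.log(e.sigma)], np.zeros(d),
            [l.mu, math.log(l.sigma)], np.zeros(d),
            [math.log(em.params.pi_early / em.params.pi_late)],
        ]
    )
    single = fit_single_snp(ages, degree=d, config=config)
    sp = single.params
    theta_single = np.concatenate(
        [
            [sp.mu, math.log(sp.sigma)], sp.coeffs[1:],
            [sp.mu, math.log(sp.sigma)], sp.coeffs[1:],
            [0.0],
        ]
    )
    rng = np.random.default_rng([config.seed, 37])
    starts = [theta_em, theta_single]
    for _ in range(config.n_random_starts):
        jitter = np.concatenate(
            [
                rng.normal(0, 2.0, 1), rng.normal(0, 0.15, 1),
                rng.normal(0, 0.3, d),
                rng.normal(0, 2.0, 1), rng.normal(0, 0.15, 1),
                rng.normal(0, 0.3, d),
                rng.normal(0, 0.5, 1),
            ]
        )
        starts.append(theta_em + jitter)

    log_floor = math.log(config.sigma_floor)
    bounds = (
        [(None, None), (log_floor, 12.0)] + [(None, None)] * d
    ) * 2 + [(-12.0, 12.0)]
    # initial points count toward the best so nesting survives optimizer
    # failure on any individual start
    best_theta = theta_em
    best_nll = nll(theta_em)
    for theta in starts:
        v0 = nll(theta)
        if v0 < best_nll:
            best_nll, best_theta = v0, theta
    n_used, iters, converged = 0, 0, False
    for theta in starts:
        n_used += 1
        try:
            res = optimize.minimize(
                nll, theta, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": config.max_iter, "ftol": 1e-12},
            )
        except (FloatingPointError, OverflowError):
            continue
        iters += int(res.nit)
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll, best_theta = float(res.fun), res.x
        converged = converged or bool(res.success)
    if not converged:
        warnings.warn(
            "SNP-mixture fit: no start converged; best attempt returned",
            ConvergenceWarning,
            stacklevel=2,
        )
    raw = _mix_from_theta(best_theta, d)
    params = _order_components(raw.comp_early, raw.comp_late, raw.pi_early)
    return FitResult(
        model="mixture_snp",
        params=params,
        loglik=-float(best_nll),
        k=2 * (2 + d) + 1,
        converged=converged,
        n_starts_used=n_used,
        iterations=iters,
    )
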