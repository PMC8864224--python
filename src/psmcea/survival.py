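"""Parametric survival curves, censored maximum likelihood, and AIC model selection.

Six families are supported — exponential, Weibull, log-normal, log-logistic,
Gompertz and generalized gamma — which together span the extrapolation
candidates routinely used for oncology trial curves.  Each family exposes the
survival function S(t), hazard h(t), inverse survival function and median on a
common time scale of months.

Parameterizations
-----------------
exponential(rate)            S(t) = exp(-rate * t)
weibull(shape, scale)        S(t) = exp(-(t / scale) ** shape)
lognormal(mu, sigma)         S(t) = 1 - Phi((ln t - mu) / sigma)
loglogistic(lam, gamma)      S(t) = 1 / (1 + lam * t ** gamma)
gompertz(shape, rate)        S(t) = exp(-(rate / shape) * (exp(shape * t) - 1))
gengamma(mu, sigma, Q)       stable (mu, sigma, Q) form; Q -> 0 is log-normal

The log-logistic form with a scale-like ``lam`` (rather than the
``(t/alpha)**beta`` form) is chosen so that the median is (1/lam)**(1/gamma);
the log-normal median is exp(mu).  Hazard-ratio-adjusted curves are obtained
by raising a reference curve to the power of the hazard ratio, i.e. by scaling
the cumulative hazard (proportional hazards).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "ProportionalHazardsCurve",
    "HazardRatio",
    "FitResult",
    "survival_at",
    "median_survival",
    "apply_hazard_ratio",
    "fit_mle",
    "fit_all_families",
    "select_best",
]

#: canonical family order, also the final tie-break in model selection
FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic", "gompertz", "gengamma")

_EPS = 1e-300  # guards log(0) in censored likelihoods
_GG_Q_TOL = 1e-6  # |Q| below this: generalized gamma treated as its log-normal limit


class _FamilyDef:
    """Internal definition of one parametric family.

    ``positive`` marks parameters constrained to (0, inf); those are
    log-transformed during optimization so the search space is unconstrained.
    """

    def __init__(self, name, param_names, positive, sf, logpdf, isf, init):
        self.name = name
        self.param_names = param_names
        self.positive = positive
        self.sf = sf
        self.logpdf = logpdf
        self.isf = isf
        self.init = init

    @property
    def n_params(self):
        return len(self.param_names)


def _exp_sf(t, p):
    return np.exp(-p[0] * t)


def _exp_logpdf(t, p):
    return math.log(p[0]) - p[0] * t


def _wei_sf(t, p):
    return np.exp(-((t / p[1]) ** p[0]))


def _wei_logpdf(t, p):
    k, lam = p
    with np.errstate(divide="ignore"):
        logt = np.log(np.maximum(t, _EPS))
    return math.log(k) - k * math.log(lam) + (k - 1.0) * logt - (t / lam) ** k


def _lnorm_sf(t, p):
    mu, sigma = p
    with np.errstate(divide="ignore"):
        z = (np.log(np.maximum(t, _EPS)) - mu) / sigma
    return stats.norm.sf(z)


def _lnorm_logpdf(t, p):
    mu, sigma = p
    logt = np.log(np.maximum(t, _EPS))
    z = (logt - mu) / sigma
    return -logt - math.log(sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z


def _llog_sf(t, p):
    lam, gam = p
    return 1.0 / (1.0 + lam * t**gam)


def _llog_logpdf(t, p):
    lam, gam = p
    with np.errstate(divide="ignore"):
        logt = np.log(np.maximum(t, _EPS))
    return (
        math.log(lam)
        + math.log(gam)
        + (gam - 1.0) * logt
        - 2.0 * np.log1p(lam * t**gam)
    )


def _gomp_sf(t, p):
    a, b = p
    return np.exp(-(b / a) * np.expm1(a * t))


def _gomp_logpdf(t, p):
    a, b = p
    return math.log(b) + a * t - (b / a) * np.expm1(a * t)


def _gg_wq(t, p):
    mu, sigma, q = p
    with np.errstate(divide="ignore"):
        w = (np.log(np.maximum(t, _EPS)) - mu) / sigma
    return w, q


def _gg_sf(t, p):
    w, q = _gg_wq(t, p)
    if abs(q) < _GG_Q_TOL:
        return stats.norm.sf(w)
    q2 = 1.0 / (q * q)
    u = q2 * np.exp(np.clip(q * w, -700, 700))
    if q > 0:
        return special.gammaincc(q2, u)
    return special.gammainc(q2, u)


def _gg_logpdf(t, p):
    mu, sigma, q = p
    if abs(q) < _GG_Q_TOL:
        return _lnorm_logpdf(t, (mu, sigma))
    w, _ = _gg_wq(t, p)
    q2 = 1.0 / (q * q)
    logt = np.log(np.maximum(t, _EPS))
    qw = np.clip(q * w, -700, 700)
    return (
        math.log(abs(q))
        + q2 * math.log(q2)
        + q2 * qw
        - q2 * np.exp(qw)
        - math.log(sigma)
        - logt
        - special.gammaln(q2)
    )


def _exp_isf(prob, p):
    return -np.log(prob) / p[0]


def _wei_isf(prob, p):
    return p[1] * (-np.log(prob)) ** (1.0 / p[0])


def _lnorm_isf(prob, p):
    return np.exp(p[0] + p[1] * stats.norm.ppf(1.0 - np.asarray(prob, dtype=float)))


def _llog_isf(prob, p):
    prob = np.asarray(prob, dtype=float)
    return ((1.0 - prob) / (prob * p[0])) ** (1.0 / p[1])


def _gomp_isf(prob, p):
    a, b = p
    return np.log1p(-(a / b) * np.log(prob)) / a


def _gg_isf(prob, p):
    mu, sigma, q = p
    prob = np.asarray(prob, dtype=float)
    if abs(q) < _GG_Q_TOL:
        return np.exp(mu + sigma * stats.norm.ppf(1.0 - prob))
    q2 = 1.0 / (q * q)
    if q > 0:
        u = special.gammainccinv(q2, prob)
    else:
        u = special.gammaincinv(q2, prob)
    w = np.log(u / q2) / q
    return np.exp(mu + sigma * w)


# moment-based starting values from log event times (m = mean, s = sd, r = 1/mean t)
def _exp_init(m, s, r):
    return (r,)


def _wei_init(m, s, r):
    shape = (math.pi / math.sqrt(6.0)) / s
    return (shape, math.exp(m + 0.5772156649 / shape))


def _lnorm_init(m, s, r):
    return (m, s)


def _llog_init(m, s, r):
    gam = (math.pi / math.sqrt(3.0)) / s
    return (math.exp(-gam * m), gam)


def _gomp_init(m, s, r):
    return (0.05, r)


def _gg_init(m, s, r):
    return (m, s, 0.5)


_FAMILY_DEFS = {
    "exponential": _FamilyDef(
        "exponential", ("rate",), (True,), _exp_sf, _exp_logpdf, _exp_isf, _exp_init
    ),
    "weibull": _FamilyDef(
        "weibull", ("shape", "scale"), (True, True), _wei_sf, _wei_logpdf, _wei_isf, _wei_init
    ),
    "lognormal": _FamilyDef(
        "lognormal", ("mu", "sigma"), (False, True), _lnorm_sf, _lnorm_logpdf, _lnorm_isf, _lnorm_init
    ),
    "loglogistic": _FamilyDef(
        "loglogistic", ("lam", "gamma"), (True, True), _llog_sf, _llog_logpdf, _llog_isf, _llog_init
    ),
    "gompertz": _FamilyDef(
        "gompertz", ("shape", "rate"), (True, True), _gomp_sf, _gomp_logpdf, _gomp_isf, _gomp_init
    ),
    "gengamma": _FamilyDef(
        "gengamma", ("mu", "sigma", "Q"), (False, True, False), _gg_sf, _gg_logpdf, _gg_isf, _gg_init
    ),
}


@runtime_checkable
class SurvivalCurve(Protocol):
    """Anything that evaluates a survival function S(t) on t >= 0 (months)."""

    def sf(self, t): ...

    def isf(self, prob): ...

    def median(self) -> float: ...


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival distribution on a time axis of months.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : tuple of float
        Family-specific parameter vector (see module docstring).
    """

    family: str
    params: tuple

    def __post_init__(self):
        if self.family not in _FAMILY_DEFS:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        fd = _FAMILY_DEFS[self.family]
        params = tuple(float(v) for v in self.params)
        if len(params) != fd.n_params:
            raise ValueError(
                f"{self.family} expects {fd.n_params} parameters {fd.param_names}, got {len(params)}"
            )
        for name, value, pos in zip(fd.param_names, params, fd.positive):
            if not math.isfinite(value):
                raise ValueError(f"{self.family} parameter {name} must be finite")
            if pos and value <= 0:
                raise ValueError(f"{self.family} parameter {name} must be > 0, got {value}")
        if self.family == "gompertz" and params[0] <= 0:
            raise ValueError("gompertz shape must be > 0 for a proper distribution")
        object.__setattr__(self, "params", params)

    @property
    def _def(self) -> _FamilyDef:
        return _FAMILY_DEFS[self.family]

    @property
    def param_names(self):
        return self._def.param_names

    @property
    def n_params(self) -> int:
        return self._def.n_params

    def sf(self, t):
        """Survival probability S(t); accepts scalars or arrays, t >= 0."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("survival time t must be >= 0")
        out = np.where(t_arr == 0.0, 1.0, self._def.sf(np.maximum(t_arr, _EPS), self.params))
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    __call__ = sf

    def logpdf(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr <= 0):
            raise ValueError("density evaluated at t > 0 only")
        out = self._def.logpdf(t_arr, self.params)
        return float(out) if t_arr.ndim == 0 else out

    def hazard(self, t):
        """Hazard h(t) = f(t) / S(t)."""
        s = np.maximum(self.sf(t), _EPS)
        return np.exp(self.logpdf(t)) / s

    def isf(self, prob):
        """Time t at which S(t) = prob, for prob in (0, 1)."""
        prob_arr = np.asarray(prob, dtype=float)
        if np.any((prob_arr <= 0) | (prob_arr >= 1)):
            raise ValueError("prob must lie strictly in (0, 1)")
        out = self._def.isf(prob_arr, self.params)
        return float(out) if prob_arr.ndim == 0 else np.asarray(out, dtype=float)

    def median(self) -> float:
        return float(self.isf(0.5))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricSurvival":
        return cls(d["family"], tuple(d["params"]))


@dataclass(frozen=True)
class ProportionalHazardsCurve:
    """A reference curve with its cumulative hazard scaled by a hazard ratio.

    S(t) = S_ref(t) ** hr.  The result is generally not a member of the
    reference family (the exponential family is the notable exception).
    """

    reference: SurvivalCurve
    hr: float

    def __post_init__(self):
        if not (self.hr > 0 and math.isfinite(self.hr)):
            raise ValueError(f"hazard ratio must be a positive finite real, got {self.hr}")

    def sf(self, t):
        return self.reference.sf(t) ** self.hr

    __call__ = sf

    def isf(self, prob):
        prob_arr = np.asarray(prob, dtype=float)
        return self.reference.isf(prob_arr ** (1.0 / self.hr))

    def median(self) -> float:
        return float(self.isf(0.5))


@dataclass(frozen=True)
class HazardRatio:
    """A hazard ratio with its 95% confidence interval."""

    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (0 < self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"require 0 < ci_low <= mean <= ci_high, got "
                f"({self.ci_low}, {self.mean}, {self.ci_high})"
            )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a censored maximum-likelihood fit of one family."""

    model: ParametricSurvival
    loglik: float
    aic: float
    n_params: int
    converged: bool = True
    message: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.model.family,
                "params": list(self.model.params),
                "loglik": self.loglik,
                "aic": self.aic,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        model = ParametricSurvival(d["family"], tuple(d["params"]))
        return cls(model, d["loglik"], d["aic"], model.n_params)


def survival_at(model: SurvivalCurve, t) -> float:
    """S(t) for a curve object; thin functional wrapper."""
    return model.sf(t)


def median_survival(model: SurvivalCurve) -> float:
    """Median survival time in months (solves S(t) = 0.5)."""
    return model.median()


def apply_hazard_ratio(reference: SurvivalCurve, hr: float) -> ProportionalHazardsCurve:
    """Counterfactual curve under proportional hazards: t -> S_ref(t) ** hr."""
    return ProportionalHazardsCurve(reference, float(hr))


def _neg_loglik(theta, fd, times, events, positive):
    params = tuple(math.exp(v) if pos else v for v, pos in zip(theta, positive))
    try:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll = 0.0
            ev = events.astype(bool)
            if ev.any():
                ll += np.sum(fd.logpdf(times[ev], params))
            if (~ev).any():
                s = np.clip(fd.sf(times[~ev], params), _EPS, 1.0)
                ll += np.sum(np.log(s))
    except (OverflowError, FloatingPointError, ValueError):
        return 1e12
    if not np.isfinite(ll):
        return 1e12
    return -float(ll)


def fit_mle(
    times: Sequence[float],
    events: Sequence[int],
    family: str,
    n_restarts: int = 4,
) -> FitResult:
    """Fit one parametric family to right-censored data by maximum likelihood.

    Parameters
    ----------
    times : array-like of float
        Observation times in months (event or censoring), all >= 0.
    events : array-like of {0, 1}
        1 = event observed at ``times``, 0 = right-censored.
    family : str
        One of :data:`FAMILIES`.
    n_restarts : int
        Additional optimizer starts from dispersed initial points; the best
        (highest log-likelihood) converged solution is kept.

    Returns
    -------
    FitResult
        With ``converged=False`` and an explanatory message when no start
        converged; the log-likelihood is then ``-inf`` so a failed fit can
        never win model selection.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be matching 1-D arrays")
    if len(times) < 10:
        raise ValueError("need at least 10 observations to fit")
    if events.sum() < 1:
        raise ValueError("need at least one observed event")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    fd = _FAMILY_DEFS[family]  # KeyError -> caller passed a bad family name

    ev_times = times[events == 1]
    pos_times = ev_times[ev_times > 0]
    if len(pos_times) == 0:
        pos_times = times[times > 0]
    m = float(np.mean(np.log(pos_times)))
    s = max(float(np.std(np.log(pos_times))), 0.2)
    r = events.sum() / max(times.sum(), _EPS)
    x0 = fd.init(m, s, r)
    theta0 = np.array(
        [math.log(v) if pos else v for v, pos in zip(x0, fd.positive)], dtype=float
    )

    rng = np.random.default_rng(12345)  # fixed: restarts are deterministic
    starts = [theta0]
    for _ in range(n_restarts):
        starts.append(theta0 + rng.normal(scale=0.5, size=len(theta0)))

    best = None
    for theta_start in starts:
        res = optimize.minimize(
            _neg_loglik,
            theta_start,
            args=(fd, times, events, fd.positive),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            continue
        if best is None or res.fun < best.fun:
            best = res

    if best is None:
        placeholder = ParametricSurvival(family, x0)
        return FitResult(
            placeholder, -math.inf, math.inf, fd.n_params, converged=False,
            message="optimizer failed from every start",
        )

    params = tuple(
        math.exp(v) if pos else v for v, pos in zip(best.x, fd.positive)
    )
    loglik = -float(best.fun)
    aic = 2.0 * fd.n_params - 2.0 * loglik
    return FitResult(ParametricSurvival(family, params), loglik, aic, fd.n_params)


def fit_all_families(times, events, families=FAMILIES) -> list:
    """Fit every requested family; failed fits are kept (flagged), not dropped."""
    return [fit_mle(times, events, fam) for fam in families]


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Minimum-AIC fit.

    Ties are broken by fewer parameters, then by the fixed family order
    exponential < weibull < lognormal < loglogistic < gompertz < gengamma.
    Non-converged fits are excluded.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_best requires a non-empty list of fits")
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to select from")
    return min(
        usable,
        key=lambda f: (f.aic, f.n_params, FAMILIES.index(f.model.family)),
    )
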