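"""Parametric survival curves, censored maximum-likelihood fitting and
model selection.

Five families common in health-economic extrapolation are supported, in the
rate-style parameterisations used throughout decision modelling:

=============  =======================================  ==================
family         survival function S(t)                   parameter slots
=============  =======================================  ==================
exponential    exp(-lambda * t)                         scale=lambda (shape fixed at 1)
weibull        exp(-lambda * t**gamma)                  scale=lambda, shape=gamma
log-logistic   1 / (1 + (lambda*t)**gamma)              scale=lambda, shape=gamma
gompertz       exp((lambda/gamma) * (1 - e**(gamma*t))) scale=lambda, shape=gamma
log-normal     1 - Phi((ln t - mu) / sigma)             scale=mu, shape=sigma
=============  =======================================  ==================

For the log-normal family the ``scale`` slot holds the log-time location mu
(any real number) and the ``shape`` slot holds the spread sigma > 0; for all
other families both parameters must be strictly positive.

Fitting maximises the right-censored log-likelihood
``sum_events log f(t_i) + sum_censored log S(t_i)`` with a multi-start
Nelder-Mead search on log-transformed parameters, and families are compared
by AIC or BIC.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_LOG_EPS = 1e-300  # floor before taking logs of vanishing densities


class Family(str, enum.Enum):
    """Parametric survival families, in the documented tie-break order."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    LOG_LOGISTIC = "log-logistic"
    GOMPERTZ = "gompertz"
    LOG_NORMAL = "log-normal"


#: number of free parameters per family
N_PARAMS = {
    Family.EXPONENTIAL: 1,
    Family.WEIBULL: 2,
    Family.LOG_LOGISTIC: 2,
    Family.GOMPERTZ: 2,
    Family.LOG_NORMAL: 2,
}


@dataclass(frozen=True)
class SurvivalCurveParams:
    """A parametric survival curve.

    Parameters
    ----------
    family:
        One of the five supported families (a :class:`Family` or its string
        value).
    scale:
        lambda for the rate-style families; mu (log-time location) for the
        log-normal.
    shape:
        gamma for the two-parameter rate families; sigma for the log-normal;
        must equal 1.0 for the exponential.
    """

    family: Family
    scale: float
    shape: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if not (np.isfinite(self.scale) and np.isfinite(self.shape)):
            raise ValueError("survival parameters must be finite")
        if self.family is Family.LOG_NORMAL:
            if self.shape <= 0:
                raise ValueError("log-normal spread sigma must be > 0")
        else:
            if self.scale <= 0 or self.shape <= 0:
                raise ValueError(
                    f"{self.family.value} parameters must be > 0 "
                    f"(scale={self.scale}, shape={self.shape})"
                )
        if self.family is Family.EXPONENTIAL and self.shape != 1.0:
            raise ValueError("exponential family has shape fixed at 1")

    # -- survival quantities -------------------------------------------------

    def survival_at(self, t):
        """S(t) for scalar or array ``t >= 0`` (same time unit as the fit)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        lam, gam = self.scale, self.shape
        if self.family is Family.EXPONENTIAL:
            s = np.exp(-lam * t)
        elif self.family is Family.WEIBULL:
            s = np.exp(-lam * np.power(t, gam))
        elif self.family is Family.LOG_LOGISTIC:
            s = 1.0 / (1.0 + np.power(lam * t, gam))
        elif self.family is Family.GOMPERTZ:
            s = np.exp((lam / gam) * -np.expm1(gam * t))
        else:  # log-normal
            with np.errstate(divide="ignore"):
                z = (np.log(np.maximum(t, _LOG_EPS)) - lam) / gam
            s = np.where(t > 0, stats.norm.sf(z), 1.0)
        return s if s.ndim else float(s)

    def hazard_at(self, t):
        """Instantaneous hazard h(t) = f(t) / S(t)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        lam, gam = self.scale, self.shape
        if self.family is Family.EXPONENTIAL:
            h = np.full_like(t, lam)
        elif self.family is Family.WEIBULL:
            h = lam * gam * np.power(t, gam - 1.0)
        elif self.family is Family.LOG_LOGISTIC:
            u = np.power(lam * t, gam)
            h = lam * gam * np.power(lam * t, gam - 1.0) / (1.0 + u)
        elif self.family is Family.GOMPERTZ:
            h = lam * np.exp(gam * t)
        else:
            z = (np.log(t) - lam) / gam
            h = stats.norm.pdf(z) / (gam * t * stats.norm.sf(z))
        return h if h.ndim else float(h)

    def quantile(self, p):
        """Time t at which S(t) = ``p`` (inverse survival), p in (0, 1]."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("survival probability must lie in (0, 1]")
        lam, gam = self.scale, self.shape
        if self.family is Family.EXPONENTIAL:
            t = -np.log(p) / lam
        elif self.family is Family.WEIBULL:
            t = np.power(-np.log(p) / lam, 1.0 / gam)
        elif self.family is Family.LOG_LOGISTIC:
            t = np.power((1.0 - p) / p, 1.0 / gam) / lam
        elif self.family is Family.GOMPERTZ:
            t = np.log1p(-(gam / lam) * np.log(p)) / gam
        else:
            t = np.exp(lam + gam * stats.norm.isf(p))
        return t if t.ndim else float(t)

    @property
    def median(self) -> float:
        """Median survival time, ``(ln 2 / lambda)**(1/gamma)`` for Weibull."""
        return self.quantile(0.5)


@dataclass(frozen=True)
class CensoredObservation:
    """One subject's follow-up time and event indicator.

    ``event`` is True for an observed death/progression, False for
    right-censoring.
    """

    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be non-negative")


@dataclass(frozen=True)
class FitResult:
    """A fitted family with its likelihood and information criteria."""

    params: SurvivalCurveParams
    log_likelihood: float
    aic: float
    bic: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "family": self.params.family.value,
            "scale": self.params.scale,
            "shape": self.params.shape,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
        }


# -- likelihood ---------------------------------------------------------------


def _as_arrays(observations) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(observations, pd.DataFrame):
        times = observations["time_months"].to_numpy(float)
        events = observations["event"].to_numpy(bool)
    else:
        obs = list(observations)
        times = np.array([o.time for o in obs], dtype=float)
        events = np.array([o.event for o in obs], dtype=bool)
    return times, events


def log_likelihood(params: SurvivalCurveParams, times, events) -> float:
    """Right-censored log-likelihood at ``params``.

    Events contribute log f(t) = log h(t) + log S(t); censored observations
    contribute log S(t).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    t = np.maximum(times, _LOG_EPS)  # zero event times carry no density mass
    s = np.maximum(np.asarray(params.survival_at(t)), _LOG_EPS)
    ll = np.sum(np.log(s))
    if events.any():
        h = np.maximum(np.asarray(params.hazard_at(t[events])), _LOG_EPS)
        ll += np.sum(np.log(h))
    return float(ll)


def _starts(family: Family, times: np.ndarray, events: np.ndarray) -> list[np.ndarray]:
    """Fixed moment-informed multi-start points in the optimiser's coordinates."""
    d = max(int(events.sum()), 1)
    total = max(float(times.sum()), _LOG_EPS)
    rate = d / total  # exponential MLE
    if family is Family.LOG_NORMAL:
        lt = np.log(np.maximum(times[events], 1e-6))
        mu0 = float(np.mean(lt)) if lt.size else 0.0
        sig0 = float(np.std(lt)) if lt.size > 1 else 1.0
        sig0 = max(sig0, 0.1)
        return [np.array([mu0, math.log(sig0)]),
                np.array([mu0 + 0.5, math.log(sig0 * 1.5)]),
                np.array([mu0 - 0.5, math.log(max(sig0 * 0.6, 0.05))])]
    starts = []
    for gam in (1.0, 0.7, 1.5):
        if family is Family.GOMPERTZ:
            starts.append(np.array([math.log(rate), math.log(0.05 * gam)]))
        else:
            lam = d / max(float(np.sum(times**gam)), _LOG_EPS)
            starts.append(np.array([math.log(lam), math.log(gam)]))
    return starts


def _decode(family: Family, theta: np.ndarray) -> SurvivalCurveParams:
    if family is Family.EXPONENTIAL:
        return SurvivalCurveParams(family, math.exp(theta[0]))
    if family is Family.LOG_NORMAL:
        return SurvivalCurveParams(family, theta[0], math.exp(theta[1]))
    return SurvivalCurveParams(family, math.exp(theta[0]), math.exp(theta[1]))


def fit_censored(observations, family: Family | str, n_starts: int = 3) -> FitResult:
    """Maximum-likelihood fit of one family to right-censored observations.

    Parameters
    ----------
    observations:
        Sequence of :class:`CensoredObservation` or a DataFrame with columns
        ``time_months`` and ``event``.
    family:
        Family to fit.
    n_starts:
        How many of the fixed starting points to try (guards against local
        optima on the log-parameter surface).

    Raises
    ------
    ValueError
        On all-censored input (the likelihood is unbounded/unidentifiable)
        or fewer than two observations.
    RuntimeError
        If no start converges, with the optimiser diagnostics attached.
    """
    family = Family(family)
    times, events = _as_arrays(observations)
    n = times.size
    if n < 2:
        raise ValueError("need at least two observations to fit")
    if not events.any():
        raise ValueError("all observations censored: likelihood unidentifiable")

    def nll(theta: np.ndarray) -> float:
        try:
            params = _decode(family, theta)
        except (ValueError, OverflowError):
            return np.inf
        ll = log_likelihood(params, times, events)
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    diagnostics = []
    for theta0 in _starts(family, times, events)[:n_starts]:
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        diagnostics.append(res.message)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"{family.value} fit did not converge: {diagnostics}")

    params = _decode(family, best.x)
    ll = -best.fun
    k = N_PARAMS[family]
    return FitResult(
        params=params,
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        bic=k * math.log(n) - 2 * ll,
        n_obs=n,
    )


def fit_all_families(observations, families: Sequence[Family] | None = None) -> list[FitResult]:
    """Fit every requested family (default: all five), skipping failures."""
    results = []
    for fam in families or list(Family):
        try:
            results.append(fit_censored(observations, fam))
        except (ValueError, RuntimeError) as exc:  # pragma: no cover - rare
            logger.warning("fit of %s failed: %s", Family(fam).value, exc)
    if not results:
        raise RuntimeError("no family could be fitted")
    return results


_FAMILY_ORDER = {fam: i for i, fam in enumerate(Family)}


def select_family(fits: Iterable[FitResult], criterion: str = "aic") -> FitResult:
    """Pick the fit minimising AIC or BIC.

    Exact ties are broken deterministically by the family enum order
    (exponential, weibull, log-logistic, gompertz, log-normal).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_family needs a non-empty list of fits")
    if criterion not in ("aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    return min(fits, key=lambda f: (getattr(f, criterion), _FAMILY_ORDER[f.params.family]))


# -- transition probabilities -------------------------------------------------


def cycle_transition_prob(curve, cycle_index: int, cycle_length: float) -> float:
    """Per-cycle exit probability ``p_k = 1 - S(k c) / S((k-1) c)``.

    ``curve`` is anything exposing ``survival_at``; ``cycle_length`` is in the
    curve's own time unit.  Returns 1 (with a warning) once the conditioning
    survival has numerically vanished: the cohort is effectively absorbed.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be > 0")
    s_prev = curve.survival_at((cycle_index - 1) * cycle_length)
    if s_prev <= 0.0:
        logger.warning("survival numerically zero at cycle %d; cohort absorbed", cycle_index)
        return 1.0
    p = 1.0 - curve.survival_at(cycle_index * cycle_length) / s_prev
    return float(min(max(p, 0.0), 1.0))


# -- external interfaces ------------------------------------------------------


def read_ipd(path: str | Path) -> pd.DataFrame:
    """Read pseudo individual-patient data (CSV, ``time_months,event``)."""
    df = pd.read_csv(path)
    missing = {"time_months", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"pseudo-IPD file missing columns: {sorted(missing)}")
    return df


def write_ipd(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=["time_months", "event"])


def write_fit_report(fits: Sequence[FitResult], path: str | Path,
                     selected: FitResult | None = None) -> None:
    """JSON report of all fitted families, flagging the selected one."""
    payload = {
        "fits": [f.to_dict() for f in fits],
        "selected": selected.to_dict() if selected is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
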