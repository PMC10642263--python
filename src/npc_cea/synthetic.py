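"""Synthetic censored time-to-event data and curve reconstruction.

Published survival evidence for this comparison exists only as printed
Kaplan-Meier figures, which modellers digitise and convert back into pseudo
individual-patient data before refitting parametric curves.  This module
emulates that pipeline end to end so the fitting stage is testable without
any external data:

1. :func:`simulate_ipd` draws event times from a parametric curve by
   inverse-CDF sampling and applies administrative censoring with a uniform
   accrual offset (a staggered-entry trial closed at a data cut-off);
2. :func:`km_estimator` computes the product-limit estimate;
3. :func:`digitize_emulate` samples the step curve on a grid with truncated
   jitter, the imprecision a graph digitiser introduces;
4. :func:`reconstruct_ipd` allocates event and censoring counts per
   interval so the reconstructed data's Kaplan-Meier tracks the digitised
   coordinates (a simplified interval-allocation variant of the standard
   reconstruction algorithm, without numbers-at-risk refinement).

Defaults mirror the source trial's scale: 263 patients per arm with a
24-month administrative cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

DEFAULT_N = 263
DEFAULT_CENSOR_MONTHS = 24.0


def simulate_ipd(params, n: int = DEFAULT_N,
                 censor_time: Optional[float] = DEFAULT_CENSOR_MONTHS,
                 accrual_window: float = 0.0,
                 seed=None) -> pd.DataFrame:
    """Draw censored pseudo individual-patient data from a survival curve.

    Event times come from the curve's inverse CDF; each subject's follow-up
    is administratively limited to ``censor_time`` minus a uniform entry
    offset in ``[0, accrual_window]``.  ``censor_time=None`` observes every
    event.  Returns a DataFrame with columns ``time_months`` (float) and
    ``event`` (0/1), reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    u = np.clip(rng.uniform(size=n), 1e-12, 1.0)
    times = np.asarray(params.quantile(u), dtype=float)
    if censor_time is None:
        return pd.DataFrame({"time_months": times, "event": np.ones(n, dtype=int)})
    if censor_time < 0 or accrual_window < 0:
        raise ValueError("censor_time and accrual_window must be >= 0")
    offsets = rng.uniform(0.0, accrual_window, size=n) if accrual_window > 0 else 0.0
    follow_up = np.maximum(censor_time - offsets, 0.0)
    event = times <= follow_up
    observed = np.where(event, times, follow_up)
    return pd.DataFrame({"time_months": observed, "event": event.astype(int)})


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier step function with at-risk counts."""

    times: np.ndarray       # event/censoring times, ascending, starting at 0
    survival: np.ndarray    # S(t) immediately after each time
    n_at_risk: np.ndarray
    variance: np.ndarray    # Greenwood variance of S(t)

    def survival_at(self, t):
        """Right-continuous step-function evaluation."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        s = self.survival[np.clip(idx, 0, len(self.survival) - 1)]
        return s if np.ndim(t) else float(s)


def km_estimator(observations) -> KMCurve:
    """Product-limit survival estimate with Greenwood variance."""
    if isinstance(observations, pd.DataFrame):
        times = observations["time_months"].to_numpy(float)
        events = observations["event"].to_numpy(bool)
    else:
        obs = list(observations)
        times = np.array([o.time for o in obs], dtype=float)
        events = np.array([o.event for o in obs], dtype=bool)
    if not events.any():
        raise ValueError("Kaplan-Meier estimate needs at least one event")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    # lifelines reports the at-risk count at each distinct time
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(float)
    # Greenwood: Var(S) = S^2 * sum d / (n (n - d))
    table = kmf.event_table
    d = table["observed"].to_numpy(float)
    n_r = table["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_r > d, d / (n_r * (n_r - d)), 0.0)
    var = surv**2 * np.cumsum(terms)
    return KMCurve(times=grid, survival=surv, n_at_risk=at_risk, variance=var)


def digitize_emulate(km: KMCurve, grid, jitter_sd: float = 0.0,
                     seed=None) -> pd.DataFrame:
    """Sample a KM curve on a grid with digitiser-style imprecision.

    Adds truncated (clipped at two SDs) Gaussian jitter, clamps to [0, 1]
    and re-monotonises by a running minimum, so the output is always a
    valid survival curve.  ``jitter_sd=0`` returns the exact step-function
    values.  Columns: ``time_months, survival``.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 2:
        raise ValueError("digitisation grid needs at least two points")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    values = np.asarray(km.survival_at(grid), dtype=float)
    if jitter_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        noise = np.clip(rng.normal(0.0, jitter_sd, size=grid.size),
                        -2 * jitter_sd, 2 * jitter_sd)
        values = values + noise
    values = np.clip(values, 0.0, 1.0)
    values = np.minimum.accumulate(values)
    return pd.DataFrame({"time_months": grid, "survival": values})


def reconstruct_ipd(coordinates: pd.DataFrame, n_total: int,
                    censor_time: Optional[float] = None) -> pd.DataFrame:
    """Rebuild pseudo individual-patient data from digitised coordinates.

    Event counts are allocated per interval from the drop in survival
    relative to the cohort still at risk, tracking rounded alive counts so
    the reconstructed Kaplan-Meier follows the input curve; patients alive
    past the last coordinate are censored there (or at ``censor_time``).
    Input must be non-increasing in survival starting from (about) 1.

    This deliberately omits the numbers-at-risk refinement of the full
    published reconstruction algorithm: without risk tables, within-interval
    censoring cannot be located, so all censoring is placed at the end of
    follow-up.
    """
    t = coordinates["time_months"].to_numpy(float)
    s = coordinates["survival"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("coordinate times must be strictly increasing")
    if np.any(np.diff(s) > 1e-12) or np.any(s < 0) or np.any(s > 1):
        raise ValueError("survival coordinates must be non-increasing in [0, 1]")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")

    alive = int(n_total)
    times, events = [], []
    for tj, sj in zip(t, s):
        target_alive = int(round(n_total * sj))
        d = alive - target_alive
        if d > 0:
            times.extend([tj] * d)
            events.extend([1] * d)
            alive = target_alive
    end = censor_time if censor_time is not None else t[-1]
    if alive > 0:
        times.extend([end] * alive)
        events.extend([0] * alive)
    return pd.DataFrame({"time_months": np.asarray(times, dtype=float),
                         "event": np.asarray(events, dtype=int)})
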