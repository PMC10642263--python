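"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the base case with each uncertain parameter set to
its low and high bound in turn and ranks parameters by the span of the
resulting ICERs.  Probabilistic analysis draws every parameter at once from
its assigned family — gamma for costs, beta for probabilities and
utilities, uniform for the discount rate — with moments matched to the mean
and an SD derived from the one-way range, re-runs the model per draw (the
survival curves stay at their fitted values: the published table assigns
them no distribution), and summarises the fraction of draws that are
cost-effective at a willingness-to-pay threshold, traced out over a WTP
grid as the cost-effectiveness acceptability curve.

Draws for parameters logically common to the two strategies (utilities,
unit costs, the discount rate) are shared within an iteration; arm-specific
parameters (adverse-event risks, post-discontinuation rates, disutilities)
are drawn independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import economics
from .config import Config, ParameterRef, build_model, parameter_specs
from .markov import run_totals

logger = logging.getLogger(__name__)

#: keep the published name for the flattened uncertain-parameter handle
ParameterSpec = ParameterRef


def _base_comparison(config: Config,
                     overrides: Mapping[str, float] | None = None
                     ) -> economics.CEAComparison:
    tc, chemo, settings = build_model(config, overrides)
    return economics.compare(run_totals(tc, settings), run_totals(chemo, settings),
                             settings.wtp, tc.name, chemo.name)


# -- one-way (tornado) --------------------------------------------------------


def owsa(config: Config,
         parameters: Sequence[ParameterRef] | None = None) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis.

    Returns a tornado table with columns ``parameter, low_value, high_value,
    icer_low, icer_high, span``, sorted by descending span (alphabetical
    tie-break).  A perturbation that makes the QALY gain non-positive leaves
    a NaN ICER and is excluded from the span ordering with a warning.
    """
    params = list(parameters) if parameters is not None else parameter_specs(config)
    base = _base_comparison(config)
    rows = []
    for ref in params:
        icers = {}
        for bound, value in (("low", ref.low), ("high", ref.high)):
            cmp_ = _base_comparison(config, {ref.name: value})
            if cmp_.delta_qaly <= 0:
                logger.warning("owsa: %s at %s makes dQALY <= 0; ICER undefined",
                               ref.name, bound)
                icers[bound] = math.nan
            else:
                icers[bound] = cmp_.icer_per_qaly
        span = (abs(icers["high"] - icers["low"])
                if all(map(math.isfinite, icers.values())) else math.nan)
        rows.append({"parameter": ref.name, "low_value": ref.low,
                     "high_value": ref.high, "icer_low": icers["low"],
                     "icer_high": icers["high"], "span": span})
    table = pd.DataFrame(rows)
    table["base_icer"] = base.icer_per_qaly
    finite = table["span"].notna()
    table = pd.concat([
        table[finite].sort_values(["span", "parameter"],
                                  ascending=[False, True]),
        table[~finite],
    ]).reset_index(drop=True)
    return table


# -- probabilistic ------------------------------------------------------------


def _moment_matched_draw(ref: ParameterRef, sd_divisor: float,
                         rng: np.random.Generator, size: int) -> np.ndarray:
    """One vector of draws for a parameter, by method of moments.

    Beta and gamma shapes come from (mean = base, SD = (high - low) /
    sd_divisor).  Degenerate ranges return the base; an infeasible beta
    moment match (variance at or beyond the Bernoulli bound) falls back to
    uniform on [low, high] with a warning.
    """
    mean, lo, hi = ref.base, ref.low, ref.high
    if ref.distribution == "fixed" or hi == lo:
        return np.full(size, mean)
    if ref.distribution == "uniform":
        return rng.uniform(lo, hi, size)
    sd = (hi - lo) / sd_divisor
    var = sd * sd
    if ref.distribution == "beta":
        if var >= mean * (1.0 - mean) or mean <= 0.0 or mean >= 1.0:
            logger.warning("beta moment match infeasible for %s; "
                           "falling back to uniform", ref.name)
            return rng.uniform(lo, hi, size)
        nu = mean * (1.0 - mean) / var - 1.0
        return rng.beta(mean * nu, (1.0 - mean) * nu, size)
    if ref.distribution == "gamma":
        if mean <= 0:
            return np.full(size, mean)
        shape = (mean / sd) ** 2
        return rng.gamma(shape, var / mean, size)
    raise ValueError(f"unknown distribution {ref.distribution!r}")


def sample_parameters(specs: Sequence[ParameterRef], seed_or_rng,
                      size: int = 1, sd_divisor: float = 3.92
                      ) -> Dict[str, np.ndarray]:
    """Sample all parameters at once; reproducible for a fixed seed.

    Returns a mapping name -> array of ``size`` draws.  Draw order follows
    the order of ``specs``, so identical seeds give identical parameter maps.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return {ref.name: _moment_matched_draw(ref, sd_divisor, rng, size)
            for ref in specs}


@dataclass(frozen=True)
class PSAResult:
    """All iterations of a probabilistic sensitivity analysis."""

    iterations: pd.DataFrame  # iter, cost/qaly per arm, delta_cost, delta_qaly
    wtp: float

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        w = self.wtp if wtp is None else wtp
        nmb = w * self.iterations["delta_qaly"] - self.iterations["delta_cost"]
        return float((nmb > 0).mean())

    def ce_plane(self) -> pd.DataFrame:
        return self.iterations[["iter", "delta_cost", "delta_qaly"]]


def run_psa(config: Config, n_iter: int | None = None,
            seed: int | None = None) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Each iteration redraws every uncertain parameter and re-runs both arms
    over the full horizon (vectorised across iterations).  Deterministic for
    a fixed seed.
    """
    n = config.psa.n_iterations if n_iter is None else n_iter
    if n < 1:
        raise ValueError("n_iter must be >= 1")
    specs = parameter_specs(config)
    draws = sample_parameters(specs, seed, size=n,
                              sd_divisor=config.psa.sd_divisor)
    tc, chemo, settings = build_model(config, draws)
    tot_tc = run_totals(tc, settings)
    tot_chemo = run_totals(chemo, settings)
    frame = pd.DataFrame({
        "iter": np.arange(n),
        "cost_intervention": np.broadcast_to(tot_tc.cost, (n,)),
        "qaly_intervention": np.broadcast_to(tot_tc.qaly, (n,)),
        "cost_comparator": np.broadcast_to(tot_chemo.cost, (n,)),
        "qaly_comparator": np.broadcast_to(tot_chemo.qaly, (n,)),
    })
    frame["delta_cost"] = frame["cost_intervention"] - frame["cost_comparator"]
    frame["delta_qaly"] = frame["qaly_intervention"] - frame["qaly_comparator"]
    return PSAResult(iterations=frame, wtp=settings.wtp)


def ceac(psa: PSAResult | pd.DataFrame,
         wtp_grid: Iterable[float] | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    The probability at each threshold is the fraction of iterations with a
    strictly positive incremental net monetary benefit.  The default grid
    spans zero to twice the configured threshold in 100 steps.
    """
    frame = psa.iterations if isinstance(psa, PSAResult) else psa
    if frame.empty:
        raise ValueError("ceac needs at least one PSA iteration")
    if wtp_grid is None:
        top = 2.0 * (psa.wtp if isinstance(psa, PSAResult) else 36289.0)
        wtp_grid = np.linspace(0.0, top, 101)
    dq = frame["delta_qaly"].to_numpy()
    dc = frame["delta_cost"].to_numpy()
    rows = [(float(w), float(np.mean(w * dq - dc > 0))) for w in wtp_grid]
    return pd.DataFrame(rows, columns=["wtp", "probability"])
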