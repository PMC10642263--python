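"""Three-state Markov cohort engine (PFS -> PD -> Death).

The whole cohort starts progression-free.  Each 6-week cycle a patient may
progress or die; Death is absorbing and no backwards transition exists.  The
death probability is taken from the overall-survival curve and applied
identically from PFS and PD (the standard construction when only the two
marginal curves are published); the PFS-exit probability comes from the PFS
curve and the progression probability is their difference, clamped at zero.

Costs, life-years and QALYs accrue per cycle on the occupancy at the chosen
accrual point (start of cycle by default, matching the "beginning of stage"
reward convention of cohort-simulation software; end-of-cycle and half-cycle
corrected accrual are available), discounted continuously in cycles at the
annual rate.  Death (terminal-care) costs attach to the cycle in which the
deaths occur, discounted at the end of that cycle.

Scalar parameters give a :class:`CohortTrace`; cost and utility parameters
may also be numpy arrays of draws, in which case :func:`run_totals`
broadcasts the whole cohort simulation across the draw dimension (the fast
path used by the probabilistic sensitivity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, NamedTuple, Tuple

import numpy as np
import pandas as pd

from .survival import cycle_transition_prob

logger = logging.getLogger(__name__)

#: 6 weeks expressed in average months (42 days / 30.4375 days per month)
SIX_WEEKS_MONTHS = 42.0 / 30.4375

#: 10-year horizon in 6-week cycles: round(10 * 365.25 / 42)
DEFAULT_N_CYCLES = 87


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings.

    ``survival_time_unit`` says in what unit the fitted survival curves
    measure time: ``"cycles"`` evaluates S at the cycle count k (the unit in
    which the shipped curve parameters reproduce the published cohort
    results), ``"months"`` at k times the cycle length in months.
    Discounting always runs on calendar months regardless.
    """

    cycle_length_months: float = SIX_WEEKS_MONTHS
    n_cycles: int = DEFAULT_N_CYCLES
    discount_rate_annual: float | np.ndarray = 0.05
    wtp: float = 36289.0
    accrual: Literal["start", "end", "half"] = "start"
    survival_time_unit: Literal["cycles", "months"] = "cycles"

    def __post_init__(self) -> None:
        if self.cycle_length_months <= 0:
            raise ValueError("cycle_length_months must be > 0")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        r = np.asarray(self.discount_rate_annual)
        if np.any(r < 0) or np.any(r > 0.08):
            raise ValueError("discount_rate_annual must lie in [0, 0.08]")
        if self.wtp <= 0:
            raise ValueError("wtp must be > 0")
        if self.accrual not in ("start", "end", "half"):
            raise ValueError(f"unknown accrual convention {self.accrual!r}")
        if self.survival_time_unit not in ("cycles", "months"):
            raise ValueError(f"unknown survival_time_unit {self.survival_time_unit!r}")

    @property
    def half_cycle_correction(self) -> bool:
        return self.accrual == "half"

    @property
    def horizon_months(self) -> float:
        return self.n_cycles * self.cycle_length_months

    @property
    def curve_cycle_length(self) -> float:
        """Cycle length in the survival curves' own time unit."""
        return 1.0 if self.survival_time_unit == "cycles" else self.cycle_length_months


class ArmTotals(NamedTuple):
    """Discounted totals for one strategy over the horizon."""

    cost: float | np.ndarray
    ly: float | np.ndarray
    qaly: float | np.ndarray


@dataclass(frozen=True)
class ArmSpec:
    """One treatment strategy: curves, costs, adverse events and utilities.

    Drug costs are per administration; ``drug_doses_per_model_cycle`` converts
    3-weekly dosing onto the 6-week model cycle.  Drugs listed in
    ``chemo_drugs`` stop after ``chemo_duration_cycles`` model cycles; other
    drugs run while the patient remains progression-free (treatment until
    progression).  Routine costs attach to the states named in
    ``routine_states``.  Second-line therapy in the progressed state is
    weighted by the arm's post-discontinuation therapy rate.  Adverse-event
    management costs and the AE disutility are one-time hits to the whole
    cohort at model entry.
    """

    name: str
    pfs_curve: object
    os_curve: object
    drug_costs_per_cycle: Mapping[str, float] = field(default_factory=dict)
    drug_doses_per_model_cycle: Mapping[str, float] = field(default_factory=dict)
    chemo_drugs: Tuple[str, ...] = ()
    chemo_duration_cycles: int = 2
    routine_costs_per_cycle: Mapping[str, float] = field(default_factory=dict)
    routine_states: Tuple[str, ...] = ("pfs", "pd")
    bsc_cost_per_cycle: float = 0.0
    second_line_cost_per_cycle: float = 0.0
    second_line_doses_per_model_cycle: float = 1.0
    post_discontinuation_rate: float | np.ndarray = 0.0
    terminal_care_cost: float = 0.0
    ae_profile: Tuple[Tuple[str, float, float], ...] = ()
    utility_pfs: float | np.ndarray = 1.0
    utility_pd: float | np.ndarray = 1.0
    ae_disutility_onetime: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        for label, value in (("post_discontinuation_rate", self.post_discontinuation_rate),
                             ("utility_pfs", self.utility_pfs),
                             ("utility_pd", self.utility_pd)):
            v = np.asarray(value)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{label} must lie in [0, 1]")
        for name, risk, cost in self.ae_profile:
            if not 0 <= float(np.min(np.asarray(risk))):
                raise ValueError(f"AE risk for {name} must be >= 0")
            if np.any(np.asarray(risk) > 1):
                raise ValueError(f"AE risk for {name} must be <= 1")
            if np.any(np.asarray(cost) < 0):
                raise ValueError(f"AE cost for {name} must be >= 0")
        if self.chemo_duration_cycles < 0:
            raise ValueError("chemo_duration_cycles must be >= 0")

    # -- per-cycle cost building blocks --------------------------------------

    @property
    def ae_onetime_cost(self):
        """Expected one-time AE management cost: sum of risk_i * cost_i."""
        total = 0.0
        for _, risk, cost in self.ae_profile:
            total = total + np.asarray(risk, float) * np.asarray(cost, float)
        return total

    @property
    def routine_cost(self):
        total = 0.0
        for cost in self.routine_costs_per_cycle.values():
            total = total + np.asarray(cost, float)
        return total

    def pfs_cost(self, cycle_index: int):
        """Cost per model cycle borne by a progression-free patient."""
        total = 0.0
        for drug, cost in self.drug_costs_per_cycle.items():
            if drug in self.chemo_drugs and cycle_index > self.chemo_duration_cycles:
                continue
            doses = self.drug_doses_per_model_cycle.get(drug, 1.0)
            total = total + doses * np.asarray(cost, float)
        if "pfs" in self.routine_states:
            total = total + self.routine_cost
        return total

    def pd_cost(self):
        """Cost per model cycle borne by a progressed patient."""
        total = (np.asarray(self.bsc_cost_per_cycle, float)
                 + self.second_line_doses_per_model_cycle
                 * np.asarray(self.second_line_cost_per_cycle, float)
                 * np.asarray(self.post_discontinuation_rate, float))
        if "pd" in self.routine_states:
            total = total + self.routine_cost
        return total


def transition_probs(arm: ArmSpec, cycle_index: int, settings: ModelSettings
                     ) -> tuple[float, float]:
    """Per-cycle (PFS-exit, death) probabilities from the two marginal curves."""
    c = settings.curve_cycle_length
    p_exit = cycle_transition_prob(arm.pfs_curve, cycle_index, c)
    p_death = cycle_transition_prob(arm.os_curve, cycle_index, c)
    return p_exit, p_death


@dataclass
class CohortTrace:
    """Per-cycle state occupancies and discounted accruals for one arm.

    Occupancies are measured at the end of each cycle and always sum to one;
    the accrual columns already include the one-time adverse-event cost and
    disutility (attached to cycle 1).
    """

    frame: pd.DataFrame

    COLUMNS = ("cycle", "t_months", "pfs", "pd", "death", "new_deaths",
               "disc_cost", "disc_ly", "disc_qaly")

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def totals(self) -> ArmTotals:
        f = self.frame
        return ArmTotals(float(f["disc_cost"].sum()),
                         float(f["disc_ly"].sum()),
                         float(f["disc_qaly"].sum()))


def _monthly_discount(settings: ModelSettings):
    r = np.asarray(settings.discount_rate_annual, float)

    def disc(t_months):
        return (1.0 + r) ** (-(t_months / 12.0))

    return disc


def run_cohort(arm: ArmSpec, settings: ModelSettings) -> CohortTrace:
    """Run the cohort for one arm and return the full per-cycle trace.

    Scalar parameters only; see :func:`run_totals` for the broadcasting path.
    """
    c = settings.cycle_length_months
    disc = _monthly_discount(settings)
    rows = []
    pfs, pd_ = 1.0, 0.0
    for k in range(1, settings.n_cycles + 1):
        p_exit, p_death = transition_probs(arm, k, settings)
        p_prog = p_exit - p_death
        if p_prog < 0:
            logger.debug("cycle %d: death prob exceeds PFS-exit prob; clamping", k)
            p_prog = 0.0
        pfs0, pd0 = pfs, pd_
        new_deaths = (pfs0 + pd0) * p_death
        pfs = pfs0 * max(1.0 - p_death - p_prog, 0.0)
        pd_ = pd0 * (1.0 - p_death) + pfs0 * p_prog

        if settings.accrual == "start":
            o_pfs, o_pd, t_acc = pfs0, pd0, (k - 1) * c
        elif settings.accrual == "end":
            o_pfs, o_pd, t_acc = pfs, pd_, k * c
        else:
            o_pfs, o_pd, t_acc = (pfs0 + pfs) / 2, (pd0 + pd_) / 2, (k - 0.5) * c

        d_acc, d_end = disc(t_acc), disc(k * c)
        cost = d_acc * (o_pfs * arm.pfs_cost(k) + o_pd * arm.pd_cost())
        cost += d_end * new_deaths * arm.terminal_care_cost
        ly = (o_pfs + o_pd) * c / 12.0 * d_acc
        qaly = (o_pfs * arm.utility_pfs + o_pd * arm.utility_pd) * c / 12.0 * d_acc
        if k == 1:  # one-time AE cost and disutility at model entry
            cost += arm.ae_onetime_cost
            qaly -= arm.ae_disutility_onetime
        rows.append((k, k * c, pfs, pd_, 1.0 - pfs - pd_, new_deaths,
                     float(cost), float(ly), float(qaly)))
    frame = pd.DataFrame(rows, columns=list(CohortTrace.COLUMNS))
    return CohortTrace(frame)


def accrue_totals(trace: CohortTrace, arm: ArmSpec | None = None,
                  settings: ModelSettings | None = None) -> ArmTotals:
    """Total discounted cost, life-years and QALYs from a cohort trace."""
    return trace.totals


def run_totals(arm: ArmSpec, settings: ModelSettings) -> ArmTotals:
    """Discounted totals without building a trace.

    Cost, utility and discount parameters may be numpy arrays of identical
    length; the cohort recursion then broadcasts across the draw axis.
    """
    c = settings.cycle_length_months
    disc = _monthly_discount(settings)
    pfs, pd_ = 1.0, 0.0
    cost = np.asarray(arm.ae_onetime_cost, float) + 0.0
    qaly = -np.asarray(arm.ae_disutility_onetime, float) + 0.0
    ly = 0.0
    if settings.n_cycles == 0:
        return ArmTotals(0.0, 0.0, 0.0)
    pd_cost = arm.pd_cost()
    for k in range(1, settings.n_cycles + 1):
        p_exit, p_death = transition_probs(arm, k, settings)
        p_prog = max(p_exit - p_death, 0.0)
        pfs0, pd0 = pfs, pd_
        new_deaths = (pfs0 + pd0) * p_death
        pfs = pfs0 * max(1.0 - p_death - p_prog, 0.0)
        pd_ = pd0 * (1.0 - p_death) + pfs0 * p_prog
        if settings.accrual == "start":
            o_pfs, o_pd, t_acc = pfs0, pd0, (k - 1) * c
        elif settings.accrual == "end":
            o_pfs, o_pd, t_acc = pfs, pd_, k * c
        else:
            o_pfs, o_pd, t_acc = (pfs0 + pfs) / 2, (pd0 + pd_) / 2, (k - 0.5) * c
        d_acc, d_end = disc(t_acc), disc(k * c)
        cost = cost + d_acc * (o_pfs * arm.pfs_cost(k) + o_pd * pd_cost) \
                    + d_end * new_deaths * arm.terminal_care_cost
        ly = ly + (o_pfs + o_pd) * c / 12.0 * d_acc
        qaly = qaly + (o_pfs * arm.utility_pfs + o_pd * arm.utility_pd) * c / 12.0 * d_acc
    squeeze = lambda x: float(x) if np.ndim(x) == 0 else x
    return ArmTotals(squeeze(cost), squeeze(ly), squeeze(qaly))
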