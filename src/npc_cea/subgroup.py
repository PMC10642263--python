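"""Subgroup cost-effectiveness via hazard-ratio modulation.

The trial's forest plot reports only PFS hazard ratios per subgroup, while
a full cohort model needs four curves.  Under proportional hazards an HR
raises a baseline survival function to a power, ``S_adj(t) = S(t)**hr`` —
for a Weibull (and exponential, and Gompertz) baseline this is exactly a
rescaling of the scale parameter with the shape unchanged.

How the single published PFS HR propagates to the intervention arm's OS
curve is not identified by the published inputs, so the coupling is a
strategy knob:

``os-inverse`` (default)
    TC PFS = chemo PFS ** hr; TC OS = chemo OS ** (H * (0.52 / hr)) where H
    is the overall OS hazard ratio implied by the two fitted OS curves at
    the comparator's median and 0.52 the overall trial PFS HR.  This is the
    only coupling of the three that reproduces the published subgroup
    ordering (larger PFS HR, smaller ICER) and its net-health-benefit
    levels.
``os-coupled``
    TC OS = chemo OS ** (H * (hr / 0.52)): OS benefit scales with the PFS
    benefit.  Yields the opposite ICER ordering.
``pfs-only``
    Only the TC PFS curve is rebuilt; both OS curves stay at base case.

Subgroups whose trial stratum was too small for the published analysis
(``pfs_hr_ci`` straddling very wide bounds, marked here by ``skip=True``)
are carried in the roster but excluded from computation, as published.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import economics
from .config import CHEMO_ARM, TC_ARM, Config, build_model
from .markov import run_totals
from .survival import Family, SurvivalCurveParams

#: overall trial PFS hazard ratio, combination vs chemotherapy
OVERALL_PFS_HR = 0.52

Strategy = Literal["os-inverse", "os-coupled", "pfs-only"]


@dataclass(frozen=True)
class SubgroupSpec:
    """One trial subgroup: label and its PFS hazard ratio with 95% CI."""

    label: str
    pfs_hr: float
    pfs_hr_ci: Tuple[float, float] = (float("nan"), float("nan"))
    os_hr: Optional[float] = None  # used directly when the trial reports one
    skip: bool = False  # stratum too small; excluded as published

    def __post_init__(self) -> None:
        if self.pfs_hr <= 0:
            raise ValueError("pfs_hr must be > 0")
        lo, hi = self.pfs_hr_ci
        if np.isfinite(lo) and np.isfinite(hi) and not lo <= self.pfs_hr <= hi:
            raise ValueError("pfs_hr must lie inside its confidence interval")


#: trial subgroup roster (PFS HRs from the randomised comparison)
TRIAL_SUBGROUPS: Tuple[SubgroupSpec, ...] = (
    SubgroupSpec("age_lt_65", 0.45, (0.33, 0.62)),
    SubgroupSpec("age_ge_65", 1.91, (0.73, 5.02), skip=True),
    SubgroupSpec("male", 0.51, (0.36, 0.71)),
    SubgroupSpec("female", 0.44, (0.23, 0.83)),
    SubgroupSpec("ecog_0", 0.46, (0.28, 0.74)),
    SubgroupSpec("ecog_1", 0.51, (0.35, 0.75)),
    SubgroupSpec("never_smoker", 0.38, (0.25, 0.58)),
    SubgroupSpec("current_smoker", 0.41, (0.10, 1.67), skip=True),
    SubgroupSpec("former_smoker", 0.66, (0.41, 1.06)),
    SubgroupSpec("primary_metastatic", 0.53, (0.39, 0.71)),
    SubgroupSpec("recurrent", 0.10, (0.01, 0.86), skip=True),
    SubgroupSpec("liver_metastases", 0.48, (0.31, 0.74)),
    SubgroupSpec("no_liver_metastases", 0.53, (0.35, 0.80)),
    SubgroupSpec("ebv_dna_lt_500", 0.55, (0.28, 1.07)),
    SubgroupSpec("ebv_dna_ge_500", 0.46, (0.32, 0.64)),
    SubgroupSpec("pdl1_lt_10", 0.46, (0.26, 0.81)),
    SubgroupSpec("pdl1_ge_10", 0.47, (0.32, 0.68)),
)


@dataclass(frozen=True)
class PowerSurvival:
    """``S(t)**hr`` for a baseline without a closed-form rescaling."""

    base: object
    hr: float

    def survival_at(self, t):
        return np.power(self.base.survival_at(t), self.hr)


def apply_hr(baseline, hr: float):
    """Proportional-hazards adjustment of a survival curve.

    For Weibull, exponential and Gompertz baselines the result is the same
    family with ``scale * hr`` (shape unchanged); other curves return a
    :class:`PowerSurvival` wrapper evaluating ``S(t)**hr``.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    if isinstance(baseline, SurvivalCurveParams) and baseline.family in (
            Family.WEIBULL, Family.EXPONENTIAL, Family.GOMPERTZ):
        return SurvivalCurveParams(baseline.family, baseline.scale * hr,
                                   baseline.shape)
    if isinstance(baseline, PowerSurvival):
        return PowerSurvival(baseline.base, baseline.hr * hr)
    return PowerSurvival(baseline, hr)


def implied_os_hr(config: Config) -> float:
    """Overall OS hazard ratio implied by the two fitted OS curves.

    Evaluated as the ratio of the arms' instantaneous hazards at the
    comparator's median OS time — the mid-follow-up point where the fitted
    curves are best supported.
    """
    tc_os = config.survival[TC_ARM].os.build()
    chemo_os = config.survival[CHEMO_ARM].os.build()
    t_med = chemo_os.median
    return float(tc_os.hazard_at(t_med) / chemo_os.hazard_at(t_med))


def subgroup_curves(config: Config, spec: SubgroupSpec,
                    strategy: Strategy = "os-inverse") -> Dict[str, Dict[str, object]]:
    """The intervention arm's rebuilt curves for one subgroup."""
    chemo = config.survival[CHEMO_ARM]
    pfs = apply_hr(chemo.pfs.build(), spec.pfs_hr)
    if strategy == "pfs-only":
        return {TC_ARM: {"pfs": pfs}}
    H = spec.os_hr if spec.os_hr is not None else implied_os_hr(config)
    if strategy == "os-inverse":
        os_hr = H * (OVERALL_PFS_HR / spec.pfs_hr)
    elif strategy == "os-coupled":
        os_hr = H * (spec.pfs_hr / OVERALL_PFS_HR)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return {TC_ARM: {"pfs": pfs, "os": apply_hr(chemo.os.build(), os_hr)}}


@dataclass(frozen=True)
class SubgroupResult:
    spec: SubgroupSpec
    comparison: economics.CEAComparison
    prob_cost_effective: Optional[float]


def subgroup_cea(config: Config, spec: SubgroupSpec,
                 strategy: Strategy = "os-inverse",
                 psa_iterations: int = 0, seed: int | None = None
                 ) -> SubgroupResult:
    """Full comparison (and optional PSA) for one subgroup."""
    curves = subgroup_curves(config, spec, strategy)
    tc, chemo, settings = build_model(config, curves=curves)
    comparison = economics.compare(run_totals(tc, settings),
                                   run_totals(chemo, settings),
                                   settings.wtp, tc.name, chemo.name)
    prob = None
    if psa_iterations > 0:
        sub_config = config.model_copy(deep=True)
        psa = _psa_with_curves(sub_config, curves, psa_iterations, seed)
        prob = psa.prob_cost_effective()
    return SubgroupResult(spec, comparison, prob)


def _psa_with_curves(config: Config, curves, n_iter: int, seed):
    from .config import parameter_specs
    from .sensitivity import PSAResult, sample_parameters
    specs = parameter_specs(config)
    draws = sample_parameters(specs, seed, size=n_iter,
                              sd_divisor=config.psa.sd_divisor)
    tc, chemo, settings = build_model(config, draws, curves=curves)
    tot_tc = run_totals(tc, settings)
    tot_chemo = run_totals(chemo, settings)
    frame = pd.DataFrame({
        "iter": np.arange(n_iter),
        "delta_cost": np.broadcast_to(tot_tc.cost - tot_chemo.cost, (n_iter,)),
        "delta_qaly": np.broadcast_to(tot_tc.qaly - tot_chemo.qaly, (n_iter,)),
    })
    return PSAResult(iterations=frame, wtp=settings.wtp)


def subgroup_table(config: Config,
                   subgroups: Sequence[SubgroupSpec] = TRIAL_SUBGROUPS,
                   strategy: Strategy = "os-inverse",
                   psa_iterations: int = 0, seed: int | None = None
                   ) -> pd.DataFrame:
    """Subgroup results table: ``subgroup, pfs_hr, icer, inhb, prob_ce_at_wtp``.

    Skipped strata appear with NaN results, mirroring the published table.
    """
    rows = []
    for spec in subgroups:
        if spec.skip:
            rows.append({"subgroup": spec.label, "pfs_hr": spec.pfs_hr,
                         "icer": np.nan, "inhb": np.nan,
                         "prob_ce_at_wtp": np.nan})
            continue
        res = subgroup_cea(config, spec, strategy, psa_iterations, seed)
        rows.append({"subgroup": spec.label, "pfs_hr": spec.pfs_hr,
                     "icer": res.comparison.icer_per_qaly,
                     "inhb": res.comparison.inhb_qaly,
                     "prob_ce_at_wtp": res.prob_cost_effective})
    return pd.DataFrame(rows)
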