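"""Configuration schema, validation and model building.

One structured YAML file carries every model input: the fitted Weibull
curves for both arms, all per-cycle costs, adverse-event risks and costs,
utilities, discounting and the willingness-to-pay threshold — the
machine-readable twin of the published key-parameters table.  A defaults
file with the published values ships inside the package.

Every uncertain parameter is written ``{base, low, high, distribution}``;
the ranges default to plus/minus 20 percent of the mean, costs sample from
gamma, probabilities and utilities from beta, and the discount rate from a
uniform distribution over its stated range.  :func:`parameter_specs`
flattens the configuration into named :class:`ParameterRef` handles, and
:func:`build_model` turns a configuration (plus optional parameter
overrides) into the two :class:`~npc_cea.markov.ArmSpec` objects and
:class:`~npc_cea.markov.ModelSettings` the engine consumes.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .markov import ArmSpec, ModelSettings
from .survival import SurvivalCurveParams

TC_ARM = "tislelizumab_chemo"
CHEMO_ARM = "chemo"

Distribution = Literal["beta", "gamma", "uniform", "fixed"]


class Param(BaseModel):
    """An uncertain scalar: mean with its one-way range and PSA family."""

    model_config = ConfigDict(extra="forbid")

    base: float
    low: Optional[float] = None
    high: Optional[float] = None
    distribution: Distribution = "fixed"

    @model_validator(mode="after")
    def _default_range(self) -> "Param":
        if self.low is None:
            object.__setattr__(self, "low", 0.8 * self.base)
        if self.high is None:
            object.__setattr__(self, "high", 1.2 * self.base)
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"range must satisfy low <= base <= high "
                f"(got {self.low} / {self.base} / {self.high})")
        return self


class ProbParam(Param):
    @model_validator(mode="after")
    def _in_unit_interval(self) -> "ProbParam":
        if not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(f"probability/utility must lie in [0, 1] "
                             f"(got {self.low}..{self.high})")
        return self


class CurveSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: str = "weibull"
    scale: float
    shape: float = 1.0

    def build(self) -> SurvivalCurveParams:
        return SurvivalCurveParams(self.family, self.scale, self.shape)


class ArmCurves(BaseModel):
    model_config = ConfigDict(extra="forbid")
    os: CurveSpec
    pfs: CurveSpec


class CostParam(Param):
    doses_per_model_cycle: float = 1.0


class ArmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    post_discontinuation_rate: ProbParam
    ae_disutility: ProbParam
    ae_risks: Dict[str, ProbParam]


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cycle_length_months: float = 42.0 / 30.4375
    n_cycles: int = 87
    discount_rate: Param = Field(
        default_factory=lambda: Param(base=0.05, low=0.0, high=0.08,
                                      distribution="uniform"))
    wtp_per_qaly: float = 36289.0
    accrual: Literal["start", "end", "half"] = "start"
    survival_time_unit: Literal["cycles", "months"] = "cycles"
    chemo_duration_model_cycles: int = 2
    routine_cost_states: List[Literal["pfs", "pd"]] = Field(
        default_factory=lambda: ["pfs", "pd"])

    @model_validator(mode="after")
    def _horizon(self) -> "ModelSection":
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        return self


class PSASection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_iterations: int = 10000
    #: SD = (high - low) / sd_divisor; the default treats the range as a
    #: 95% interval (divisor 2 * 1.96)
    sd_divisor: float = 3.92


class MetaSection(BaseModel):
    model_config = ConfigDict(extra="allow")
    currency: str = "USD"
    cny_per_usd: float = 7.0848  # stored for provenance, never applied


#: routine (non-drug) cost keys and the chemotherapy doublet
ROUTINE_KEYS = ("laboratory", "tumor_imaging", "administration")
CHEMO_DRUGS = ("gemcitabine", "cisplatin")


class Config(BaseModel):
    """Validated full parameter set for one analysis."""

    model_config = ConfigDict(extra="forbid")

    meta: MetaSection = Field(default_factory=MetaSection)
    model: ModelSection = Field(default_factory=ModelSection)
    survival: Dict[str, ArmCurves]
    costs: Dict[str, CostParam]
    ae_costs: Dict[str, Param]
    utilities: Dict[str, ProbParam]
    arms: Dict[str, ArmConfig]
    psa: PSASection = Field(default_factory=PSASection)
    scenario_copayment: Dict[str, float] = Field(
        default_factory=lambda: {"gemcitabine": 0.20, "cisplatin": 0.0,
                                 "capecitabine": 0.05})

    @model_validator(mode="after")
    def _completeness(self) -> "Config":
        problems = []
        for arm in (TC_ARM, CHEMO_ARM):
            if arm not in self.survival:
                problems.append(f"survival.{arm} missing")
            if arm not in self.arms:
                problems.append(f"arms.{arm} missing")
        required_costs = ("tislelizumab", "gemcitabine", "cisplatin",
                          "second_line", "best_supportive_care",
                          "terminal_care") + ROUTINE_KEYS
        for key in required_costs:
            if key not in self.costs:
                problems.append(f"costs.{key} missing")
        for key in ("pfs", "pd"):
            if key not in self.utilities:
                problems.append(f"utilities.{key} missing")
        for arm_name, arm in self.arms.items():
            for ae in arm.ae_risks:
                if ae not in self.ae_costs:
                    problems.append(f"ae_costs.{ae} missing "
                                    f"(referenced by arms.{arm_name})")
        for rate_drug, rate in self.scenario_copayment.items():
            if not 0.0 <= rate <= 1.0:
                problems.append(f"scenario_copayment.{rate_drug} outside [0, 1]")
        if problems:
            raise ValueError("; ".join(problems))
        return self

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a configuration file (``None``: packaged defaults).

    Validation failures raise with every offending field listed.
    """
    if path is None:
        text = (importlib.resources.files("npc_cea") / "data" /
                "default_config.yaml").read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        text = p.read_text()
    raw = yaml.safe_load(text)
    try:
        return Config.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors())
        raise ValueError(f"invalid configuration: {details}") from exc


def default_config() -> Config:
    return load_config(None)


# -- parameter flattening for sensitivity analyses ----------------------------


class ParameterRef:
    """A named handle onto one uncertain scalar inside a Config.

    ``shared`` marks parameters common to both arms (utilities, unit costs,
    the discount rate) so a probabilistic draw uses one value everywhere.
    """

    def __init__(self, name: str, param: Param, shared: bool):
        self.name = name
        self.base = param.base
        self.low = param.low
        self.high = param.high
        self.distribution = param.distribution
        self.shared = shared

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"ParameterRef({self.name}, base={self.base}, "
                f"[{self.low}, {self.high}], {self.distribution})")


def parameter_specs(config: Config) -> List[ParameterRef]:
    """All uncertain parameters of the analysis, flattened and named."""
    refs: List[ParameterRef] = [
        ParameterRef("discount_rate", config.model.discount_rate, shared=True)
    ]
    for key in ("pfs", "pd"):
        refs.append(ParameterRef(f"utility_{key}", config.utilities[key], True))
    for key, par in config.costs.items():
        refs.append(ParameterRef(f"cost_{key}", par, True))
    for key, par in config.ae_costs.items():
        refs.append(ParameterRef(f"ae_cost_{key}", par, True))
    for arm_name, arm in config.arms.items():
        refs.append(ParameterRef(f"post_discontinuation_{arm_name}",
                                 arm.post_discontinuation_rate, False))
        refs.append(ParameterRef(f"ae_disutility_{arm_name}",
                                 arm.ae_disutility, False))
        for ae, par in arm.ae_risks.items():
            refs.append(ParameterRef(f"ae_risk_{arm_name}_{ae}", par, False))
    return refs


def _value(overrides: Mapping[str, float] | None, name: str, base: float) -> float:
    if overrides and name in overrides:
        return overrides[name]
    return base


def build_settings(config: Config,
                   overrides: Mapping[str, float] | None = None) -> ModelSettings:
    m = config.model
    return ModelSettings(
        cycle_length_months=m.cycle_length_months,
        n_cycles=m.n_cycles,
        discount_rate_annual=_value(overrides, "discount_rate",
                                    m.discount_rate.base),
        wtp=m.wtp_per_qaly,
        accrual=m.accrual,
        survival_time_unit=m.survival_time_unit,
    )


def build_arm(config: Config, arm_name: str,
              overrides: Mapping[str, float] | None = None,
              curves: Mapping[str, object] | None = None) -> ArmSpec:
    """Assemble one arm's :class:`ArmSpec`.

    ``overrides`` maps :func:`parameter_specs` names to replacement values
    (one-way and probabilistic sensitivity analyses; values may be numpy
    arrays on the fast path).  ``curves`` may replace the arm's fitted
    ``"os"`` / ``"pfs"`` curves (subgroup analysis).
    """
    if arm_name not in config.arms:
        raise KeyError(f"unknown arm {arm_name!r}")
    arm_cfg = config.arms[arm_name]
    curve_cfg = config.survival[arm_name]
    ov = overrides or {}

    cost = {key: _value(ov, f"cost_{key}", par.base)
            for key, par in config.costs.items()}
    doses = {key: par.doses_per_model_cycle for key, par in config.costs.items()}

    drugs = {}
    if arm_name == TC_ARM:
        drugs["tislelizumab"] = cost["tislelizumab"]
    for d in CHEMO_DRUGS:
        drugs[d] = cost[d]

    ae_profile = tuple(
        (ae,
         _value(ov, f"ae_risk_{arm_name}_{ae}", par.base),
         _value(ov, f"ae_cost_{ae}", config.ae_costs[ae].base))
        for ae, par in arm_cfg.ae_risks.items())

    curves = curves or {}
    return ArmSpec(
        name=arm_name,
        pfs_curve=curves.get("pfs", curve_cfg.pfs.build()),
        os_curve=curves.get("os", curve_cfg.os.build()),
        drug_costs_per_cycle=drugs,
        drug_doses_per_model_cycle={d: doses[d] for d in drugs},
        chemo_drugs=CHEMO_DRUGS,
        chemo_duration_cycles=config.model.chemo_duration_model_cycles,
        routine_costs_per_cycle={k: cost[k] for k in ROUTINE_KEYS},
        routine_states=tuple(config.model.routine_cost_states),
        bsc_cost_per_cycle=cost["best_supportive_care"],
        second_line_cost_per_cycle=cost["second_line"],
        second_line_doses_per_model_cycle=doses["second_line"],
        post_discontinuation_rate=_value(ov, f"post_discontinuation_{arm_name}",
                                         arm_cfg.post_discontinuation_rate.base),
        terminal_care_cost=cost["terminal_care"],
        ae_profile=ae_profile,
        utility_pfs=_value(ov, "utility_pfs", config.utilities["pfs"].base),
        utility_pd=_value(ov, "utility_pd", config.utilities["pd"].base),
        ae_disutility_onetime=_value(ov, f"ae_disutility_{arm_name}",
                                     arm_cfg.ae_disutility.base),
    )


def build_model(config: Config,
                overrides: Mapping[str, float] | None = None,
                curves: Mapping[str, Mapping[str, object]] | None = None
                ) -> Tuple[ArmSpec, ArmSpec, ModelSettings]:
    """(intervention arm, comparator arm, settings) for one evaluation."""
    curves = curves or {}
    tc = build_arm(config, TC_ARM, overrides, curves.get(TC_ARM))
    chemo = build_arm(config, CHEMO_ARM, overrides, curves.get(CHEMO_ARM))
    return tc, chemo, build_settings(config, overrides)
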