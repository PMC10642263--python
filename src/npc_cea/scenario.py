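"""Deterministic scenario analyses.

The insurance co-payment scenario rescales listed drug prices by the
fraction of each price that enters the payer-perspective cost under local
reimbursement rules (gemcitabine 20%, cisplatin 0%, capecitabine 5% by
default; tislelizumab is not reimbursed for this indication and keeps its
full price).  Second-line therapy is costed as capecitabine, the guideline
oral second-line agent, so the ``capecitabine`` rate applies to it.
"""

from __future__ import annotations

from typing import Mapping

from . import economics
from .config import Config, build_model
from .markov import run_totals

#: scenario drug keys -> configuration cost keys
_DRUG_KEYS = {
    "tislelizumab": "tislelizumab",
    "gemcitabine": "gemcitabine",
    "cisplatin": "cisplatin",
    "capecitabine": "second_line",
    "second_line": "second_line",
}


def copayment_scenario(config: Config,
                       rates: Mapping[str, float] | None = None
                       ) -> economics.CEAComparison:
    """Re-run the base case with co-paid drug prices.

    ``rates`` maps drug names to the fraction of the listed price kept in
    the model (1.0 leaves a price untouched; the default comes from the
    configuration's ``scenario_copayment`` block).  Unknown drug names
    raise ``KeyError``.
    """
    if rates is None:
        rates = config.scenario_copayment
    overrides = {}
    for drug, rate in rates.items():
        if drug not in _DRUG_KEYS:
            raise KeyError(f"unknown drug {drug!r}; expected one of "
                           f"{sorted(set(_DRUG_KEYS))}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"co-payment rate for {drug} must lie in [0, 1]")
        key = _DRUG_KEYS[drug]
        overrides[f"cost_{key}"] = rate * config.costs[key].base
    tc, chemo, settings = build_model(config, overrides)
    return economics.compare(run_totals(tc, settings), run_totals(chemo, settings),
                             settings.wtp, tc.name, chemo.name)
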