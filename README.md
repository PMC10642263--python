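# npc-cea

Cost-effectiveness model of first-line **tislelizumab plus
gemcitabine/cisplatin** versus **gemcitabine/cisplatin alone** for recurrent
or metastatic nasopharyngeal carcinoma, from the Chinese healthcare-system
perspective (USD, willingness-to-pay $36,289/QALY).

The package implements the full decision-analytic pipeline:

- **`npc_cea.survival`** — parametric survival curves (exponential, Weibull,
  log-logistic, Gompertz, log-normal), censored maximum-likelihood fitting,
  AIC/BIC model selection, and conversion of curves into per-cycle Markov
  transition probabilities.
- **`npc_cea.markov`** — three-state (progression-free → progressed → dead)
  cohort engine with 6-week cycles, a 10-year horizon, 5% annual discounting
  and configurable reward-accrual conventions; vectorised across parameter
  draws for fast probabilistic analysis.
- **`npc_cea.economics`** — incremental cost, ICER, incremental net health
  benefit (INHB) and net monetary benefit, with dominance classification.
- **`npc_cea.sensitivity`** — one-way (tornado) analysis and a
  10,000-iteration Monte-Carlo probabilistic sensitivity analysis
  (gamma costs, beta probabilities/utilities, uniform discount rate) with
  cost-effectiveness acceptability curves.
- **`npc_cea.subgroup`** — subgroup analysis by proportional-hazards
  modulation of the trial's published subgroup PFS hazard ratios.
- **`npc_cea.scenario`** — insurance co-payment scenario.
- **`npc_cea.synthetic`** — synthetic pseudo individual-patient data:
  inverse-CDF simulation, Kaplan-Meier estimation with Greenwood variance,
  digitiser-noise emulation, and curve-to-IPD reconstruction.
- **`npc_cea.config` / `npc_cea.cli`** — a validated YAML configuration
  carrying every model input (the packaged default holds the published
  values) and a `cea` command-line pipeline.

See [docs/methods.md](docs/methods.md) for the model structure, calibration
decisions and known limitations.

## Quick start

```python
from npc_cea import build_model, compare, load_config, run_totals

config = load_config()                 # packaged published inputs
tc, chemo, settings = build_model(config)
result = compare(run_totals(tc, settings), run_totals(chemo, settings),
                 settings.wtp, tc.name, chemo.name)
print(result.to_frame().to_string(index=False))
```

```
          treatment  total_cost   ly  qaly icer_per_ly icer_per_qaly inhb_qaly
              chemo       16171 2.79  1.55   Reference     Reference Reference
tislelizumab_chemo       34191 4.66  2.63        9647         16721      0.58
```

The combination arm costs $34,191 and yields 2.63 QALYs versus $16,171 and
1.55 QALYs for chemotherapy alone — an ICER of **$16,721/QALY**, well below
the $36,289/QALY threshold (INHB 0.58 QALYs).

Command-line equivalents (each writes CSV/JSON artifacts plus a run
manifest into `--out`):

```bash
cea basecase  --out results/
cea owsa      --out results/
cea psa       --n 10000 --seed 7 --out results/
cea subgroups --out results/
cea scenario  --out results/
cea simulate  --arm chemo --endpoint os --n 263 --seed 7 --out results/
cea fit       --ipd results/ipd_chemo_os.csv --out results/
```

## Tests

```bash
python -m pytest -q tests/
```

All numeric assertions are checked against independent oracles (scipy
distributions, lifelines fitters, hand-computed toy models). Three tests in
`tests/test_acceptance.py` intentionally assert published values that the
published inputs cannot reproduce (see the discrepancy analysis above) and
fail with the discrepancy recorded in their assertion; everything else is
green.
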