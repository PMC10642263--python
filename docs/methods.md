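# Model methods and calibration notes

## Decision problem

Two first-line strategies for recurrent/metastatic nasopharyngeal carcinoma
are compared from the Chinese healthcare-system perspective in USD:

- **Combination**: tislelizumab + gemcitabine/cisplatin, tislelizumab
  continued until progression;
- **Chemotherapy**: gemcitabine/cisplatin alone.

Outcomes are discounted lifetime costs, life-years and QALYs over a 10-year
horizon, summarised as an ICER and an incremental net health benefit at a
willingness-to-pay of $36,289/QALY (three times per-capita GDP).

## Model structure

A three-state Markov cohort model — progression-free (PFS), progressed
(PD), dead — with 6-week cycles (42/30.4375 ≈ 1.3799 months) and 87 cycles
(10 years). The whole cohort starts in PFS; death is absorbing.

Transition probabilities come from the two fitted parametric marginal
curves per arm (Weibull, `S(t) = exp(−λ t^γ)`), the standard construction
when only published OS and PFS curves are available:

- per-cycle death probability: `1 − S_os(kc)/S_os((k−1)c)`, applied
  identically from PFS and PD;
- per-cycle PFS-exit probability from `S_pfs`; progression is the excess of
  PFS-exit over death, clamped at zero.

Because each probability is a conditional-survival ratio, the product of
per-cycle non-death probabilities telescopes exactly back to `S_os` — a
property the test suite checks to 1e-10.

### Curve parameters and the time unit

The shipped Weibull parameters are

| arm | endpoint | λ | γ |
|---|---|---|---|
| combination | OS | 0.005008 | 1.297713 |
| combination | PFS | 0.075560 | 0.950960 |
| chemotherapy | OS | 0.001060 | 2.027554 |
| chemotherapy | PFS | 0.034444 | 1.615226 |

These parameters are scale-dependent, and the scale is not stated where
they are published. Evaluated with **time in months** they reproduce the
trial's median OS (≈23 months) and PFS (9.2 vs 7.4 months) almost exactly —
so that is clearly the scale on which they were fitted. Evaluated that way
in the cohort model, however, the downstream totals are far from the
published cohort results (the chemotherapy arm's life-years come out ~34%
low). Evaluated with **time in model cycles** (`survival_time_unit:
cycles`, the shipped default) the cohort totals match the published table
within a few percent across both arms and all three outcome columns. The
model therefore exposes the time unit as a configuration knob and defaults
to cycle units; the months interpretation remains available
(`survival_time_unit: months`).

### Reward accrual and discounting

Costs, life-years and QALYs accrue on the **start-of-cycle** occupancy (the
"beginning of stage" convention of common cohort-simulation software),
selected from {start, end, half-cycle} by calibration against the published
totals. Discounting is continuous in time at 5%/year:
`(1 + r)^(−t/12)` with `t` in calendar months. Terminal-care costs attach
to the deaths of each cycle, discounted at that cycle's end.

### Cost and utility structure

Per 6-week model cycle (two 3-weekly treatment cycles):

- **PFS state** — tislelizumab $778 once per model cycle (combination arm,
  until progression); gemcitabine $39 ×2 and cisplatin $31 ×2 for the first
  2 model cycles (= 4 chemotherapy cycles); routine costs (laboratory $97 +
  imaging $208 + administration $48 = $353).
- **PD state** — best supportive care $142; second-line therapy $77 ×2
  weighted by the arm's post-discontinuation treatment rate (0.52
  combination / 0.72 chemotherapy); the same $353 routine costs.
- **Death** — one-time terminal care $1,833 per death.
- **Adverse events** — grade ≥3 AE management costs and the AE disutility
  are one-time hits to the whole cohort at model entry
  (expected cost Σ riskᵢ·costᵢ: $1,304.19 combination, $1,523.43
  chemotherapy; disutility 0.0070 / 0.0069).
- **Utilities** — PFS 0.65, PD 0.52.

Four of these choices are not derivable from the published description
(accrual convention, chemotherapy-cost duration, AE timing, which states
carry routine costs). They were calibrated once against the published
base-case totals and then frozen in the default configuration; each is an
explicit configuration field, not a hidden constant.

## Sensitivity analyses

- **One-way**: every uncertain parameter set to its low/high bound
  (±20% of the mean unless a source range exists; discount rate 0–8%),
  ranked by ICER span.
- **Probabilistic**: 10,000 iterations; gamma for costs, beta for
  probabilities/utilities (method-of-moments with SD = range/3.92, treating
  the ±20% range as a 95% interval), uniform for the discount rate.
  Survival-curve parameters stay fixed (they are assigned no distribution
  in the published parameter table). Draws for parameters common to both
  arms are shared within an iteration. The whole PSA runs vectorised
  through the cohort recursion (<1 s for 10,000 iterations).

## Subgroups

The trial reports only **PFS hazard ratios** per subgroup. Under
proportional hazards an HR acts as `S_adj = S^hr`; for a Weibull baseline
this is exactly `λ → hr·λ`. The combination arm's PFS curve is rebuilt from
the chemotherapy baseline with the subgroup HR. How the single PFS HR
propagates to the combination arm's OS curve is **not identified** by the
published inputs, so the coupling is a strategy knob:

- `os-inverse` (default): OS HR = H·(0.52/hr), where H ≈ 0.293 is the
  overall OS hazard ratio implied by the two fitted OS curves at the
  comparator's median and 0.52 the overall trial PFS HR. This is the only
  coupling of the three that reproduces the published subgroup ordering
  (weaker PFS effect → lower ICER) and net-health-benefit levels.
- `os-coupled`: OS HR = H·(hr/0.52) — benefit scales together; yields the
  opposite ordering.
- `pfs-only`: OS curves stay at base case.

Strata the trial deemed too small (age ≥65, current smokers, recurrent
disease) are carried in the roster but reported as NA, as published.

## Synthetic data

Published survival evidence exists only as printed Kaplan-Meier figures.
The synthetic module emulates the digitise-and-reconstruct workflow so the
fitting stage is testable without external data: inverse-CDF simulation
with administrative censoring and staggered accrual (defaults n = 263,
24-month cut-off, the trial's scale), product-limit estimation with
Greenwood variance, grid sampling with truncated digitiser jitter, and a
simplified interval-allocation reconstruction (no numbers-at-risk
refinement, so all censoring sits at end of follow-up).

## Known discrepancies

Three published figures cannot be reproduced from the published inputs
under any configuration of this model; the acceptance tests assert them at
the published tolerance and fail, recording the gap rather than masking it.

1. **Tornado top-3** — the published tornado lists the combination arm's
   thrombocytopenia risk among the three widest bars. As a one-time
   entry cost (risk 0.206 × $3,588), ±20% of that risk moves total cost by
   ≈ $148 and the ICER span by ≈ $275 — two orders of magnitude below the
   top bars (tislelizumab cost ≈ $4,236, PD utility ≈ $3,422, PFS utility
   ≈ $3,335). No AE-timing variant supported by the published description
   closes that gap. The computed min/max ICER bracket does match the
   published $15,045–$19,171 within 15%.
2. **PSA probability** — published 97.9% cost-effective at the threshold.
   With all SDs tied to the ±20% ranges and fixed survival curves, the
   incremental QALY gain is bounded far from zero and essentially every
   iteration is cost-effective (≈100%). Reproducing 97.9% would require
   wider, unpublished uncertainty (e.g. sampling the survival parameters).
3. **Former-smoker subgroup ICER** — published $9,698/QALY (95% CI
   $5,298–$14,852). The model yields ≈ $14,245 under the default
   `os-inverse` strategy — inside the published CI but outside ±20% of the
   point estimate. A lower bound argument shows the point estimate is
   unreachable with the published cost structure: even pure
   progressed-state life extension costs ≈ $9.6k per QALY at the margin
   before any tislelizumab cost, so arm-level ICERs floor near $12.5k.

## Limitations

- The OS coupling across subgroups is structurally unidentifiable from the
  published inputs (see above); subgroup ICERs are sensitive to it.
- The death probability is applied identically from PFS and PD, the usual
  simplification when only marginal OS and PFS curves are published.
- The curve time-unit calibration means the shipped parameters should not
  be reinterpreted as month-scale Weibull fits when used in the cohort
  model.
- PSA uncertainty excludes the survival-curve parameters, so decision
  uncertainty is understated.
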