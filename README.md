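# asthmacea

A dynamic-adherence Markov cohort model for asthma cost-effectiveness
analysis, built for health economists evaluating pharmacist-run medication
adherence clinics (RMTAC) as an adjunct to usual physician care (UC) in
adults with asthma.

Most asthma decision models treat medication adherence as an external
scenario. Here adherence is part of the state space: the model tracks a
closed cohort of 50-year-old patients over monthly cycles until age 105
through eight health states —

| state | meaning |
|---|---|
| A | good control, high adherence |
| B | good control, low adherence |
| C | poor control, high adherence |
| D | poor control, low adherence |
| E | exacerbation with urgent/ED visit |
| F | exacerbation with hospitalization |
| G | death due to asthma (absorbing) |
| H | death due to other causes (absorbing) |

Low-adherence patients (B, D) carry tabulated monthly exacerbation
probabilities; high-adherence patients (A, C) get them adjusted on the rate
scale, p' = 1 − (1 − p)^HR. The usual-care arm's A–D dynamics are derived
from the intervention arm by converting an effectiveness odds ratio to a
relative risk (Zhang–Yu, RR = OR / (1 − p₀ + p₀·OR)) and deflating the
transitions into the promoted states. Outcomes are discounted QALYs and
costs ((1+d)^(−t/12) per monthly cycle) and undiscounted life years and
hospitalization events; strategies are compared by ICER = ΔC/ΔE against a
willingness-to-pay threshold of $9,006 per QALY (all costs 2014 USD).

The package also implements the estimation stage that produced the
transition inputs: classifying (ACT, adherence) score pairs into states A–D,
counting transitions at mixed visit gaps, decomposing k-month transition
matrices into monthly ones by a regularized principal matrix root, add-one
smoothing of zero cells, and Wilson score intervals. A synthetic-data module
generates the inputs the original analysis drew from unpublished sources: a
calibrated Gompertz–Makeham life table, an in-hospital case-fatality
fixture, and longitudinal clinic-style visit panels.

## Worked example

```sh
python examples/run_base_case.py
```

```
RMTAC_UC:  26.76 life years |  9.11 QALYs |  8.50 hospitalizations | $22,434
      UC:  26.68 life years |  9.02 QALYs |  9.24 hospitalizations | $23,495

incremental cost          $-1,060.32
incremental QALYs          0.0966
hospitalizations averted   0.7440
ICER per QALY gained      $-10,973  -> dominant
```

Read: per patient over a lifetime, adding the adherence clinic saves about
$1,060, gains about 0.10 QALYs and averts 0.74 hospitalizations — the
intervention is *dominant* (cheaper and more effective), so the ICER is
negative. Probabilistic and one-way sensitivity analyses
(`examples/run_psa.py`, `examples/tornado_analysis.py`) show the cost saving
is robust while the QALY gain is uncertain in sign, and that only the
health-state utilities can push the ICER past the threshold — lowering the
good-control utility to its lower limit, or raising the poor-control utility
to its upper limit, flips the QALY increment negative.

Other entry points: `examples/estimate_transitions.py` (panel →
matrix estimation round trip) and the `asthmacea` command line
(`validate`, `run-base`, `run-owsa`, `run-psa`, `estimate-transitions`,
`simulate-records`, `make-lifetable`).

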