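# Methods

## Model

A discrete-time Markov cohort model with monthly cycles over eight states
(A–F alive, G asthma death, H other-cause death). The cohort enters at age
50 distributed over states B, C and D and is followed for 660 cycles (to age
105). Four structural assumptions are carried over from the clinical
setting being modelled: exacerbation severities are mutually exclusive
within a cycle; adherence is high on recovery from an exacerbation (so E and
F can only discharge into A or C); comorbidities and pharmacological
management are assumed adequate; and clinic follow-up continues until death.

Each cycle, mortality is applied first: every alive state sends q(age) to H;
state E additionally sends p_EG to G and state F the age-banded case
fatality. Surviving mass is redistributed proportionally over the
alive-state dynamics, which keeps every row stochastic at every age. The
alive-state dynamics are: tabulated A–D transitions (self-loop as residual);
exacerbation entries from B/D at tabulated monthly probabilities and from
A/C after hazard-ratio adjustment on the rate scale (p' = 1 − (1 − p)^HR,
i.e. r' = HR·r under p = 1 − e^(−rt)); recovery from E/F into A or C;
re-exacerbation E↔F at a shared probability.

The usual-care arm replaces the A–D block: each transition from a state
outside the effectiveness factor's target set into the target set is
deflated by the relative risk obtained from the odds ratio via the Zhang–Yu
correction RR = OR/(1 − p₀ + p₀·OR); the removed mass returns to the row's
self-loop. Two open choices are settled as follows and are configurable:

* **Reference risk p₀** for the OR→RR conversion: no control-arm risk is
  reported, so the default uses the intervention-arm cell being adjusted as
  its own reference (`effect.reference_risk: rmtac_row_probability`); an
  `exact_odds` mode (divide the cell's odds by the OR) is the self-consistent
  alternative and gives nearly identical results at these magnitudes.
* **Direction**: the intervention matrix is treated as observed and the
  usual-care matrix derived by deflation (not inflation from a UC baseline),
  matching the provenance of the estimates (clinic records).

The effect applies only to the A–D rows; post-exacerbation recovery and all
E/F dynamics are arm-independent. Effect targets: the asthma-control factor
promotes the good-control states {A, B}; the medication-adherence factor
(scenario) promotes the high-adherence states {A, C}.

### Outcome accumulation

Life years and hospitalization events are undiscounted; QALYs and costs are
discounted at 3%/year with per-cycle factor (1 + d)^(−t/12). This split is
inferred from the relative magnitudes of reported life years (~28) versus
QALYs (~9.5) in analyses of this design. Accrual uses post-transition
occupancy; no half-cycle correction is applied by default (a config switch
exists). Hospitalizations are counted as expected *entries* into state F
(flows from any other state), not occupancy-months; the occupancy-month
variant is available via `model.hospitalization_metric` and gives much
larger counts because a hospitalized episode here spans several cycles.
Clinic costs are charged to the intervention arm only, weighted by the
fraction alive: recruitment at cycle 0, the quarterly-follow-up rate for
cycles 1–15, the biannual rate thereafter.

### Parameters

All tabulated inputs (point value, 95% range, distribution family) ship in
`config/base_case.yaml`: the 12 A–D transition probabilities (Dirichlet
rows), two effectiveness odds ratios (lognormal), four low-adherence
exacerbation probabilities and two hazard ratios, four recovery
probabilities, the tied re-exacerbation probability (0.047), the E-state
mortality (5.9e-5), two utility sets (A/B and C/D tied within each), and
nine monthly costs in 2014 USD. The starting mix over B/C/D is not reported
anywhere; the default is equal thirds, exposed in config and varied in
tests. The willingness-to-pay threshold is $9,006/QALY.

## Estimation stage

Visit records carry an ACT score (5–25; ≤ 19 = poor control) and an 8-item
adherence score (0–8; < 6 = low adherence). Consecutive visits k months
apart contribute to the gap-k count table (gaps > 12 months are discarded as
uninformative for monthly dynamics). Gap-1 tables yield monthly proportions
directly; longer gaps are decomposed by the principal k-th matrix root via
eigendecomposition, with regularization (imaginary parts < 1e-8 dropped,
negative entries clipped, rows renormalized) and diagnostics (clipped mass,
imaginary residual). A k-step matrix without a real principal root raises an
error advising the pooled-count fallback. Estimates pool across gaps with
per-row pair-count weights; a row whose pooled off-diagonal contains an
exact zero is recomputed from its gap-1 counts with one added to every cell
(uninformative add-one prior), e.g. counts (0,0,0 | 5 stays) become
probabilities (1/9, 1/9, 1/9, 6/9). Cell intervals are Wilson score
intervals at z = 1.959964 on the pooled effective counts. Rows never
observed as an origin are flagged inestimable and left to configuration.

## Probabilistic sensitivity analysis

Distribution fits: Beta and Gamma by method of moments with
sd = (high − low)/3.92 (an optional quantile-matching fit solves both range
endpoints numerically); Lognormal with μ = ln(value), σ = (ln high − ln
low)/3.92 — both assume the interval is normal on the (log) scale; Dirichlet
rows with α = p·N_eff, N_eff = 16 by default (the order of the observed
one-month sample), self-loop taking the residual α. N_eff controls the
spread of the transition rows and materially widens the credible intervals
as it shrinks; it is exposed as `base_transitions.dirichlet_n_eff`.

Tied draws: u_A = u_B, u_C = u_D, p_EF = p_FE, and one draw per hazard-ratio
pair. Structural inputs without tabulated ranges (life table, case
fatality, initial mix) are held fixed. Per draw, the usual-care matrix is
re-derived from the sampled intervention matrix and sampled OR. Draws whose
rows would sum past one are rejected and redrawn (observed rejection rate
~0.02%). A single master `numpy` Generator seeds all sampling; draws are
sampled as whole arrays, so results are bitwise reproducible from one seed.
ICERs are reported both as ratio-of-means and as percentiles of per-draw
ratios (draws with |ΔE| < 1e-9 excluded and counted); the CEAC is
P(λ·ΔE − ΔC > 0) over a threshold grid.

## Synthetic inputs and what passing tests mean

Three inputs of the original analysis are not published and are replaced by
declared synthetic stand-ins:

* **Life table** — Gompertz–Makeham hazard μ(a) = α + β·e^(γa), monthly
  q = 1 − e^(−μ/12), with β scaled by bisection so the discrete monthly life
  expectancy at 50 equals 27.8 years (the national figure used for external
  validation). The table's LE uses the same age-indexing convention as the
  engine (cycle t uses age = start + ⌊(t−1)/12⌋, 12 cycles per row), so the
  cohort reproduces it exactly when state dynamics carry no extra mortality.
* **In-hospital case fatality** — a non-evidentiary fixture
  (`config/case_fatality.yaml`), 0.08%–0.6% per month by decade band.
  Because a hospitalized episode spans ~5 cycles under the tabulated
  recovery probabilities, this implies ~0.4–3% per-admission fatality,
  consistent with reported in-hospital asthma mortality and with the
  validation property that cohort life years stay near the background life
  expectancy. Real analyses must supply their own table.
* **Visit panels** — latent monthly A–D trajectories from a known matrix,
  observed through scores drawn uniformly from the region matching the
  latent state (optional misclassification noise), at a monthly or
  clinic-style (1/3/6-month gap) schedule.

Passing tests therefore demonstrate internal correctness (conservation,
agreement with an independent microsimulation within Monte-Carlo error,
estimator recovery on synthetic panels, determinism) and the qualitative
economic conclusions (dominance; only the utility levers overturn
cost-effectiveness). They do not certify agreement with any particular
national mortality experience, and lifetime counts that depend on the E/F
episode structure (hospitalization events, scenario QALY gains driven only
by the exacerbation channel) are sensitive to the stand-ins and to the
episode-duration structure implied by the tabulated recovery probabilities.

## Numerical choices and problem sizes

Tolerances: rows stochastic within 1e-12 at build, 1e-9 over the trace;
matrix-root imaginary tolerance 1e-8; life-table calibration to 0.01 year.
Degenerate inputs: ranges of zero width collapse to point masses; q = 1
ages cap total death probability at one (asthma deaths take precedence).
One-way variation of a Dirichlet cell absorbs the change in the row's
self-loop rather than renormalizing proportionally, so a single lever moves
a single probability. The test suite runs the full 660-cycle horizon for
deterministic checks, a 120-cycle window against a 200,000-individual
microsimulation oracle, and 1,500-draw PSAs; the acceptance script runs
10,000-draw PSAs, matching the configured `psa_draws`.

## Known limitations

* The A–D effect conversion treats each cell independently; a composite
  control-and-adherence treatment effect is not modelled (no such source
  estimate exists).
* No interval-censoring likelihood for the estimation stage; the matrix-root
  reconstruction can fail for k-step matrices without a real principal root,
  in which case pooled counts at that gap must be used directly.
* Cohort age is cohort-wide (12 cycles per life-table row); no state-specific
  ageing or time-varying utilities.
* Currency is fixed 2014 USD; no transferability adjustment of the non-local
  effect sizes.
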