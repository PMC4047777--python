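# Methods

## Model structure

`equicea` is a deterministic three-state Markov cohort model on a
monthly cycle. A cohort enters at diagnosis and, each month, exits to
death from the modelled cancer or death from other causes via a
competing-risks split of two cause-specific rates; remaining mass stays
alive. The run ends at age 110 and surviving mass is reported as such.
Rather than attaching rewards to states cycle by cycle, valuation is
conditioned on the absorbing outcome: for every (cause, month-of-death)
pair — and for survival to the horizon — the disease trajectory is
reconstructed retrospectively and valued in discounted HALYs and NZ$
costs, then expectation-weighted by the absorption distribution. The
two formulations are equivalent here because phase membership depends
only on the outcome and the month, and the retrospective form makes
end-anchored phases (terminal disease before a cancer death, final
months of life before a non-cancer death) natural to express.

Key structural assumptions:

* **Excess-mortality hazard.** The cancer's excess rate is constant in
  time since diagnosis until the statistical-cure month, then exactly
  zero. No published within-period hazard shape was available;
  constancy is the minimal assumption, and the engine accepts any
  precomputed monthly hazard array (`run_cohort(..., excess_monthly=)`)
  so a declining shape can be substituted without touching the engine.
* **Intervention.** A proportional reduction (default 20 %) applied to
  the excess hazard in every cycle in which it is nonzero — i.e. from
  diagnosis to cure, not only during treatment — because the effect is
  defined on monthly excess mortality without restriction.
* **Entry age.** Cohorts enter at the midpoint of their 5-year age band
  (52.5 for 50–54); results are reported by band.
* **No half-cycle correction.** With monthly cycles the correction is
  far below reporting precision.
* **Calendar time.** Background mortality is projected at the cohort's
  *attained* calendar year (entry year + elapsed months), with the
  decline frozen at the horizon year (2026). Entry year and horizon are
  both configurable.

## Phase trajectories and valuation

Cancer deaths at month *d*: the last `terminal_months` months are
terminal, the `preterminal_months` before them pre-terminal, the first
`diagnosis_months` diagnosis, with remission filling any gap. When *d*
is too early for all phases, end-anchored precedence applies: terminal
first, then pre-terminal, then a truncated diagnosis phase (a death at
month 3 for a 5/5/1 schedule is 2 pre-terminal months plus 1 terminal
month and no diagnosis slots). Survivors and other-cause deaths follow
diagnosis → remission → cured at `cure_months`, front-anchored.

Each lived month is worth `(1 − DW_phase) × (1 − pYLD)` / 12 HALYs,
discounted by `(1+r)^(−t/12)` at month's end. The two morbidity terms
combine **multiplicatively**: the envelope (1 − pYLD) is the maximum
health attainable in the stratum and the cancer's disability weight
scales what remains, which keeps weights in [0, 1] and never subtracts
past zero. This is the one genuinely unverifiable valuation choice; an
additive convention would lower all HALYs slightly but cannot change
the layering-dominance results. The remission disability weight is held
constant until cure (no decay). pYLD is looked up at the attained
5-year age band; ages past the top band (90–94) reuse the top band, as
do band-indexed costs.

Other-cause deaths keep their cancer phase schedule for costs and
disability, substitute the (pro-rated) last-six-months-of-life cost for
the background cost in their final six months, and — representing the
elevated terminal morbidity of those deaths — apply the terminal-phase
disability weight in their final month (configurable off via
`other_death_terminal_dw=False`).

Costs per month: cancer phase-specific monthly cost (zero once cured) +
background annual cost/12 at the attained band + the intervention's
direct monthly cost during diagnosis months when the intervention is
on, all discounted identically to benefits.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| Intervention effect | 0.20 | fraction of excess hazard | scenario-standardised treatment |
| Direct cost | 2,500 | NZ$/month, diagnosis phase | sized to put mid-age ICERs near a NZ$40k threshold |
| Discount rate | 0.03 | per annum | applied to costs and HALYs |
| Horizon | 110 | years of age | practical lifetime bound |
| Phase durations | lung 5/5/1, breast 6/11/1, colon 9/3/1 | months (diagnosis/pre-terminal/terminal) | terminal is always the death month |
| Statistical cure | lung 72, breast 240, colon 96 | months since diagnosis | excess hazard is zero afterwards |
| Disability weights | lung .469/.539/.548/.315; breast .194/.512/.520/.174; colon .288/.539/.548/.167 | (diagnosis/pre-terminal/terminal/remission) | standard per-phase weights for the three cancers |
| Background decline | Māori 2.25 %, non-Māori 1.75 % | per calendar year to 2026 | matches long-run life-expectancy improvement; valid range 0–4 % |
| Life-table base year | 2006 | — | also the cohort entry year |

Rates are stored per person-year and divided by 12 inside the engine
(rate division, not a probability root, because rates are additive and
the engine works in rates); conversion to per-cycle probabilities is
`1 − exp(−m)` with the competing-risks allocation proportional to
rates. The reference group for "set to non-Māori" switches defaults to
`non_maori` but is an argument everywhere, so standard-population
analyses with any reference are possible.

## The synthetic bundles

`generate_bundle(seed)` emulates the *structure* of the real inputs,
not their values:

* incidence ratios Māori/non-Māori of 3.0 (lung), 1.17 (breast, female
  only) and 0.6 (colon), exact in every stratum because lognormal
  stratum noise (σ = 0.05) is shared between ethnicities;
* excess mortality with non-Māori annual rates of 0.45 (lung), 0.045
  (breast) and 0.09 (colon) and Māori ratios 1.35/1.5/1.35 — lung sits
  in a low absolute-survival regime and breast/colon in high-survival
  regimes, which is what produces the characteristic reversal: an equal
  proportional hazard reduction yields *smaller* per-case gains for the
  higher-mortality group in a low-survival cancer but *larger* gains in
  high-survival cancers;
* Gompertz-like background mortality (log-linear in age, rate 0.02 at
  age 70 for non-Māori males, slope 0.09/yr, female factor 0.65) with a
  constant Māori/non-Māori ratio of 1.7 — large enough that Māori rates
  stay above non-Māori even after the faster Māori decline runs to its
  2026 horizon;
* pYLD linear in band-midpoint age (0.006/yr), anchored at 0.224 for
  non-Māori females aged 70–74, male factor 0.9, Māori uplift +0.06 at
  every age;
* deprivation distributions Māori (0.15, 0.25, 0.60) vs non-Māori
  (0.40, 0.35, 0.25) over tertiles 1–3/4–6/7–10, with deprivation
  gradients on incidence and excess mortality;
* populations declining log-linearly in age, Māori younger and ~1/8 the
  size; costs rising log-linearly in age from NZ$1,200/yr, flat
  NZ$25,000 last-six-months cost, and per-cancer phase costs of a few
  thousand NZ$/month.

What the synthetic bundles do **not** emulate: real NZ levels (they are
calibrated to nothing), age-dependence of ethnic rate ratios,
sex-specific cancer survival, deprivation-specific life tables or pYLD,
cohort effects, and any parameter uncertainty. Passing tests on these
bundles therefore demonstrates the model's internal correctness and the
direction and mechanism of the heterogeneity-layering effects — not
reproduction of published absolute HALY or ICER magnitudes, which would
require the undeposited national inputs.

## Numerical choices

* Absorption mass conservation is exact by construction
  (`p_other = p_exit − p_cancer`; checked to 1e-10 in tests).
* The pipeline values all outcomes with an O(T) prefix-sum formulation
  (`value_all_outcomes`); tests pin it to the explicit per-trajectory
  construction at 1e-12 relative tolerance.
* Both cause-specific rates zero ⇒ (0, 0, 1) survival split; zero
  reference in a percent change and a zero relative-risk denominator
  return NaN rather than raising; an ICER with non-positive incremental
  HALYs carries an `undefined` flag, negative incremental cost with
  positive gain a `dominant` flag.
* Rounding happens only in the reporting layer (`reporting_view`: HALYs
  2 dp, % 1 dp, RR 2 dp, ICER to the nearest NZ$100); all internal
  computation is full precision.
* Bundle CSVs are re-read with round-trip float parsing so a written
  bundle reloads bit-identically.
* Per-case results are computed per sex and aggregated with case
  weights (population × deprivation weight × incidence), as is the
  deprivation aggregation; breast cancer is female-only throughout.
  Per-100,000 denominators use the population of the sexes at risk for
  the cancer in the reported age band.

Default analyses use the three reporting age bands (50–54, 65–69,
80–84); the stratum grid spans 45–49 through 90–94 and any subset can
be requested. A full three-cancer, five-model grid at the default bands
is ~900 cohort runs of ≤690 monthly cycles and completes in about a
second; the validation suite's 50-seed dominance sweep and the
100,000-individual Monte-Carlo engine oracle each finish in seconds.

## Known limitations

* Expected values only: no probabilistic sensitivity analysis (the
  deterministic two-way cost × effect grid is provided instead).
* Excess-mortality estimation from registry data, cost regression from
  linked health data, and census linkage are out of scope; all inputs
  arrive as tables.
* The morbidity adjustment for other-cause decedents and the
  multiplicative DW×envelope combination are modelling conventions (see
  above), isolated behind flags/arguments.
* Equity *weighting* (valuing gains to disadvantaged groups more) is
  deliberately not implemented; the package quantifies how conventional
  methods value them less.
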