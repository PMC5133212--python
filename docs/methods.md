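# Methods

## Model structure

The package implements a deterministic cohort expectation model with two
stages and a societal side-calculation.

**NICU stage.** The cohort of `n_preterm` infants (default 51,703) is split
across four birthweight bands and three feeding arms (exclusive human milk /
mixed / formula). For each in-NICU outcome — medical NEC, surgical NEC,
late-onset sepsis — the published band incidence is interpreted as the
mixed arm's risk (the published odds ratios are phrased "mother's milk vs
mixed" and "formula vs mixed"), and the other arms' risks follow by exact
odds-scale adjustment: `odds(p_arm) = OR × odds(p_mixed)`. Expected cases
are `n × band share × arm share × risk`. A scenario is a pair
(exclusive-HM rate, any-HM rate); arm shares are (exclusive, any−exclusive,
1−any). The base case is 35%/35%, the counterfactual 100%/100%, so the base
case has no mixed-fed infants and the comparison is effectively exclusive
human milk vs formula, with the mixed arm serving as the OR anchor.

Costs are per-case treatment costs: length of stay × £630.08/day plus any
fixed tariff. They are *always computed from components* because the
published input table's per-case "total cost" cells for medical NEC
(£1,739) and sepsis (£17,138) are inconsistent with their own days ×
per-day entries — the surgical-NEC total £18,877 = 27.2 × £630.08 + £1,739
shows the medical-NEC and sepsis cells are transposed. Computed values:
medical NEC £17,138.18, sepsis £3,717.47, surgical NEC £18,877.18 (the full
medical treatment cost plus the £1,739 surgical tariff).

Deaths are attributed only through condition cases: a case in band *b*
carries excess death probability
`apply_or(m_b, OR_death|condition) − m_b` against the baseline band
mortality `m_b` (20.5/8.0/5.0/0%). There is no direct feeding→mortality
pathway. Each death averted is valued at 23.6 discounted QALYs.

**Post-discharge stage.** Two arms: any human milk vs formula, shares
(any-HM rate, 1−any). Published incidences here are population rates, so
they are decomposed into arm risks by solving
`Σ share_i · apply_or(p_ref, OR_i) = p_pop` with the *base-case* shares
(monotone bracketing via Brent's method, |residual| < 1e-12); arm risks are
therefore scenario-invariant and deltas arise purely from shifting shares.
Condition handling:

* **SIDS** (0.07%, OR 0.40): first-year, undiscounted £72/case; every case
  averted is a death averted worth 23.6 QALYs.
* **AOM** (0.14%, OR 0.40): first-year £46/case; no QALY weight is
  published, so none is applied.
* **Leukaemia** (0.04% to age 15, OR 0.91): £114,456/case discounted from
  the diagnosis age; per-case QALY gain = (comparator utility − 0.66) ×
  annuity(treatment years) discounted from diagnosis, plus (1 − 0.92) ×
  23.6 for the fatal fraction.
* **Obesity chain** (9.5% childhood obesity, OR 0.79): obese children
  averted × 65% persistence → obese adults; × 9.61%/6.04% prevalence →
  diabetes/CHD cases; each pays its annual cost (£787/£1,974) and utility
  decrement (vs 0.866/0.867) from the diagnosis age (55/65) to age 75,
  discounted to birth.
* **NDI**: driven by the NICU case deltas. Each NEC/sepsis case carries
  excess NDI probability `apply_or(band NDI incidence, OR_NDI|condition) −
  incidence` (band incidences 49/41/34/0%). Cases are split
  mild/moderate/severe by the published 65/22/14% — which sums to 101% and
  is renormalised, with a log line. Lifetime costs (£14,421 / £13,959 /
  £365,005) are treated as present values at occurrence. Per-case QALY loss
  = comparator utility × annuity(78.5 y) − severity utility ×
  annuity(severity life expectancy).

**Economics.** Year-0 amounts are undiscounted; an amount at year *t* is
multiplied by `(1+r)^−t` (r = 3.5%/year); no half-cycle correction.
`annuity(n, r) = (1 − (1+r)^−n)/r` (computed via `expm1`/`log1p` for
stability; a fractional final year is pro-rated). QALYs are monetised at
£20,000/QALY; net monetary value = savings + monetised QALYs, an exact
identity in the summary. Productivity preserved by averted deaths is an
undiscounted lifetime-earnings lump sum (mid value £645,500; low/high
£540,500/£750,500 exposed to the DSA).

## Key parameters and defaults

| parameter | default | why |
|---|---|---|
| band shares (500–999/1000–1749/1750–2500/>2500 g) | 4/10/36/50% | **assumption** — the source never states its birthweight distribution; the >2500 g band carries zero NICU-outcome and NDI risk, which is conservative. This is the model's principal free parameter. |
| NICU anchoring | mixed arm | the published ORs are phrased against the mixed arm |
| post-discharge anchoring | population mix at base shares | published incidences are population rates under current feeding |
| leukaemia diagnosis age / treatment years | 5 y / 2 y | unpublished; configurable |
| comparator (age-norm) utility | 1.0 flat | condition utilities are published, the comparator profile is not |
| qaly-loss-per-death profile | utility 0.880255 over 81 y | calibrated: 0.880255 × annuity(81, 0.035) = 23.6, rebuilding the published per-death constant from first principles |
| DSA ranges | ±20% (ORs log-symmetric: ×0.8, /0.8) | 95% CIs are not published; ranges are labelled `pct20_default` and overridable per parameter. The two NEC feeding ORs are varied as single linked parameters across both NEC severities, since the surgical row declares its ORs "as for medical NEC". |

## What the microsimulation shows — and what it does not

`simulate_cohort` samples individual infants from *exactly* the structure
the expectation model assumes: categorical band and arm, independent
Bernoulli condition events, excess-death and excess-NDI draws per condition
case, an independent post-discharge arm, independent post-discharge events.
A single seeded PCG64 stream with a fixed draw order makes every run
reproducible. Agreement (z-scores of sampled vs expected tallies, binomial
SE) verifies the expectation algebra — mixture decomposition, OR
adjustment, attribution arithmetic — to Monte-Carlo precision, across
random parameter sets generated by `random_plausible_config` (feeding ORs
log-uniform in [0.2, 5], so both protective and harmful effects are
exercised; conditional mortality/NDI ORs in [1, 5] so excess probabilities
stay non-negative).

It does **not** validate the model against reality: comorbidity
correlations, length-of-stay variation, time-to-event structure and any
feeding→outcome pathway outside the published odds ratios are absent from
both the engine and the simulator by construction. Passing tests show
internal consistency, not external calibration.

Because z-scores are standard normal under a correct engine, the agreement
tests are statistical: over ~1,100 event comparisons (50 parameter sets ×
~22 events) they require ≥99% of |z| < 3, a hard cap of |z| < 5, and ≥90%
of runs with max |z| < 3, rather than a strict max < 3 that a correct
sampler would fail with high probability.

## Published headline figures and the identity layer

The published cohort totals (£30.1M first-year savings, £46.7M lifetime,
4,568 + 6,026 QALYs, 190 + 48 deaths) are *not* recoverable from the
published input table alone: the birthweight distribution, the anchoring
convention and the full calculation diagram are unpublished, and e.g. the
published 48.03 SIDS cases averted cannot be produced from the 0.07%
incidence and OR 0.40 under any standard anchoring (this implementation
obtains 17.86). The model therefore treats the published long-term table as
structural guidance, while `neomilk.reporting` verifies everything that
*is* arithmetically determined: per-case cost construction and the
monetisation/aggregation identities that link the published stage figures
(used as inputs) through the WTP threshold and cohort size to the published
£91.4M, £1,767, £121.5M, 0.088, £120.5M, £137.1M, £321, 10,594, 238 and
0.2. The published £153.4M productivity figure corresponds to unrounded
deaths ≈ 237.65; 238 × £645,500 = £153.6M, and both conventions are
reported.

## Numerical choices and degenerate inputs

* OR adjustment is exact on the odds scale; `p_ref = 1` maps to 1 (infinite
  odds); `p_ref = 0` stays 0.
* The mixture solver brackets on [0, 1]; the endpoints anchor without
  solving. The mixture maps [0, 1] onto [0, 1] monotonically, so every
  valid population rate is feasible; the infeasibility error exists only
  defensively.
* Degenerate scenarios (one arm holding the whole population) reproduce the
  population rate in that arm exactly.
* Tornado ties are broken by parameter path, lexicographically; a bound
  outside a parameter's domain is recorded on its entry and the run
  continues.
* Configuration files must be complete (every defaulted key present);
  numeric values given as text are coerced with a warning.

## Problem sizes

The shipped verification runs use n = 10⁶ simulated infants for the
default-configuration check and 50 random parameter sets at n = 10⁵–10⁶
for the sweep; these sizes put Monte-Carlo error well below every effect
of interest while keeping a full run in seconds on one core.

## Known limitations

* Headline totals depend on the assumed birthweight mix (see above);
  sensitivity to it can be explored through the config, and no claim of
  numerical equivalence with the published totals is made.
* The sepsis "formula vs mixed" OR is published as 0.803 — protective for
  formula relative to mixed, directionally opposite to NEC; it is applied
  at face value.
* AOM's 0.14% is treated as cumulative first-year risk; SIDS deaths use the
  same 23.6 QALY constant as NICU deaths (no age shift); the post-discharge
  population defaults to the full cohort (a `survivors_only` switch applies
  expected baseline NICU survival instead).
* Maternal outcomes, interventions to raise feeding rates, probabilistic
  sensitivity analysis and price-year adjustment are out of scope.
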