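"""Post-discharge stage: SIDS, acute otitis media, childhood leukaemia, the
obesity → type-2-diabetes/CHD chain, and neurodevelopmental impairment.

After NICU discharge the comparison is two-armed: infants who received any
human milk versus exclusively formula-fed infants, with each published
population incidence decomposed against the base-case feeding mix
(``population_mix`` anchoring) so that arm risks are scenario-invariant.

Time horizons follow the source analysis: first year of life for the acute
conditions (SIDS, AOM — costs undiscounted), lifetime for leukaemia, the
obesity sequelae and NDI (discounted at the cohort rate; amounts at year t
carry ``(1+r)^-t``, no half-cycle correction). NDI lifetime costs are
treated as present values applied at occurrence. NDI is driven not by
feeding directly but by the NICU condition deltas: each NEC/sepsis case
carries an excess NDI probability via its condition-specific odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .econ import annuity, discount_factor
from .nicu import NICUDelta, compare_nicu
from .params import (
    NICU_OUTCOME_ORDER,
    FeedingScenario,
    ModelConfig,
    NDIParams,
    ObesityChainParams,
    PostDischargeOutcomeParams,
)
from .risk import apply_or, arm_risks

__all__ = [
    "ConditionDelta",
    "DeltaReport",
    "simple_condition_delta",
    "leukaemia_delta",
    "obesity_chain_delta",
    "ndi_delta",
    "run_postdischarge",
]

#: Output row order of the long-term benefits table.
CONDITION_ORDER = ("sids", "aom", "leukaemia", "ndi", "diabetes", "chd")


@dataclass(frozen=True)
class ConditionDelta:
    """Scenario difference for one condition: cases averted and the
    discounted cost savings and QALY gains they carry."""

    condition: str
    cases_averted: float
    cost_savings: float
    qaly_gain: float
    deaths_averted: float = 0.0


@dataclass(frozen=True)
class DeltaReport:
    """The six-condition long-term benefits table plus its totals."""

    base_label: str
    counterfactual_label: str
    rows: tuple[ConditionDelta, ...]
    total_cases_averted: float
    total_cost_savings: float
    total_qaly_gain: float
    sids_deaths_averted: float

    def row(self, condition: str) -> ConditionDelta:
        for r in self.rows:
            if r.condition == condition:
                return r
        raise KeyError(condition)


def _pd_cases_averted(
    incidence: float,
    or_any_hm: float,
    anchoring: str,
    n: float,
    scenario: FeedingScenario,
    base_scenario: FeedingScenario,
) -> float:
    """Expected cases averted when the any-human-milk share moves from the
    base rate to the scenario rate, at fixed arm risks."""
    ors = (or_any_hm, 1.0)  # (any_hm, formula); formula is the reference
    anchor = "population_mix" if anchoring == "population_mix" else "reference"
    risks = arm_risks(incidence, ors, anchor, base_scenario.pd_arm_shares())
    base_mix = float(np.dot(base_scenario.pd_arm_shares(), risks))
    cf_mix = float(np.dot(scenario.pd_arm_shares(), risks))
    return n * (base_mix - cf_mix)


def simple_condition_delta(
    params: PostDischargeOutcomeParams,
    n: float,
    scenario: FeedingScenario,
    base_scenario: FeedingScenario,
    qaly_loss_per_death: float,
) -> ConditionDelta:
    """Acute first-year condition (SIDS or AOM): cost savings are
    undiscounted; a fatal condition (SIDS) converts each case averted into a
    death averted worth the discounted QALYs lost per premature death."""
    cases = _pd_cases_averted(
        params.baseline_incidence,
        params.or_any_hm_vs_formula,
        params.reference_arm,
        n,
        scenario,
        base_scenario,
    )
    deaths = cases if params.is_fatal else 0.0
    return ConditionDelta(
        condition=params.name,
        cases_averted=cases,
        cost_savings=cases * params.cost_per_case,
        qaly_gain=deaths * qaly_loss_per_death,
        deaths_averted=deaths,
    )


def leukaemia_delta(
    params: PostDischargeOutcomeParams,
    n: float,
    scenario: FeedingScenario,
    base_scenario: FeedingScenario,
    discount_rate: float,
    qaly_loss_per_death: float,
    comparator_utility: float = 1.0,
) -> ConditionDelta:
    """Childhood leukaemia: treatment cost is a lump sum discounted from the
    diagnosis age; the per-case QALY gain combines the on-treatment utility
    decrement over the treatment years (discounted from diagnosis) with the
    fatal fraction (1 − survival) valued at the QALYs lost per death."""
    cases = _pd_cases_averted(
        params.baseline_incidence,
        params.or_any_hm_vs_formula,
        params.reference_arm,
        n,
        scenario,
        base_scenario,
    )
    dx = params.diagnosis_age or 0.0
    df = discount_factor(dx, discount_rate)
    cost_per_case = params.cost_per_case * df
    decrement = comparator_utility - (params.on_treatment_utility or 0.0)
    qaly_per_case = (
        decrement * annuity(params.treatment_years or 0.0, discount_rate) * df
        + (1.0 - (params.survival_rate or 1.0)) * qaly_loss_per_death
    )
    return ConditionDelta(
        condition=params.name,
        cases_averted=cases,
        cost_savings=cases * cost_per_case,
        qaly_gain=cases * qaly_per_case,
    )


def obesity_chain_delta(
    params: ObesityChainParams,
    n: float,
    scenario: FeedingScenario,
    base_scenario: FeedingScenario,
    discount_rate: float,
    comparator_utility: float = 1.0,
) -> tuple[ConditionDelta, ConditionDelta]:
    """Childhood obesity chain: obese children averted (two-arm mixture on
    the childhood obesity rate) carry forward to obese adults, then to
    type-2 diabetes and CHD at their prevalences in obese adults. Each
    adult condition pays an annual cost and a utility decrement from its
    diagnosis age to ``end_age``, discounted to birth."""
    if params.t2d_diagnosis_age >= params.end_age or (
        params.chd_diagnosis_age >= params.end_age
    ):
        raise ValueError("diagnosis age must precede end_age")
    obese_children = _pd_cases_averted(
        params.child_obesity_rate,
        params.or_any_hm_vs_formula,
        params.reference_arm,
        n,
        scenario,
        base_scenario,
    )
    obese_adults = obese_children * params.p_obese_adult_given_obese_child
    out = []
    for cond, prevalence, annual_cost, dx_age, utility in (
        ("diabetes", params.t2d_prevalence_in_obese, params.t2d_annual_cost,
         params.t2d_diagnosis_age, params.t2d_utility),
        ("chd", params.chd_prevalence_in_obese, params.chd_annual_cost,
         params.chd_diagnosis_age, params.chd_utility),
    ):
        cases = obese_adults * prevalence
        years = params.end_age - dx_age
        pv = annuity(years, discount_rate) * discount_factor(dx_age, discount_rate)
        cost_per_case = annual_cost * pv
        qaly_per_case = (comparator_utility - utility) * pv
        out.append(
            ConditionDelta(
                condition=cond,
                cases_averted=cases,
                cost_savings=cases * cost_per_case,
                qaly_gain=cases * qaly_per_case,
            )
        )
    return out[0], out[1]


def ndi_delta(
    nicu: NICUDelta,
    ndi: NDIParams,
    config: ModelConfig,
) -> ConditionDelta:
    """Neurodevelopmental impairment driven by NEC/sepsis case changes.

    Per condition and band, each case averted removes an excess NDI
    probability ``apply_or(band NDI incidence, condition NDI OR) − band
    incidence``. NDI cases averted are split across mild/moderate/severe by
    the (renormalised) severity mix. Lifetime costs are present-value lump
    sums; the per-case QALY gain is the healthy discounted QALY stream to
    the healthy life expectancy minus the impaired stream (severity utility
    over the severity life expectancy)."""
    r = config.cohort.discount_rate
    split = ndi.normalised_severity_split()
    ndi_cases = 0.0
    for name in NICU_OUTCOME_ORDER:
        outcome = config.nicu_outcomes[name]
        excess = np.array(
            [apply_or(p, outcome.ndi_or) - p for p in ndi.incidence_by_band]
        )
        ndi_cases += float(nicu.case_deltas_by_band[name] @ excess)
    healthy_qalys = config.comparator_utility * annuity(ndi.healthy_life_expectancy, r)
    cost = 0.0
    qalys = 0.0
    for share, lump, le, u in zip(
        split, ndi.lifetime_cost, ndi.life_expectancy, ndi.utility
    ):
        sev_cases = ndi_cases * share
        cost += sev_cases * lump
        qalys += sev_cases * (healthy_qalys - u * annuity(le, r))
    return ConditionDelta(
        condition="ndi", cases_averted=ndi_cases,
        cost_savings=cost, qaly_gain=qalys,
    )


def _pd_population(config: ModelConfig) -> float:
    """Post-discharge population: the full cohort, or NICU survivors if
    ``survivors_only`` is set (expected survivors under baseline band
    mortality)."""
    n = float(config.cohort.n_preterm)
    if not config.survivors_only:
        return n
    mort = np.asarray(config.mortality.baseline_nicu_mortality_by_band)
    shares = np.asarray(config.cohort.band_shares)
    return n * (1.0 - float(shares @ mort))


def run_postdischarge(
    config: ModelConfig,
    scenario: FeedingScenario | None = None,
    nicu: NICUDelta | None = None,
) -> DeltaReport:
    """The six-row long-term benefits table (SIDS, AOM, leukaemia, NDI,
    diabetes, CHD) comparing the base case against ``scenario`` (default:
    the configured counterfactual)."""
    scenario = scenario or config.counterfactual_scenario
    base = config.base_scenario
    nicu = nicu or compare_nicu(config)
    n = _pd_population(config)
    r = config.cohort.discount_rate
    qpd = config.cohort.qaly_loss_per_death
    cu = config.comparator_utility

    sids = simple_condition_delta(config.postdischarge["sids"], n, scenario, base, qpd)
    aom = simple_condition_delta(config.postdischarge["aom"], n, scenario, base, qpd)
    leuk = leukaemia_delta(
        config.postdischarge["leukaemia"], n, scenario, base, r, qpd, cu
    )
    ndi_row = ndi_delta(nicu, config.ndi, config)
    t2d, chd = obesity_chain_delta(config.obesity, n, scenario, base, r, cu)

    rows = (sids, aom, leuk, ndi_row, t2d, chd)
    assert tuple(row.condition for row in rows) == CONDITION_ORDER
    return DeltaReport(
        base_label=base.label,
        counterfactual_label=scenario.label,
        rows=rows,
        total_cases_averted=sum(row.cases_averted for row in rows),
        total_cost_savings=sum(row.cost_savings for row in rows),
        total_qaly_gain=sum(row.qaly_gain for row in rows),
        sids_deaths_averted=sids.deaths_averted,
    )


def long_term_benefits_frame(report: DeltaReport):
    """The long-term benefits table as a DataFrame (machine precision)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "condition": row.condition,
                "cases_averted": row.cases_averted,
                "total_cost_savings": row.cost_savings,
                "total_qaly_gain": row.qaly_gain,
            }
            for row in report.rows
        ]
    )
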