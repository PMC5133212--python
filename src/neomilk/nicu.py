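"""In-NICU stage: expected NEC/sepsis events, treatment costs, attributable
deaths and death-related QALY losses for a feeding scenario.

The three NICU feeding arms are exclusive human milk / mixed / formula, with
odds ratios anchored to the mixed arm. Costs cover the NICU stay only
(length-of-stay × per-day cost + any fixed tariff); surgical NEC incurs the
full medical-NEC treatment cost on top of its surgical tariff. Deaths are
attributed only through condition (NEC/sepsis) case changes — the excess
death probability of a case is ``apply_or(band mortality, mortality OR) −
band mortality`` — never through a direct feeding→mortality pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    BANDS,
    NICU_ARMS,
    NICU_OUTCOME_ORDER,
    FeedingScenario,
    ModelConfig,
    MortalityParams,
    NICUOutcomeParams,
)
from .risk import apply_or, arm_risks, expected_cases

__all__ = [
    "per_case_cost",
    "nicu_arm_risks_by_band",
    "attributable_deaths",
    "NICUStageResult",
    "NICUDelta",
    "run_nicu",
    "compare_nicu",
]


def per_case_cost(outcome: NICUOutcomeParams, config: ModelConfig) -> float:
    """Treatment cost of one case: los_days × cost_per_day + fixed_cost,
    plus the per-case cost of any outcome named in ``cost_includes``.

    Costs are always computed from their components; the source table's
    printed per-case totals for medical NEC and sepsis are mutually
    transposed and are never read.
    """
    cost = outcome.los_days * outcome.cost_per_day + outcome.fixed_cost
    if outcome.cost_includes is not None:
        cost += per_case_cost(config.nicu_outcomes[outcome.cost_includes], config)
    return cost


def _ors_vs_anchor(outcome: NICUOutcomeParams) -> tuple[float, float, float]:
    """ORs of (exclusive, mixed, formula) against the configured anchor arm."""
    oe, of = outcome.or_exclusive_vs_mixed, outcome.or_formula_vs_mixed
    if outcome.reference_arm in ("mixed_arm", "population_mix"):
        return (oe, 1.0, of)
    if outcome.reference_arm == "formula_arm":
        return (oe / of, 1.0 / of, 1.0)
    raise ValueError(f"unknown reference_arm {outcome.reference_arm!r}")


def nicu_arm_risks_by_band(
    outcome: NICUOutcomeParams, config: ModelConfig
) -> np.ndarray:
    """Risk per band × arm, honouring the outcome's anchoring convention.

    ``population_mix`` anchoring decomposes each band incidence against the
    base-case feeding mix, so arm risks are scenario-invariant and deltas
    arise purely from shifting arm shares.
    """
    ors = _ors_vs_anchor(outcome)
    anchoring = (
        "population_mix" if outcome.reference_arm == "population_mix" else "reference"
    )
    base_shares = config.base_scenario.nicu_arm_shares()
    return np.array(
        [
            arm_risks(p, ors, anchoring, base_shares)
            for p in outcome.incidence_by_band
        ]
    )


def attributable_deaths(
    case_delta_by_band: np.ndarray,
    mortality: MortalityParams,
    outcome: NICUOutcomeParams,
) -> float:
    """Expected deaths averted through a band-resolved change in cases.

    Per band, the excess death probability carried by one case is
    ``apply_or(baseline band mortality, mortality OR) − baseline``; summed
    over bands weighted by the case change.
    """
    deltas = np.asarray(case_delta_by_band, dtype=float)
    excess = np.array(
        [
            apply_or(m, outcome.mortality_or) - m
            for m in mortality.baseline_nicu_mortality_by_band
        ]
    )
    return float(deltas @ excess)


@dataclass(frozen=True)
class NICUStageResult:
    """Expected NICU events and costs for one scenario."""

    scenario_label: str
    #: outcome -> (band × arm) expected case matrix
    cases: dict[str, np.ndarray]
    per_case_cost: dict[str, float]
    total_cost: float

    def cases_by_band(self, outcome: str) -> np.ndarray:
        return self.cases[outcome].sum(axis=1)

    def total_cases(self, outcome: str) -> float:
        return float(self.cases[outcome].sum())


@dataclass(frozen=True)
class NICUDelta:
    """Base-case minus counterfactual NICU stage comparison."""

    base_label: str
    counterfactual_label: str
    #: outcome -> band-resolved cases averted (base − counterfactual)
    case_deltas_by_band: dict[str, np.ndarray]
    cases_averted: dict[str, float]
    cost_savings: dict[str, float]
    total_cost_savings: float
    deaths_averted: dict[str, float]
    deaths_averted_total: float
    qaly_gain: float


def run_nicu(config: ModelConfig, scenario: FeedingScenario) -> NICUStageResult:
    """Expected events and treatment costs for one feeding scenario."""
    n = config.cohort.n_preterm
    band_shares = config.cohort.band_shares
    shares = scenario.nicu_arm_shares()
    cases: dict[str, np.ndarray] = {}
    costs: dict[str, float] = {}
    total = 0.0
    for name in NICU_OUTCOME_ORDER:
        outcome = config.nicu_outcomes[name]
        risks = nicu_arm_risks_by_band(outcome, config)
        mat = expected_cases(n, band_shares, risks, shares)
        cases[name] = mat
        costs[name] = per_case_cost(outcome, config)
        total += mat.sum() * costs[name]
    return NICUStageResult(
        scenario_label=scenario.label, cases=cases,
        per_case_cost=costs, total_cost=total,
    )


def compare_nicu(config: ModelConfig) -> NICUDelta:
    """Compare base case against the counterfactual: cases averted, cost
    savings, deaths averted and the resulting QALY gain (deaths ×
    discounted QALYs lost per premature death)."""
    base = run_nicu(config, config.base_scenario)
    cf = run_nicu(config, config.counterfactual_scenario)
    case_deltas: dict[str, np.ndarray] = {}
    averted: dict[str, float] = {}
    savings: dict[str, float] = {}
    deaths: dict[str, float] = {}
    for name in NICU_OUTCOME_ORDER:
        delta_band = base.cases_by_band(name) - cf.cases_by_band(name)
        case_deltas[name] = delta_band
        averted[name] = float(delta_band.sum())
        savings[name] = averted[name] * base.per_case_cost[name]
        deaths[name] = attributable_deaths(
            delta_band, config.mortality, config.nicu_outcomes[name]
        )
    deaths_total = sum(deaths.values())
    return NICUDelta(
        base_label=base.scenario_label,
        counterfactual_label=cf.scenario_label,
        case_deltas_by_band=case_deltas,
        cases_averted=averted,
        cost_savings=savings,
        total_cost_savings=sum(savings.values()),
        deaths_averted=deaths,
        deaths_averted_total=deaths_total,
        qaly_gain=deaths_total * config.cohort.qaly_loss_per_death,
    )


def nicu_outcomes_frame(result: NICUStageResult):
    """Long-format table of expected cases (outcome × arm × band)."""
    import pandas as pd

    rows = []
    for name in NICU_OUTCOME_ORDER:
        mat = result.cases[name]
        for bi, band in enumerate(BANDS):
            for ai, arm in enumerate(NICU_ARMS):
                rows.append(
                    dict(
                        outcome=name,
                        band=band,
                        arm=arm,
                        expected_cases=mat[bi, ai],
                        per_case_cost=result.per_case_cost[name],
                        cost=mat[bi, ai] * result.per_case_cost[name],
                    )
                )
    return pd.DataFrame(rows)
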