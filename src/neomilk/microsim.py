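"""Individual-level Monte-Carlo validation of the cohort expectation model.

Each simulated infant is drawn from exactly the probabilistic structure the
deterministic engine assumes: birthweight band, NICU feeding arm, Bernoulli
condition events at the band-and-arm risks, then conditional excess-death
and excess-NDI draws per condition case (mirroring the engine's attribution
of deaths and NDI through condition cases), an independent post-discharge
arm, and independent post-discharge condition draws. Event tallies must
agree with the analytic expectations to binomial Monte-Carlo error; that
agreement is the package's central correctness check.

Draw order is fixed (band, NICU arm, then per NICU outcome in
medical-NEC/surgical-NEC/sepsis order: case, excess death, excess NDI +
severity, then post-discharge arm, SIDS, AOM, leukaemia, obese child) and a
single numpy Generator (PCG64) stream is used, so a (config, scenario, n,
seed) tuple is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nicu import nicu_arm_risks_by_band
from .params import (
    NICU_OUTCOME_ORDER,
    PD_CONDITION_ORDER,
    SEVERITIES,
    FeedingScenario,
    ModelConfig,
)
from .risk import apply_or, arm_risks

__all__ = [
    "SimResult",
    "simulate_cohort",
    "analytic_expectations",
    "compare_to_expectation",
    "max_abs_z",
    "random_plausible_config",
]


@dataclass(frozen=True)
class SimResult:
    """Sampled event tallies with binomial standard errors."""

    n_simulated: int
    seed: int
    scenario_label: str
    counts: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)


def _binomial_se(count: float, n: int) -> float:
    p_hat = count / n
    return math.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / n) * n


def _excess_probs(band_probs, odds_ratio) -> np.ndarray:
    ex = np.array([apply_or(p, odds_ratio) - p for p in band_probs])
    if np.any(ex < 0):
        # an OR < 1 removes rather than adds risk; attribution draws need
        # a non-negative excess
        ex = np.clip(ex, 0.0, None)
    return ex


def _pd_risks(config: ModelConfig, incidence: float, odds_ratio: float,
              anchoring: str) -> tuple[float, float]:
    anchor = "population_mix" if anchoring == "population_mix" else "reference"
    return arm_risks(
        incidence, (odds_ratio, 1.0), anchor,
        config.base_scenario.pd_arm_shares(),
    )


def simulate_cohort(
    config: ModelConfig,
    scenario: FeedingScenario,
    n: int,
    seed: int,
) -> SimResult:
    """Simulate ``n`` infants under one feeding scenario."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    band_shares = np.asarray(config.cohort.band_shares, dtype=float)
    arm_shares = np.asarray(scenario.nicu_arm_shares(), dtype=float)
    mort = config.mortality.baseline_nicu_mortality_by_band
    ndi = config.ndi
    split = np.asarray(ndi.normalised_severity_split())

    band = rng.choice(band_shares.size, size=n, p=band_shares)
    arm = rng.choice(arm_shares.size, size=n, p=arm_shares)

    counts: dict[str, float] = {}
    sev_counts = np.zeros(3)
    for name in NICU_OUTCOME_ORDER:
        outcome = config.nicu_outcomes[name]
        risks = nicu_arm_risks_by_band(outcome, config)  # band × arm
        p = risks[band, arm]
        case = rng.random(n) < p
        counts[f"{name}_cases"] = float(case.sum())

        death_excess = _excess_probs(mort, outcome.mortality_or)[band]
        death = case & (rng.random(n) < death_excess)
        counts[f"{name}_attributable_deaths"] = float(death.sum())

        ndi_excess = _excess_probs(ndi.incidence_by_band, outcome.ndi_or)[band]
        ndi_case = case & (rng.random(n) < ndi_excess)
        counts[f"{name}_excess_ndi"] = float(ndi_case.sum())
        k = int(ndi_case.sum())
        if k:
            sev_counts += np.bincount(
                rng.choice(3, size=k, p=split), minlength=3
            )
    for si, sev in enumerate(SEVERITIES):
        counts[f"ndi_{sev}"] = float(sev_counts[si])

    pd_arm = rng.random(n) < scenario.any_hm_rate  # True = any human milk
    for name in PD_CONDITION_ORDER:
        p_cond = config.postdischarge[name]
        p_hm, p_f = _pd_risks(
            config, p_cond.baseline_incidence, p_cond.or_any_hm_vs_formula,
            p_cond.reference_arm,
        )
        p = np.where(pd_arm, p_hm, p_f)
        counts[f"{name}_cases"] = float((rng.random(n) < p).sum())

    ob = config.obesity
    p_hm, p_f = _pd_risks(
        config, ob.child_obesity_rate, ob.or_any_hm_vs_formula, ob.reference_arm
    )
    p = np.where(pd_arm, p_hm, p_f)
    counts["obese_child_cases"] = float((rng.random(n) < p).sum())

    ses = {k: _binomial_se(v, n) for k, v in counts.items()}
    return SimResult(
        n_simulated=n, seed=seed, scenario_label=scenario.label,
        counts=counts, standard_errors=ses,
    )


def analytic_expectations(
    config: ModelConfig, scenario: FeedingScenario, n: int
) -> dict[str, float]:
    """Cohort-engine expectations for the same tallies ``simulate_cohort``
    produces, scaled to ``n`` infants."""
    band_shares = np.asarray(config.cohort.band_shares, dtype=float)
    arm_shares = np.asarray(scenario.nicu_arm_shares(), dtype=float)
    mort = config.mortality.baseline_nicu_mortality_by_band
    ndi = config.ndi
    split = np.asarray(ndi.normalised_severity_split())

    expected: dict[str, float] = {}
    total_ndi_by_band = np.zeros(band_shares.size)
    for name in NICU_OUTCOME_ORDER:
        outcome = config.nicu_outcomes[name]
        risks = nicu_arm_risks_by_band(outcome, config)
        cases_band = n * band_shares * (risks @ arm_shares)  # per band
        expected[f"{name}_cases"] = float(cases_band.sum())
        death_excess = _excess_probs(mort, outcome.mortality_or)
        expected[f"{name}_attributable_deaths"] = float(cases_band @ death_excess)
        ndi_excess = _excess_probs(ndi.incidence_by_band, outcome.ndi_or)
        ndi_band = cases_band * ndi_excess
        expected[f"{name}_excess_ndi"] = float(ndi_band.sum())
        total_ndi_by_band += ndi_band
    total_ndi = float(total_ndi_by_band.sum())
    for si, sev in enumerate(SEVERITIES):
        expected[f"ndi_{sev}"] = total_ndi * split[si]

    pd_shares = np.asarray(scenario.pd_arm_shares(), dtype=float)
    for name in PD_CONDITION_ORDER:
        p_cond = config.postdischarge[name]
        risks2 = _pd_risks(
            config, p_cond.baseline_incidence, p_cond.or_any_hm_vs_formula,
            p_cond.reference_arm,
        )
        expected[f"{name}_cases"] = float(n * np.dot(pd_shares, risks2))
    ob = config.obesity
    risks2 = _pd_risks(
        config, ob.child_obesity_rate, ob.or_any_hm_vs_formula, ob.reference_arm
    )
    expected["obese_child_cases"] = float(n * np.dot(pd_shares, risks2))
    return expected


def compare_to_expectation(
    sim: SimResult, expected: dict[str, float]
) -> dict[str, float]:
    """Per-event z-scores ``(sampled − expected) / SE`` with the binomial SE
    taken at the analytic event probability. A degenerate event (expected
    probability 0 or 1) scores 0 when sampled equals expected, else inf."""
    if set(sim.counts) != set(expected):
        missing = set(sim.counts) ^ set(expected)
        raise ValueError(f"mismatched event sets: {sorted(missing)}")
    n = sim.n_simulated
    z: dict[str, float] = {}
    for key, exp_count in expected.items():
        obs = sim.counts[key]
        p = exp_count / n
        se = math.sqrt(p * (1.0 - p) * n)
        if se == 0.0:
            z[key] = 0.0 if obs == exp_count else math.inf
        else:
            z[key] = (obs - exp_count) / se
    return z


def max_abs_z(z: dict[str, float]) -> float:
    return max(abs(v) for v in z.values())


def random_plausible_config(seed: int) -> ModelConfig:
    """A random valid parameter set for property testing: probabilities on
    wide uniform ranges, odds ratios log-uniform in [0.2, 5] (both protective
    and harmful), costs log-uniform, Dirichlet band shares."""
    from .params import default_config

    rng = np.random.default_rng(seed)
    cfg = default_config()

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    cfg.cohort.band_shares = tuple(rng.dirichlet(np.ones(4)))
    excl = float(rng.uniform(0.05, 0.95))
    any_hm = float(rng.uniform(excl, 1.0))
    cfg.base_scenario = FeedingScenario(
        exclusive_hm_rate=excl, any_hm_rate=any_hm, label="random_base"
    )
    cfg.counterfactual_scenario = FeedingScenario(
        exclusive_hm_rate=1.0, any_hm_rate=1.0, label="counterfactual_100pct"
    )
    for outcome in cfg.nicu_outcomes.values():
        outcome.incidence_by_band = tuple(rng.uniform(0.001, 0.4, size=4))
        outcome.or_exclusive_vs_mixed = lu(0.2, 5.0)
        outcome.or_formula_vs_mixed = lu(0.2, 5.0)
        outcome.mortality_or = lu(1.0, 5.0)
        outcome.ndi_or = lu(1.0, 5.0)
        outcome.cost_per_day = lu(100, 2000)
    cfg.mortality.baseline_nicu_mortality_by_band = tuple(
        rng.uniform(0.01, 0.3, size=4)
    )
    for p_cond in cfg.postdischarge.values():
        p_cond.baseline_incidence = float(rng.uniform(0.0002, 0.05))
        p_cond.or_any_hm_vs_formula = lu(0.2, 5.0)
        p_cond.cost_per_case = lu(20, 200_000)
    cfg.obesity.child_obesity_rate = float(rng.uniform(0.02, 0.3))
    cfg.obesity.or_any_hm_vs_formula = lu(0.2, 5.0)
    cfg.ndi.incidence_by_band = tuple(rng.uniform(0.05, 0.6, size=4))
    return cfg


def microsim_report_frame(sim: SimResult, expected: dict[str, float]):
    """Event-level comparison table (event, expected, sampled, SE, z)."""
    import pandas as pd

    z = compare_to_expectation(sim, expected)
    return pd.DataFrame(
        [
            {
                "event": k,
                "expected": expected[k],
                "sampled": sim.counts[k],
                "se": sim.standard_errors[k],
                "z": z[k],
            }
            for k in sim.counts
        ]
    )
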