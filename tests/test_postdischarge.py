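"""Post-discharge conditions: mixture deltas, discounting, NDI linkage."""

import numpy as np
import pytest
from scipy.optimize import brentq

from neomilk import (
    compare_nicu,
    default_config,
    leukaemia_delta,
    ndi_delta,
    obesity_chain_delta,
    run_postdischarge,
    simple_condition_delta,
)
from neomilk.postdischarge import CONDITION_ORDER


def _mixture_solve(p_pop, share_hm, odds_ratio):
    """Independent spreadsheet-style oracle for the two-arm decomposition."""

    def apply(p, o):
        odds = o * p / (1 - p)
        return odds / (1 + odds)

    p_f = brentq(
        lambda p: share_hm * apply(p, odds_ratio) + (1 - share_hm) * p - p_pop,
        1e-15, 1 - 1e-15, xtol=1e-16,
    )
    return apply(p_f, odds_ratio), p_f


class TestSimpleConditions:
    def test_or_one_gives_zero_delta(self, config):
        sids = config.postdischarge["sids"].model_copy()
        sids.or_any_hm_vs_formula = 1.0
        delta = simple_condition_delta(
            sids, 51703, config.counterfactual_scenario,
            config.base_scenario, 23.6,
        )
        assert delta.cases_averted == pytest.approx(0.0, abs=1e-9)
        assert delta.cost_savings == pytest.approx(0.0, abs=1e-7)

    def test_sids_cases_averted_matches_mixture_oracle(self, config):
        # 35% → 100% any human milk on incidence 0.0007 with OR 0.4
        p_hm, p_f = _mixture_solve(0.0007, 0.35, 0.4)
        expected = 51703 * 0.65 * (p_f - p_hm)
        delta = simple_condition_delta(
            config.postdischarge["sids"], 51703,
            config.counterfactual_scenario, config.base_scenario, 23.6,
        )
        assert delta.cases_averted == pytest.approx(expected, rel=1e-9)
        assert delta.cases_averted == pytest.approx(17.859, abs=5e-3)

    def test_each_sids_death_carries_the_discounted_qaly_constant(self, config):
        delta = simple_condition_delta(
            config.postdischarge["sids"], 51703,
            config.counterfactual_scenario, config.base_scenario, 23.6,
        )
        assert delta.deaths_averted == delta.cases_averted
        assert delta.qaly_gain == pytest.approx(delta.cases_averted * 23.6)

    def test_aom_carries_no_qalys(self, config):
        delta = simple_condition_delta(
            config.postdischarge["aom"], 51703,
            config.counterfactual_scenario, config.base_scenario, 23.6,
        )
        assert delta.qaly_gain == 0.0
        assert delta.deaths_averted == 0.0
        assert delta.cost_savings == pytest.approx(delta.cases_averted * 46.0)


class TestLeukaemia:
    def test_no_harm_limit_zero_qalys(self, config):
        leuk = config.postdischarge["leukaemia"].model_copy()
        leuk.survival_rate = 1.0
        leuk.on_treatment_utility = 1.0
        delta = leukaemia_delta(
            leuk, 51703, config.counterfactual_scenario,
            config.base_scenario, 0.035, 23.6, comparator_utility=1.0,
        )
        assert delta.qaly_gain == pytest.approx(0.0, abs=1e-12)

    def test_undiscounted_per_case_qaly_arithmetic(self, config):
        # r=0, diagnosis 5 y, 2 y on treatment at utility 0.66 vs norm 1.0,
        # 8% fatal: per-case QALY = 2 × 0.34 + 0.08 × 23.6 = 2.568
        leuk = config.postdischarge["leukaemia"]
        delta = leukaemia_delta(
            leuk, 51703, config.counterfactual_scenario,
            config.base_scenario, 0.0, 23.6, comparator_utility=1.0,
        )
        assert delta.qaly_gain / delta.cases_averted == pytest.approx(2.568)

    def test_or_one_gives_zero_delta(self, config):
        leuk = config.postdischarge["leukaemia"].model_copy()
        leuk.or_any_hm_vs_formula = 1.0
        delta = leukaemia_delta(
            leuk, 51703, config.counterfactual_scenario,
            config.base_scenario, 0.035, 23.6,
        )
        assert delta.cases_averted == pytest.approx(0.0, abs=1e-9)

    def test_cost_discounted_from_diagnosis_age(self, config):
        leuk = config.postdischarge["leukaemia"]
        delta = leukaemia_delta(
            leuk, 51703, config.counterfactual_scenario,
            config.base_scenario, 0.035, 23.6,
        )
        per_case = delta.cost_savings / delta.cases_averted
        assert per_case == pytest.approx(114_456 * 1.035 ** -5, rel=1e-12)


class TestObesityChain:
    def test_or_one_zeroes_both_conditions(self, config):
        ob = config.obesity.model_copy()
        ob.or_any_hm_vs_formula = 1.0
        t2d, chd = obesity_chain_delta(
            ob, 51703, config.counterfactual_scenario,
            config.base_scenario, 0.035,
        )
        assert t2d.cases_averted == pytest.approx(0.0, abs=1e-9)
        assert chd.cases_averted == pytest.approx(0.0, abs=1e-9)

    def test_t2d_per_case_cost_annuity_and_discount(self, config):
        # £787/y over 20 y from age 55: 787 × annuity(20) × 1.035^-55,
        # verified against an explicit year-by-year summation
        t2d, _ = obesity_chain_delta(
            config.obesity, 51703, config.counterfactual_scenario,
            config.base_scenario, 0.035,
        )
        per_case = t2d.cost_savings / t2d.cases_averted
        explicit = sum(787 * 1.035 ** -(55 + t) for t in range(1, 21))
        assert per_case == pytest.approx(explicit, rel=1e-12)
        assert per_case == pytest.approx(1686.25, abs=0.01)

    def test_zero_utility_decrement_means_zero_qalys(self, config):
        ob = config.obesity.model_copy()
        _, chd = obesity_chain_delta(
            ob, 51703, config.counterfactual_scenario,
            config.base_scenario, 0.035, comparator_utility=0.867,
        )
        assert chd.qaly_gain == pytest.approx(0.0, abs=1e-9)

    def test_diagnosis_after_end_age_is_an_error(self, config):
        ob = config.obesity.model_copy()
        ob.t2d_diagnosis_age = 80.0
        with pytest.raises(ValueError):
            obesity_chain_delta(
                ob, 51703, config.counterfactual_scenario,
                config.base_scenario, 0.035,
            )


class TestNDI:
    def test_or_one_gives_zero_delta(self):
        nicu = compare_nicu(default_config())
        cfg = default_config()
        for outcome in cfg.nicu_outcomes.values():
            outcome.ndi_or = 1.0
        delta = ndi_delta(nicu, cfg.ndi, cfg)
        assert delta.cases_averted == pytest.approx(0.0, abs=1e-9)

    def test_severe_per_case_qaly_loss_undiscounted(self, config):
        # r = 0: healthy 78.5 y at utility 1 vs 26.1 y at 0.47 → 66.233
        config.cohort.discount_rate = 0.0
        nicu = compare_nicu(config)
        ndi = config.ndi.model_copy()
        ndi.severity_split = (0.0, 0.0, 1.0)  # severe only
        delta = ndi_delta(nicu, ndi, config)
        per_case = delta.qaly_gain / delta.cases_averted
        assert per_case == pytest.approx(78.5 - 0.47 * 26.1, rel=1e-12)

    def test_cases_linked_to_nicu_condition_deltas(self, config):
        nicu = compare_nicu(config)
        delta = ndi_delta(nicu, config.ndi, config)
        # independent recomputation over conditions × bands
        brute = 0.0
        for name, outcome in config.nicu_outcomes.items():
            for b, inc in enumerate(config.ndi.incidence_by_band):
                odds = outcome.ndi_or * inc / (1 - inc) if inc < 1 else np.inf
                shifted = odds / (1 + odds)
                brute += nicu.case_deltas_by_band[name][b] * (shifted - inc)
        assert delta.cases_averted == pytest.approx(brute, rel=1e-12)


class TestReport:
    def test_null_config_gives_six_zero_rows(self, null_config):
        report = run_postdischarge(null_config)
        assert len(report.rows) == 6
        for row in report.rows:
            assert row.cases_averted == pytest.approx(0.0, abs=1e-9)
            assert row.qaly_gain == pytest.approx(0.0, abs=1e-7)

    def test_row_order_is_fixed(self, config):
        report = run_postdischarge(config)
        assert tuple(r.condition for r in report.rows) == CONDITION_ORDER

    def test_totals_equal_row_sums(self, config):
        report = run_postdischarge(config)
        assert report.total_cost_savings == pytest.approx(
            sum(r.cost_savings for r in report.rows), rel=1e-12
        )
        assert report.total_qaly_gain == pytest.approx(
            sum(r.qaly_gain for r in report.rows), rel=1e-12
        )

    def test_equal_scenarios_zero_all_deltas(self, config):
        config.counterfactual_scenario = config.base_scenario.model_copy()
        report = run_postdischarge(config)
        for row in report.rows:
            if row.condition == "ndi":
                continue  # driven by NICU arms, also zero
            assert row.cases_averted == pytest.approx(0.0, abs=1e-9)
        assert report.row("ndi").cases_averted == pytest.approx(0.0, abs=1e-9)

    def test_discounted_quantities_decrease_with_rate(self, config):
        low = default_config()
        high = default_config()
        low.cohort.discount_rate = 0.01
        high.cohort.discount_rate = 0.07
        r_low = run_postdischarge(low)
        r_high = run_postdischarge(high)
        for cond in ("leukaemia", "diabetes", "chd"):
            low_pc = r_low.row(cond).cost_savings / r_low.row(cond).cases_averted
            high_pc = r_high.row(cond).cost_savings / r_high.row(cond).cases_averted
            assert high_pc < low_pc
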