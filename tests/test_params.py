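"""Parameter defaults, validation and serialisation round-trips."""

import math

import pytest
import yaml

from neomilk import (
    ConfigError,
    default_config,
    load_config,
    save_config,
    validate,
)
from neomilk.params import export_csv

# every published scalar input and where it lives in the config
PUBLISHED_DEFAULTS = [
    ("cohort.n_preterm", 51703),
    ("cohort.discount_rate", 0.035),
    ("cohort.wtp_per_qaly", 20_000.0),
    ("cohort.lifetime_earnings_low", 540_500.0),
    ("cohort.lifetime_earnings_mid", 645_500.0),
    ("cohort.lifetime_earnings_high", 750_500.0),
    ("cohort.qaly_loss_per_death", 23.6),
    ("base_scenario.exclusive_hm_rate", 0.35),
    ("base_scenario.any_hm_rate", 0.35),
    ("counterfactual_scenario.exclusive_hm_rate", 1.0),
    ("nicu_outcomes.medical_nec.incidence_by_band.0", 0.035),
    ("nicu_outcomes.medical_nec.incidence_by_band.1", 0.021),
    ("nicu_outcomes.medical_nec.incidence_by_band.2", 0.005),
    ("nicu_outcomes.medical_nec.or_exclusive_vs_mixed", 0.412),
    ("nicu_outcomes.medical_nec.or_formula_vs_mixed", 3.006),
    ("nicu_outcomes.medical_nec.los_days", 27.2),
    ("nicu_outcomes.medical_nec.cost_per_day", 630.08),
    ("nicu_outcomes.medical_nec.mortality_or", 2.055),
    ("nicu_outcomes.medical_nec.ndi_or", 1.187),
    ("nicu_outcomes.surgical_nec.incidence_by_band.0", 0.033),
    ("nicu_outcomes.surgical_nec.incidence_by_band.1", 0.006),
    ("nicu_outcomes.surgical_nec.incidence_by_band.2", 0.001),
    ("nicu_outcomes.surgical_nec.fixed_cost", 1739.0),
    ("nicu_outcomes.surgical_nec.mortality_or", 3.124),
    ("nicu_outcomes.surgical_nec.ndi_or", 1.985),
    ("nicu_outcomes.sepsis.incidence_by_band.0", 0.272),
    ("nicu_outcomes.sepsis.incidence_by_band.1", 0.082),
    ("nicu_outcomes.sepsis.incidence_by_band.2", 0.047),
    ("nicu_outcomes.sepsis.or_exclusive_vs_mixed", 0.707),
    ("nicu_outcomes.sepsis.or_formula_vs_mixed", 0.803),
    ("nicu_outcomes.sepsis.los_days", 5.9),
    ("nicu_outcomes.sepsis.mortality_or", 3.219),
    ("nicu_outcomes.sepsis.ndi_or", 2.282),
    ("mortality.baseline_nicu_mortality_by_band.0", 0.205),
    ("mortality.baseline_nicu_mortality_by_band.1", 0.08),
    ("mortality.baseline_nicu_mortality_by_band.2", 0.05),
    ("postdischarge.sids.baseline_incidence", 0.0007),
    ("postdischarge.sids.or_any_hm_vs_formula", 0.40),
    ("postdischarge.sids.cost_per_case", 72.0),
    ("postdischarge.aom.baseline_incidence", 0.0014),
    ("postdischarge.aom.or_any_hm_vs_formula", 0.40),
    ("postdischarge.aom.cost_per_case", 46.0),
    ("postdischarge.leukaemia.baseline_incidence", 0.0004),
    ("postdischarge.leukaemia.or_any_hm_vs_formula", 0.91),
    ("postdischarge.leukaemia.cost_per_case", 114_456.0),
    ("postdischarge.leukaemia.survival_rate", 0.92),
    ("postdischarge.leukaemia.on_treatment_utility", 0.66),
    ("obesity.child_obesity_rate", 0.095),
    ("obesity.or_any_hm_vs_formula", 0.79),
    ("obesity.p_obese_adult_given_obese_child", 0.65),
    ("obesity.t2d_prevalence_in_obese", 0.0961),
    ("obesity.chd_prevalence_in_obese", 0.0604),
    ("obesity.t2d_annual_cost", 787.0),
    ("obesity.chd_annual_cost", 1974.0),
    ("obesity.t2d_diagnosis_age", 55.0),
    ("obesity.chd_diagnosis_age", 65.0),
    ("obesity.end_age", 75.0),
    ("obesity.t2d_utility", 0.866),
    ("obesity.chd_utility", 0.867),
    ("ndi.incidence_by_band.0", 0.49),
    ("ndi.incidence_by_band.1", 0.41),
    ("ndi.incidence_by_band.2", 0.34),
    ("ndi.severity_split.0", 0.65),
    ("ndi.severity_split.1", 0.22),
    ("ndi.severity_split.2", 0.14),
    ("ndi.lifetime_cost.0", 14_421.0),
    ("ndi.lifetime_cost.1", 13_959.0),
    ("ndi.lifetime_cost.2", 365_005.0),
    ("ndi.life_expectancy.0", 78.5),
    ("ndi.life_expectancy.1", 67.8),
    ("ndi.life_expectancy.2", 26.1),
    ("ndi.utility.0", 0.85),
    ("ndi.utility.1", 0.645),
    ("ndi.utility.2", 0.47),
]


@pytest.mark.parametrize("path,expected", PUBLISHED_DEFAULTS,
                         ids=[p for p, _ in PUBLISHED_DEFAULTS])
def test_default_value(config, path, expected):
    from neomilk.dsa import resolve_path

    assert resolve_path(config, path) == expected


def test_defaults_are_self_consistent(config):
    assert validate(config) == []


def test_severity_split_renormalised(config):
    split = config.ndi.normalised_severity_split()
    assert math.isclose(sum(split), 1.0, abs_tol=1e-12)
    assert split[0] == pytest.approx(0.65 / 1.01)
    assert split[2] == pytest.approx(0.14 / 1.01)


def test_band_shares_sum_violation_reported(config):
    config.cohort.band_shares = (0.04, 0.10, 0.36, 0.40)
    issues = validate(config)
    assert len(issues) == 1 and "band_shares" in issues[0]


def test_scenario_rate_ordering_violation_reported(config):
    config.base_scenario.exclusive_hm_rate = 0.5
    config.base_scenario.any_hm_rate = 0.3
    issues = validate(config)
    assert len(issues) == 1 and "exclusive_hm_rate" in issues[0]


def test_negative_cost_and_bad_or_reported(config):
    config.nicu_outcomes["sepsis"].cost_per_day = -1.0
    config.postdischarge["sids"].or_any_hm_vs_formula = 0.0
    issues = validate(config)
    assert any("sepsis.cost_per_day" in i for i in issues)
    assert any("sids.or_any_hm_vs_formula" in i for i in issues)


def test_roundtrip_is_lossless(config, tmp_path):
    path = tmp_path / "cfg.yaml"
    save_config(config, path)
    assert load_config(path) == config


def test_shipped_default_file_matches_code_defaults():
    import neomilk

    from importlib import resources

    with resources.as_file(
        resources.files("neomilk") / "params_default.yaml"
    ) as path:
        assert load_config(path) == default_config()


def test_missing_required_key_names_it(tmp_path):
    data = default_config().model_dump()
    del data["cohort"]["n_preterm"]
    path = tmp_path / "broken.yaml"
    path.write_text(yaml.safe_dump(data))
    with pytest.raises(ConfigError, match="n_preterm"):
        load_config(path)


def test_unknown_key_rejected(tmp_path):
    data = default_config().model_dump()
    data["cohort"]["unexpected_key"] = 1
    path = tmp_path / "extra.yaml"
    path.write_text(yaml.safe_dump(data))
    with pytest.raises(ConfigError):
        load_config(path)


def test_numeric_text_coerced_with_warning(tmp_path, caplog):
    data = default_config().model_dump()
    data["base_scenario"]["exclusive_hm_rate"] = "0.35"
    path = tmp_path / "coerce.yaml"
    path.write_text(yaml.safe_dump(data))
    with caplog.at_level("WARNING", logger="neomilk"):
        cfg = load_config(path)
    assert cfg.base_scenario.exclusive_hm_rate == 0.35
    assert any("coerced" in rec.message for rec in caplog.records)


def test_malformed_yaml_raises_parse_error(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("cohort: [unclosed")
    with pytest.raises(ConfigError, match="parse"):
        load_config(path)


def test_csv_export_contains_every_scalar(config, tmp_path):
    import pandas as pd

    path = tmp_path / "params.csv"
    export_csv(config, path)
    table = pd.read_csv(path).set_index("parameter")["value"]
    assert float(table["cohort.n_preterm"]) == 51703
    assert float(table["ndi.lifetime_cost.2"]) == 365_005.0
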