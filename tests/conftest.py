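import pytest

from neomilk import default_config


@pytest.fixture()
def config():
    return default_config()


@pytest.fixture()
def null_config():
    """Defaults with every treatment-effect odds ratio forced to 1, so the
    counterfactual scenario can change nothing."""
    cfg = default_config()
    for outcome in cfg.nicu_outcomes.values():
        outcome.or_exclusive_vs_mixed = 1.0
        outcome.or_formula_vs_mixed = 1.0
        outcome.mortality_or = 1.0
        outcome.ndi_or = 1.0
    for cond in cfg.postdischarge.values():
        cond.or_any_hm_vs_formula = 1.0
    cfg.obesity.or_any_hm_vs_formula = 1.0
    return cfg
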