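#!/usr/bin/env python
"""Run the cohort model under the shipped defaults: base case (35% human
milk in the NICU) vs the 100% counterfactual.

Writes to results/: nicu_outcomes.csv (expected events per outcome × arm ×
band, both scenarios), long_term_benefits.csv (the six post-discharge
condition deltas), summary.json / summary_table.csv, manifest.json, and
prints the headline totals.
"""

from pathlib import Path

from neomilk import build_summary, compare_nicu, run_postdischarge, default_config
from neomilk.cli import cmd_run

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cmd_run(config=None, out=OUT, verbose=False)

    cfg = default_config()
    nicu = compare_nicu(cfg)
    post = run_postdischarge(cfg, nicu=nicu)
    s = build_summary(nicu, post, cfg)
    print(
        f"\nNICU stage: {sum(nicu.cases_averted.values()):.0f} cases averted "
        f"(medical NEC {nicu.cases_averted['medical_nec']:.0f}, surgical NEC "
        f"{nicu.cases_averted['surgical_nec']:.0f}, sepsis "
        f"{nicu.cases_averted['sepsis']:.0f}); £{s.first_year_savings/1e6:.1f}M "
        f"saved; {s.deaths_averted_infections:.1f} deaths averted."
    )
    print(
        f"Post-discharge: £{s.postdischarge_savings/1e6:.1f}M saved, "
        f"{s.postdischarge_qaly_gain:.0f} QALYs gained; SIDS deaths averted "
        f"{s.deaths_averted_sids:.1f}."
    )
    print(
        f"Lifetime: £{s.lifetime_savings/1e6:.1f}M savings, "
        f"{s.total_qaly_gain:.0f} QALYs "
        f"(£{s.per_infant['lifetime_savings']:.0f} and "
        f"{s.per_infant['total_qaly_gain']:.3f} QALYs per infant); "
        f"net monetary value £{s.total_net_monetary_value/1e6:.1f}M; "
        f"productivity preserved £{s.productivity_loss_averted/1e6:.1f}M."
    )
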