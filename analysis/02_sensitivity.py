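#!/usr/bin/env python
"""One-way deterministic sensitivity analysis of the total cohort cost
savings over the default ±20% ranges (odds ratios varied log-symmetrically).

Writes results/tornado.csv and results/tornado.png and prints the widest
bars. The sepsis and NEC feeding odds ratios are expected to dominate.
"""

from pathlib import Path

from neomilk import default_config, default_ranges, one_way
from neomilk.dsa import tornado_figure

OUT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cfg = default_config()
    table = one_way(cfg, default_ranges(cfg), metric="total_cost_savings")
    OUT.mkdir(exist_ok=True)
    table.frame().to_csv(OUT / "tornado.csv", index=False)
    tornado_figure(table, OUT / "tornado.png")
    print(f"base total cost savings: £{table.metric_at_base/1e6:.2f}M")
    print("widest bars:")
    for e in table.entries[:8]:
        print(f"  {e.parameter:70s} spread £{e.spread/1e6:6.2f}M")
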