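"""One-way deterministic sensitivity analysis (tornado diagram).

Each parameter is set to its low and high bound in turn (all else at base
values), the full model is rerun, and the chosen summary metric recorded;
entries are ordered by spread, widest first. Published dispersion (95 %
confidence intervals) is not available for most inputs, so the default
ranges are ±20 % of the base value, with odds ratios varied symmetrically
on the log scale (low = OR × 0.8, high = OR / 0.8) to respect positivity;
ranges are labelled with their provenance (``ci95`` vs ``pct20_default``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .params import ModelConfig, ParamRange

__all__ = [
    "TornadoEntry",
    "TornadoTable",
    "resolve_path",
    "set_path",
    "default_ranges",
    "one_way",
]


def _get(node, part: str, path: str):
    if isinstance(node, dict):
        if part not in node:
            raise AttributeError(f"no key {part!r} in path {path!r}")
        return node[part]
    if isinstance(node, (list, tuple)):
        if not part.isdigit() or int(part) >= len(node):
            raise AttributeError(f"bad index {part!r} in path {path!r}")
        return node[int(part)]
    if not hasattr(node, part):
        raise AttributeError(f"no field {part!r} in path {path!r}")
    return getattr(node, part)


def resolve_path(config: ModelConfig, path: str) -> float:
    """Read a scalar parameter by dotted path, e.g.
    ``nicu_outcomes.sepsis.or_exclusive_vs_mixed`` or ``ndi.lifetime_cost.2``.

    A ``+``-joined path addresses one model parameter stored in several
    fields (the NEC feeding odds ratios are declared once, "as for medical
    NEC", but live on both NEC outcomes): all components must agree, and
    the shared value is returned.
    """
    values = []
    for single in path.split("+"):
        node = config
        for part in single.split("."):
            node = _get(node, part, path)
        values.append(node)
    if len(set(values)) > 1:
        raise ValueError(f"linked path {path!r} has diverging values {values}")
    return values[0]


def set_path(config: ModelConfig, path: str, value: float) -> None:
    """Set a scalar parameter by dotted path (in place); a tuple element is
    replaced by rebuilding the tuple on its parent. A ``+``-joined linked
    path sets every component field."""
    if "+" in path:
        for single in path.split("+"):
            set_path(config, single, value)
        return
    parts = path.split(".")
    chain = [config]
    for part in parts[:-1]:
        chain.append(_get(chain[-1], part, path))
    _get(chain[-1], parts[-1], path)  # raise before mutating on a bad leaf

    def assign(container, key: str, val):
        if isinstance(container, dict):
            container[key] = val
        elif isinstance(container, tuple):
            new = list(container)
            new[int(key)] = val
            return tuple(new)
        elif isinstance(container, list):
            container[int(key)] = val
        else:
            setattr(container, key, val)
        return None

    val = value
    for depth in range(len(chain) - 1, -1, -1):
        replaced = assign(chain[depth], parts[depth], val)
        if replaced is None:
            return
        val = replaced  # immutable container rebuilt; push up one level


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    source: str
    low: float
    high: float
    metric_at_low: float
    metric_at_high: float
    error: str | None = None

    @property
    def spread(self) -> float:
        return abs(self.metric_at_high - self.metric_at_low)


@dataclass(frozen=True)
class TornadoTable:
    metric: str
    metric_at_base: float
    entries: tuple[TornadoEntry, ...]  # sorted by spread desc, path asc

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "source": e.source,
                    "low": e.low,
                    "high": e.high,
                    "metric_at_low": e.metric_at_low,
                    "metric_at_high": e.metric_at_high,
                    "spread": e.spread,
                    "error": e.error or "",
                }
                for e in self.entries
            ],
            columns=[
                "parameter", "source", "low", "high",
                "metric_at_low", "metric_at_high", "spread", "error",
            ],
        )


# the NEC feeding odds ratios are a single parameter applied to both NEC
# severities (the surgical row declares them "as for medical NEC"), hence
# the linked "+" paths; mortality and NDI ORs genuinely differ per outcome
_OR_PATHS = tuple(
    "nicu_outcomes.medical_nec.{f}+nicu_outcomes.surgical_nec.{f}".format(f=f)
    for f in ("or_exclusive_vs_mixed", "or_formula_vs_mixed")
) + tuple(
    f"nicu_outcomes.sepsis.{f}"
    for f in ("or_exclusive_vs_mixed", "or_formula_vs_mixed")
) + tuple(
    f"nicu_outcomes.{o}.{f}"
    for o in ("medical_nec", "surgical_nec", "sepsis")
    for f in ("mortality_or", "ndi_or")
) + tuple(
    f"postdischarge.{c}.or_any_hm_vs_formula" for c in ("sids", "aom", "leukaemia")
) + ("obesity.or_any_hm_vs_formula",)

_COST_PATHS = (
    "nicu_outcomes.medical_nec.cost_per_day",
    "nicu_outcomes.sepsis.cost_per_day",
    "nicu_outcomes.surgical_nec.fixed_cost",
    "postdischarge.sids.cost_per_case",
    "postdischarge.aom.cost_per_case",
    "postdischarge.leukaemia.cost_per_case",
    "obesity.t2d_annual_cost",
    "obesity.chd_annual_cost",
    "ndi.lifetime_cost.0",
    "ndi.lifetime_cost.1",
    "ndi.lifetime_cost.2",
)


def default_ranges(config: ModelConfig) -> list[ParamRange]:
    """±20 % ranges over every odds ratio (log-symmetric) and unit cost."""
    ranges: list[ParamRange] = []
    for path in _OR_PATHS:
        base = resolve_path(config, path)
        ranges.append(ParamRange(path=path, low=base * 0.8, high=base / 0.8,
                                 source="pct20_default"))
    for path in _COST_PATHS:
        base = resolve_path(config, path)
        ranges.append(ParamRange(path=path, low=base * 0.8, high=base * 1.2,
                                 source="pct20_default"))
    return ranges


def _run_metric(config: ModelConfig, metric: str) -> float:
    from .econ import build_summary
    from .nicu import compare_nicu
    from .postdischarge import run_postdischarge

    nicu = compare_nicu(config)
    post = run_postdischarge(config, nicu=nicu)
    summary = build_summary(nicu, post, config)
    if metric == "total_cost_savings":  # common alias
        return summary.lifetime_savings
    if not hasattr(summary, metric):
        raise AttributeError(f"SummaryReport has no metric {metric!r}")
    return getattr(summary, metric)


def one_way(
    config: ModelConfig,
    ranges: Sequence[ParamRange],
    metric: str = "total_cost_savings",
) -> TornadoTable:
    """Run the one-way DSA; the base config is never mutated, a failed entry
    (e.g. a bound outside the parameter's domain) is recorded with its error
    and the run continues."""
    from .params import validate

    base_value = _run_metric(config.model_copy(deep=True), metric)
    entries: list[TornadoEntry] = []
    for rng_ in ranges:
        metrics = {}
        err = None
        for bound_name, bound in (("low", rng_.low), ("high", rng_.high)):
            trial = config.model_copy(deep=True)
            try:
                set_path(trial, rng_.path, bound)
                issues = validate(trial)
                if issues:
                    raise ValueError("; ".join(issues))
                metrics[bound_name] = _run_metric(trial, metric)
            except (AttributeError, ValueError) as exc:
                err = f"{bound_name}={bound!r}: {exc}"
                metrics[bound_name] = float("nan")
                break
        entries.append(
            TornadoEntry(
                parameter=rng_.path,
                source=rng_.source,
                low=rng_.low,
                high=rng_.high,
                metric_at_low=metrics.get("low", float("nan")),
                metric_at_high=metrics.get("high", float("nan")),
                error=err,
            )
        )
    ok = [e for e in entries if e.error is None]
    bad = [e for e in entries if e.error is not None]
    ok.sort(key=lambda e: (-e.spread, e.parameter))
    return TornadoTable(
        metric=metric, metric_at_base=base_value, entries=tuple(ok + bad)
    )


def tornado_figure(table: TornadoTable, path) -> None:
    """Horizontal-bar tornado plot of the table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = [e for e in table.entries if e.error is None][::-1]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.35 * len(entries))))
    base = table.metric_at_base
    for i, e in enumerate(entries):
        lo, hi = sorted((e.metric_at_low, e.metric_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878cf", alpha=0.8)
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in entries], fontsize=7)
    ax.set_xlabel(table.metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
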