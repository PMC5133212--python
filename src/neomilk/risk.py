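"""Odds-ratio probability algebra and feeding-arm risk decomposition.

The model represents every treatment effect as an odds ratio applied to a
reference probability on the odds scale (exact, not the rare-event
approximation): ``odds(p_arm) = OR × odds(p_ref)``. A published population
incidence can be anchored to one arm directly or decomposed into arm-specific
risks whose share-weighted mixture reproduces the population rate
(``population_mix`` anchoring), solved by monotone bracketing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "apply_or",
    "ArmRiskSet",
    "decompose_population_risk",
    "arm_risks",
    "expected_cases",
    "InfeasibleMixtureError",
]

_SOLVER_XTOL = 1e-14


class InfeasibleMixtureError(ValueError):
    """No reference probability in [0, 1] reproduces the population rate."""


def apply_or(p_ref: float, odds_ratio: float) -> float:
    """Shift a probability by an odds ratio on the odds scale.

    Returns the probability ``p`` with ``odds(p) = odds_ratio × odds(p_ref)``.
    Strictly monotone in both arguments; ``apply_or(p, 1) == p`` and
    ``apply_or(0, anything) == 0``. ``p_ref == 1`` has infinite odds and maps
    to 1 for any finite positive odds ratio.
    """
    if not 0.0 <= p_ref <= 1.0:
        raise ValueError(f"p_ref={p_ref!r} outside [0, 1]")
    if not odds_ratio > 0.0:
        raise ValueError(f"odds_ratio={odds_ratio!r} must be > 0")
    if p_ref == 1.0:
        return 1.0
    odds = odds_ratio * p_ref / (1.0 - p_ref)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class ArmRiskSet:
    """Per-arm event probabilities plus the reference anchor they satisfy."""

    risks: tuple[float, ...]
    ors_vs_reference: tuple[float, ...]
    reference_risk: float
    reference_arm: str


def decompose_population_risk(
    p_pop: float,
    arm_shares: Sequence[float],
    ors_vs_reference: Sequence[float],
) -> ArmRiskSet:
    """Split a population incidence into arm-specific risks.

    Finds the reference-arm probability ``p_ref`` such that
    ``Σ share_i × apply_or(p_ref, OR_i) == p_pop`` (the arm with OR 1 is the
    reference), by bracketing on [0, 1] to |residual| < 1e-12. When one arm
    holds the whole population, its risk equals ``p_pop`` exactly.
    """
    shares = np.asarray(arm_shares, dtype=float)
    ors = tuple(float(o) for o in ors_vs_reference)
    if len(shares) != len(ors):
        raise ValueError("arm_shares and ors_vs_reference differ in length")
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError(f"arm shares sum to {shares.sum():.12g}, not 1")
    if not 0.0 <= p_pop <= 1.0:
        raise ValueError(f"p_pop={p_pop!r} outside [0, 1]")

    def mixture(p_ref: float) -> float:
        return float(sum(s * apply_or(p_ref, o) for s, o in zip(shares, ors)))

    if p_pop in (0.0, 1.0):
        p_ref = p_pop
    else:
        lo, hi = mixture(0.0) - p_pop, mixture(1.0) - p_pop
        if lo > 0 or hi < 0:
            raise InfeasibleMixtureError(
                f"no reference risk in [0, 1] reproduces p_pop={p_pop} "
                f"with ORs {ors}"
            )
        p_ref = brentq(lambda p: mixture(p) - p_pop, 0.0, 1.0,
                       xtol=_SOLVER_XTOL, maxiter=200)
    risks = tuple(apply_or(p_ref, o) for o in ors)
    return ArmRiskSet(risks=risks, ors_vs_reference=ors,
                      reference_risk=p_ref, reference_arm="reference")


def arm_risks(
    incidence: float,
    ors_vs_reference: Sequence[float],
    anchoring: str,
    base_shares: Sequence[float] | None = None,
) -> tuple[float, ...]:
    """Arm-specific risks for one outcome in one birthweight band.

    ``ors_vs_reference`` are odds ratios of each arm against the arm whose OR
    is 1. Anchoring conventions:

    * ``reference`` — the printed incidence IS the reference arm's risk
      (used for ``mixed_arm`` / ``formula_arm`` anchored outcomes, with the
      ORs expressed against that arm);
    * ``population_mix`` — the printed incidence is the share-weighted
      population rate under the base-case feeding mix ``base_shares``; the
      reference risk is solved so the mixture reproduces it.
    """
    ors = tuple(float(o) for o in ors_vs_reference)
    if anchoring == "population_mix":
        if base_shares is None:
            raise ValueError("population_mix anchoring requires base_shares")
        return decompose_population_risk(incidence, base_shares, ors).risks
    if anchoring == "reference":
        return tuple(apply_or(incidence, o) for o in ors)
    raise ValueError(f"unknown anchoring {anchoring!r}")


def expected_cases(
    n: float,
    band_shares: Sequence[float],
    arm_risks_by_band: np.ndarray,
    arm_shares: Sequence[float],
) -> np.ndarray:
    """Expected event counts, band × arm.

    ``counts[b, a] = n × band_share[b] × arm_share[a] × risk[b, a]``. The
    grand total equals ``n`` times the share-weighted mean risk.
    """
    risks = np.asarray(arm_risks_by_band, dtype=float)
    b = np.asarray(band_shares, dtype=float)
    a = np.asarray(arm_shares, dtype=float)
    if risks.shape != (b.size, a.size):
        raise ValueError(
            f"arm_risks_by_band shape {risks.shape} does not match "
            f"{b.size} bands × {a.size} arms"
        )
    return n * b[:, None] * a[None, :] * risks
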