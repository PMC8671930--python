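"""Decision rules and the value of research on the pNHE scale.

An intervention is (provisionally) included in the package when its expected
population net health effect is positive. Decision uncertainty is present
when the uncertainty interval around expected pNHE spans zero, i.e. current
evidence could support either inclusion or exclusion. The value of
resolving that uncertainty is the expected value of perfect information:

    EVPI = E[max(pNHE, 0)] − max(E[pNHE], 0)

the expected net DALYs forgone by committing to the better-looking option
now rather than after research removes the uncertainty. For the normal
distributions induced by bivariate-normal per-patient uncertainty this has
a closed form, used here as an independent cross-check on the Monte Carlo
estimate, never as its replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import PNHEDraws


@dataclass(frozen=True)
class VOIResult:
    """Per-intervention decision summary in net DALYs averted."""

    intervention_id: str
    name: str
    expected_pnhe: float
    interval: tuple[float, float]
    expected_pop_benefit: float  # A·N·c·Δē, gross of opportunity costs
    decision: str  # 'include' | 'exclude'
    decision_uncertain: bool
    prob_cost_effective: float
    evpi: float
    provenance: str  # 'reconstructed' | 'imputed'

    def __post_init__(self):
        if self.evpi < 0:
            raise ValueError("EVPI cannot be negative")
        if self.interval[0] > self.interval[1]:
            raise ValueError("interval bounds out of order")


def summarize(draws: PNHEDraws | np.ndarray, level: float) -> tuple[float, float, float]:
    """Mean and equal-tail interval of the pNHE draws.

    Quantiles use linear interpolation of the order statistics (the numpy
    default), documented so intervals are reproducible elsewhere.
    """
    arr = draws.draws if isinstance(draws, PNHEDraws) else np.asarray(draws, float)
    if arr.size == 0:
        raise ValueError("no draws to summarize")
    if not 0 < level < 1:
        raise ValueError("interval level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha])
    return float(arr.mean()), float(lo), float(hi)


def classify_decision(summary: tuple[float, float, float]) -> tuple[str, bool]:
    """Include iff expected pNHE is strictly positive; uncertain iff the
    interval strictly spans zero. A point mass at zero is excluded with
    certainty (boundary convention)."""
    mean, lo, hi = summary
    if lo > hi:
        raise ValueError("interval bounds out of order")
    decision = "include" if mean > 0 else "exclude"
    return decision, bool(lo < 0 < hi)


def evpi_mc(draws: PNHEDraws | np.ndarray) -> float:
    """Monte Carlo EVPI: E[max(pNHE, 0)] − max(E[pNHE], 0), clamped at 0.

    The clamp guards against floating-point rounding only; the estimator is
    non-negative in exact arithmetic.
    """
    arr = draws.draws if isinstance(draws, PNHEDraws) else np.asarray(draws, float)
    if arr.size == 0:
        raise ValueError("no draws")
    raw = float(np.maximum(arr, 0.0).mean() - max(arr.mean(), 0.0))
    return max(raw, 0.0)


def evpi_mc_stderr(draws: PNHEDraws | np.ndarray) -> float:
    """Monte Carlo standard error of :func:`evpi_mc`.

    With g_i = max(d_i, 0) − d_i·1[mean > 0], the estimator is mean(g) and
    its standard error std(g)/√n (the sign of the mean is treated as known,
    which is accurate away from μ = 0 and conservative enough at it).
    """
    arr = draws.draws if isinstance(draws, PNHEDraws) else np.asarray(draws, float)
    g = np.maximum(arr, 0.0) - (arr if arr.mean() > 0 else 0.0)
    return float(np.std(g, ddof=1) / np.sqrt(arr.size))


def evpi_normal_closed_form(mu: float, sigma: float) -> float:
    """EVPI of a normal pNHE ~ N(μ, σ²): σ φ(μ/σ) − |μ| Φ(−|μ|/σ).

    Symmetric in the sign of μ (the forgone side mirrors); 0 when σ = 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return 0.0
    z = abs(mu) / sigma
    return float(sigma * stats.norm.pdf(z) - abs(mu) * stats.norm.cdf(-z))


@dataclass(frozen=True)
class RankedViews:
    """The three orderings reported to decision makers.

    ``by_population_benefit`` ranks by gross population health gain
    (ignoring opportunity costs), ``by_pnhe`` by expected population net
    health effect; ``evpi_in_pnhe_order`` repeats the pNHE ordering with the
    value of research attached so the two charts line up, and ``by_evpi`` is
    the strict research-priority ordering. All ties break by intervention id
    ascending.
    """

    by_population_benefit: tuple[VOIResult, ...]
    by_pnhe: tuple[VOIResult, ...]
    evpi_in_pnhe_order: tuple[VOIResult, ...]
    by_evpi: tuple[VOIResult, ...]


def rank_interventions(results: Sequence[VOIResult]) -> RankedViews:
    if not results:
        raise ValueError("no results to rank")

    def desc(key):
        return tuple(sorted(results, key=lambda r: (-key(r), r.intervention_id)))

    by_pnhe = desc(lambda r: r.expected_pnhe)
    return RankedViews(
        by_population_benefit=desc(lambda r: r.expected_pop_benefit),
        by_pnhe=by_pnhe,
        evpi_in_pnhe_order=by_pnhe,
        by_evpi=desc(lambda r: r.evpi),
    )


def analyse_draws(
    draws: PNHEDraws,
    *,
    name: str,
    expected_pop_benefit: float,
    level: float,
    provenance: str,
) -> VOIResult:
    """Assemble the full per-intervention decision summary from its draws."""
    summary = summarize(draws, level)
    decision, uncertain = classify_decision(summary)
    return VOIResult(
        intervention_id=draws.intervention_id,
        name=name,
        expected_pnhe=summary[0],
        interval=(summary[1], summary[2]),
        expected_pop_benefit=expected_pop_benefit,
        decision=decision,
        decision_uncertain=uncertain,
        prob_cost_effective=float(np.mean(draws.draws > 0)),
        evpi=evpi_mc(draws),
        provenance=provenance,
    )
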