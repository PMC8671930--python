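"""End-to-end analysis: reconstruct → pool → impute → simulate → VOI.

Reconstruction runs in two passes so that pooling only ever reads from
intervention-specific evidence: media that determine their own correlation
(pairs, univariate tables, tornado plots, CEACs, and any payload reporting
ρ explicitly) are inverted first; their average correlation then fills the
gap for media that cannot identify ρ (ICER histograms/CDFs and interval/SE
summaries without a reported correlation). Finally the pooled spreads are
imputed onto interventions with no sensitivity analysis at all, flagged
'imputed' throughout.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

from .datamodel import EvidenceBase
from .errors import ImputationError
from .impute import PooledUncertainty, impute, pool
from .reconstruct import JointUncertainty, needs_pooled, reconstruct
from .simulate import PNHEDraws, annuity_factor, simulate_pnhe
from .voi import RankedViews, VOIResult, analyse_draws, rank_interventions


@dataclass(frozen=True)
class AnalysisConfig:
    """Method choices left open by the reporting media (see docs/methods.md)."""

    imputation_mode: str = "absolute"  # or 'relative'
    pairs_mode: str = "parametric"  # or 'empirical'
    range_convention: str = "extremes_uniform"  # or 'interval95'
    tornado_attribution: str = "cost"  # or 'benefit'
    population_model: str = "annual_cohort"  # or 'one_off'

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RunResult:
    """Everything a run produces, in the input intervention order."""

    results: tuple[VOIResult, ...]
    views: RankedViews
    pooled: Optional[PooledUncertainty]
    joints: dict[str, JointUncertainty]
    draws: dict[str, PNHEDraws]


def run_analysis(eb: EvidenceBase, config: AnalysisConfig | None = None) -> RunResult:
    """Run the full pipeline on a validated evidence base."""
    config = config or AnalysisConfig()
    ctx = eb.context
    kwargs = dict(
        pairs_mode=config.pairs_mode,
        range_convention=config.range_convention,
        tornado_attribution=config.tornado_attribution,
    )

    joints: dict[str, JointUncertainty] = {}
    informed = [r for r in eb.interventions if r.evidence is not None]
    uninformed = [r for r in eb.interventions if r.evidence is None]

    first = [r for r in informed if not needs_pooled(r.evidence)]
    second = [r for r in informed if needs_pooled(r.evidence)]
    for rec in first:
        joints[rec.id] = reconstruct(rec, None, **kwargs)
    pooled_rho = (
        pool([(joints[r.id], (r.delta_cost_pp, r.delta_benefit_pp)) for r in first])
        if first
        else None
    )
    for rec in second:
        joints[rec.id] = reconstruct(rec, pooled_rho, **kwargs)

    pooled = (
        pool([(joints[r.id], (r.delta_cost_pp, r.delta_benefit_pp)) for r in informed])
        if informed
        else None
    )
    if uninformed:
        if pooled is None:
            raise ImputationError(
                "no intervention carries a sensitivity-analysis payload: nothing "
                "to pool, so the exploratory analysis cannot run"
            )
        for rec in uninformed:
            joints[rec.id] = impute(rec, pooled, mode=config.imputation_mode)

    a_ben = (
        1.0
        if config.population_model == "one_off"
        else annuity_factor(ctx.time_horizon_years, ctx.benefit_rate)
    )
    results = []
    draws: dict[str, PNHEDraws] = {}
    for rec in eb.interventions:
        d = simulate_pnhe(rec, joints[rec.id], ctx, population_model=config.population_model)
        draws[rec.id] = d
        results.append(
            analyse_draws(
                d,
                name=rec.name,
                expected_pop_benefit=a_ben
                * rec.eligible_population
                * rec.coverage
                * rec.delta_benefit_pp,
                level=ctx.interval_level,
                provenance=joints[rec.id].provenance,
            )
        )
    return RunResult(
        results=tuple(results),
        views=rank_interventions(results),
        pooled=pooled,
        joints=joints,
        draws=draws,
    )
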