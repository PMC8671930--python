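"""Evidence-base data model.

An evidence base couples global decision-analytic parameters (time horizon,
discount rate, health opportunity cost per DALY averted) with one record per
candidate intervention: 'best guess' point estimates of incremental cost and
incremental health benefit per patient, the eligible population and realistic
coverage, and — where the source cost-effectiveness study reported one — a
sensitivity-analysis payload in one of eight reporting media (standard
errors, confidence intervals, raw simulation pairs, digitized scatter points,
univariate low/high tables, tornado plots of ICERs, ICER histograms or CDFs,
or a cost-effectiveness acceptability curve).

Records without a payload are legal: they are handled downstream by the
exploratory imputation step, never rejected at load time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Annotated, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

MEDIA = (
    "mean_se",
    "mean_ci",
    "raw_pairs",
    "scatter_points",
    "univariate_table",
    "tornado_icer",
    "icer_histogram",
    "icer_cdf",
    "ceac",
)


def _check_finite(model: BaseModel) -> BaseModel:
    """Reject NaN/inf anywhere in a payload (None is fine)."""

    def walk(x, path):
        if isinstance(x, float) and not math.isfinite(x):
            raise ValueError(f"non-finite value at {path}: {x}")
        if isinstance(x, dict):
            for k, v in x.items():
                walk(v, f"{path}.{k}")
        elif isinstance(x, (list, tuple)):
            for i, v in enumerate(x):
                walk(v, f"{path}[{i}]")

    walk(model.model_dump(), type(model).__name__)
    return model


class _Payload(BaseModel):
    model_config = ConfigDict(frozen=True)

    @model_validator(mode="after")
    def _finite(self):
        return _check_finite(self)


class MeanSEPayload(_Payload):
    """Standard errors around mean incremental cost and benefit."""

    medium: Literal["mean_se"] = "mean_se"
    se_cost: float
    se_benefit: float
    rho: Optional[float] = None


class MeanCIPayload(_Payload):
    """Confidence intervals around mean incremental cost and benefit."""

    medium: Literal["mean_ci"] = "mean_ci"
    ci_cost: tuple[float, float]
    ci_benefit: tuple[float, float]
    level: float = 0.95
    rho: Optional[float] = None


class PairsPayload(_Payload):
    """Raw PSA simulations, or digitized cost-vs-benefit scatter points."""

    medium: Literal["raw_pairs", "scatter_points"] = "raw_pairs"
    pairs: tuple[tuple[float, float], ...]


class UnivariateRow(_Payload):
    """Incremental cost/benefit at the low and high value of one parameter."""

    param_id: str
    dc_low: float
    dc_high: float
    de_low: float
    de_high: float


class UnivariatePayload(_Payload):
    medium: Literal["univariate_table"] = "univariate_table"
    rows: tuple[UnivariateRow, ...]


class TornadoBar(_Payload):
    param_id: str
    icer_low: float
    icer_high: float


class TornadoICERPayload(_Payload):
    """Tornado plot of ICERs under single-parameter changes."""

    medium: Literal["tornado_icer"] = "tornado_icer"
    bars: tuple[TornadoBar, ...]
    base_icer: Optional[float] = None  # default: delta_cost_pp / delta_benefit_pp


class ICERHistogramPayload(_Payload):
    """Histogram of the ICER from a probabilistic sensitivity analysis."""

    medium: Literal["icer_histogram"] = "icer_histogram"
    bin_edges: tuple[float, ...]
    counts: tuple[float, ...]
    rho: Optional[float] = None  # correlation held fixed during inversion


class ICERCDFPayload(_Payload):
    """Cumulative distribution of the ICER at a set of support points."""

    medium: Literal["icer_cdf"] = "icer_cdf"
    points: tuple[tuple[float, float], ...]  # (icer, cumulative probability)
    rho: Optional[float] = None


class CEACPayload(_Payload):
    """Cost-effectiveness acceptability curve: P(cost-effective) vs WTP."""

    medium: Literal["ceac"] = "ceac"
    points: tuple[tuple[float, float], ...]  # (lambda, probability)


SensitivityEvidence = Annotated[
    Union[
        MeanSEPayload,
        MeanCIPayload,
        PairsPayload,
        UnivariatePayload,
        TornadoICERPayload,
        ICERHistogramPayload,
        ICERCDFPayload,
        CEACPayload,
    ],
    Field(discriminator="medium"),
]


class DecisionContext(BaseModel):
    """Global decision-analytic parameters shared by every intervention.

    Attributes
    ----------
    time_horizon_years : int
        Years the package decision stays in place (T); cohorts treated yearly.
    discount_rate : float
        Annual discount rate r applied to costs (and to benefits unless a
        separate ``benefit_discount_rate`` is given).
    opportunity_cost_per_daly : float
        Health opportunity cost k in currency per DALY averted: spending k on
        one intervention displaces one DALY averted elsewhere in the system.
    n_simulations, seed : int
        Monte Carlo settings; per-intervention streams are derived from
        ``seed`` and the intervention id, so results are order-independent.
    interval_level : float
        Level of the equal-tail uncertainty interval used for the decision-
        uncertainty classification (error bars crossing zero).
    """

    model_config = ConfigDict(frozen=True)

    time_horizon_years: int = Field(20, ge=1)
    discount_rate: float = Field(0.03, ge=0, allow_inf_nan=False)
    benefit_discount_rate: Optional[float] = Field(None, ge=0, allow_inf_nan=False)
    opportunity_cost_per_daly: float = Field(61.0, gt=0, allow_inf_nan=False)
    n_simulations: int = Field(10_000, ge=1)
    seed: int = 0
    interval_level: float = Field(0.95, gt=0, lt=1)

    @property
    def benefit_rate(self) -> float:
        r = self.benefit_discount_rate
        return self.discount_rate if r is None else r


class InterventionRecord(BaseModel):
    """Point estimates and population scaling for one candidate intervention.

    Bounds on ``eligible_population`` and ``coverage`` are deliberately not
    enforced here; :func:`validate_evidence_base` reports violations as
    diagnostics and loading refuses invalid files.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    name: str = ""
    delta_cost_pp: float = Field(allow_inf_nan=False)
    delta_benefit_pp: float = Field(allow_inf_nan=False)
    eligible_population: float = Field(allow_inf_nan=False)
    coverage: float = Field(allow_inf_nan=False)
    evidence: Optional[SensitivityEvidence] = None


class EvidenceBase(BaseModel):
    model_config = ConfigDict(frozen=True)

    context: DecisionContext
    interventions: tuple[InterventionRecord, ...]

    @model_validator(mode="after")
    def _non_empty_unique(self):
        if not self.interventions:
            raise ValueError("evidence base must contain at least one intervention")
        seen = set()
        for rec in self.interventions:
            if rec.id in seen:
                raise ValueError(f"duplicate intervention id: {rec.id!r}")
            seen.add(rec.id)
        return self

    def get(self, intervention_id: str) -> InterventionRecord:
        for rec in self.interventions:
            if rec.id == intervention_id:
                return rec
        raise KeyError(intervention_id)


@dataclass(frozen=True)
class Diagnostic:
    """One invariant violation, attributable to an intervention and field."""

    intervention_id: Optional[str]
    field: str
    message: str

    def __str__(self) -> str:
        where = self.intervention_id or "<globals>"
        return f"[{where}.{self.field}] {self.message}"


def _payload_diagnostics(rec: InterventionRecord) -> list[Diagnostic]:
    ev = rec.evidence
    out: list[Diagnostic] = []

    def bad(field, msg):
        out.append(Diagnostic(rec.id, field, msg))

    if ev is None:
        return out
    if ev.medium == "mean_se":
        if ev.se_cost < 0 or ev.se_benefit < 0:
            bad("evidence.se", "standard errors must be non-negative")
    elif ev.medium == "mean_ci":
        if ev.ci_cost[0] > ev.ci_cost[1]:
            bad("evidence.ci_cost", "interval lower bound exceeds upper bound")
        if ev.ci_benefit[0] > ev.ci_benefit[1]:
            bad("evidence.ci_benefit", "interval lower bound exceeds upper bound")
        if not 0 < ev.level < 1:
            bad("evidence.level", f"confidence level {ev.level} outside (0, 1)")
    elif ev.medium in ("raw_pairs", "scatter_points"):
        if len(ev.pairs) < 3:
            bad("evidence.pairs", f"need at least 3 pairs, got {len(ev.pairs)}")
    elif ev.medium == "univariate_table":
        if len(ev.rows) < 1:
            bad("evidence.rows", "univariate table is empty")
    elif ev.medium == "tornado_icer":
        if len(ev.bars) < 1:
            bad("evidence.bars", "tornado plot has no bars")
        if rec.delta_benefit_pp == 0:
            bad("delta_benefit_pp", "ICER undefined: incremental benefit is zero")
    elif ev.medium == "icer_histogram":
        edges = ev.bin_edges
        if len(edges) != len(ev.counts) + 1:
            bad("evidence.bin_edges", "need len(edges) == len(counts) + 1")
        elif any(b <= a for a, b in zip(edges, edges[1:])):
            bad("evidence.bin_edges", "bin edges must be strictly ascending")
        if any(c < 0 for c in ev.counts):
            bad("evidence.counts", "bin counts must be non-negative")
        elif sum(ev.counts) <= 0:
            bad("evidence.counts", "histogram has zero total count")
        if rec.delta_benefit_pp == 0:
            bad("delta_benefit_pp", "ICER undefined: incremental benefit is zero")
    elif ev.medium == "icer_cdf":
        pts = ev.points
        if len(pts) < 3:
            bad("evidence.points", f"need at least 3 CDF points, got {len(pts)}")
        srt = sorted(pts)
        if any(q2 < q1 for (_, q1), (_, q2) in zip(srt, srt[1:])):
            bad("evidence.points", "cumulative probabilities must be non-decreasing")
        if any(not 0 <= q <= 1 for _, q in pts):
            bad("evidence.points", "cumulative probabilities must lie in [0, 1]")
        if rec.delta_benefit_pp == 0:
            bad("delta_benefit_pp", "ICER undefined: incremental benefit is zero")
    elif ev.medium == "ceac":
        pts = ev.points
        if len({lam for lam, _ in pts}) < 3:
            bad("evidence.points", "need at least 3 distinct willingness-to-pay values")
        if any(not 0 <= p <= 1 for _, p in pts):
            bad("evidence.points", "acceptability probabilities must lie in [0, 1]")
    rho = getattr(ev, "rho", None)
    if rho is not None and not -1 <= rho <= 1:
        bad("evidence.rho", f"correlation {rho} outside [-1, 1]")
    return out


def validate_evidence_base(eb: EvidenceBase) -> list[Diagnostic]:
    """Check every documented invariant; return one diagnostic per violation.

    Returns an empty list when the evidence base is valid. Never raises:
    callers that want hard failure (e.g. the loader) wrap a non-empty result
    in :class:`~voihbp.errors.EvidenceValidationError`.
    """
    out: list[Diagnostic] = []
    for rec in eb.interventions:
        if rec.eligible_population < 0:
            out.append(
                Diagnostic(rec.id, "eligible_population", "must be non-negative")
            )
        if not 0 <= rec.coverage <= 1:
            out.append(
                Diagnostic(rec.id, "coverage", f"{rec.coverage} outside [0, 1]")
            )
        out.extend(_payload_diagnostics(rec))
    return out
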