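"""Synthetic evidence bases with known ground truth.

The original application's workbook (21 Malawian interventions) is not
published, so testing and demonstration rest on generated evidence bases:
each intervention gets a true bivariate-normal uncertainty (σ_C, σ_E, ρ)
around its point estimates, and its payload is *rendered* in one of the
eight reporting media exactly as a cost-effectiveness study would report it
— standard errors and intervals computed exactly, raw pairs and scatter
points sampled, univariate tables built from orthogonal parameter effects
whose summed variances reproduce the truth, tornado bars from the
cost-attributed convention, and ICER histograms/CDFs/CEACs from the ratio
distribution. Reconstruction can then be scored against the truth.

The default 21-intervention spec mirrors the published medium mix
(5 univariate tables, 2 ICER tornado plots, 2 raw-simulation sets,
1 scatter plot, 1 ICER histogram, 1 ICER CDF, 8 confidence-interval and
1 standard-error summaries) and spans the four qualitative decision
regimes: clearly cost-effective, clearly not, and uncertain on either side
of zero (expected pNHE at ±4 and ±0.5 population standard deviations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CEACPayload,
    DecisionContext,
    EvidenceBase,
    ICERCDFPayload,
    ICERHistogramPayload,
    InterventionRecord,
    MeanCIPayload,
    MeanSEPayload,
    PairsPayload,
    TornadoBar,
    TornadoICERPayload,
    UnivariatePayload,
    UnivariateRow,
)
from .io import write_evidence_base
from .reconstruct import Z95, ceac_probability, icer_ratio_cdf
from .simulate import derive_seed

TABLE1_MEDIA_COUNTS = {
    "univariate_table": 5,
    "tornado_icer": 2,
    "raw_pairs": 2,
    "scatter_points": 1,
    "icer_histogram": 1,
    "icer_cdf": 1,
    "mean_ci": 8,
    "mean_se": 1,
}

REGIMES = ("clear_include", "uncertain_include", "uncertain_exclude", "clear_exclude")
_REGIME_SHIFT = {
    "clear_include": 4.0,
    "uncertain_include": 0.5,
    "uncertain_exclude": -0.5,
    "clear_exclude": -4.0,
}


@dataclass(frozen=True)
class InterventionTruth:
    """Ground-truth parameters behind one rendered intervention."""

    id: str
    name: str
    delta_cost_pp: float
    delta_benefit_pp: float
    sd_cost: float
    sd_benefit: float
    correlation: float
    eligible_population: float
    coverage: float
    medium: str  # one of the eight media, 'ceac', or 'none'
    regime: str = ""


@dataclass(frozen=True)
class RenderSizes:
    """How much data each sampled/gridded payload carries."""

    n_raw_pairs: int = 10_000
    n_scatter_points: int = 500
    hist_draws: int = 100_000
    hist_bins: int = 20
    cdf_points: int = 15
    ceac_lambdas: tuple[float, ...] = (0.0, 20.0, 40.0, 61.0, 100.0, 150.0, 250.0)


@dataclass(frozen=True)
class FixtureSpec:
    context: DecisionContext
    interventions: tuple[InterventionTruth, ...]
    sizes: RenderSizes = field(default_factory=RenderSizes)
    seed: int = 0


class FixtureError(ValueError):
    """The requested truth cannot be represented in the requested medium."""


def _icer_sd(truth: InterventionTruth) -> float:
    """Delta-method standard deviation of the ICER under the truth."""
    de = truth.delta_benefit_pp
    base = truth.delta_cost_pp / de
    var = (
        truth.sd_cost**2
        + base**2 * truth.sd_benefit**2
        - 2 * base * truth.correlation * truth.sd_cost * truth.sd_benefit
    ) / de**2
    return float(np.sqrt(max(var, 0.0)))


def render_payload(
    truth: InterventionTruth,
    medium: Optional[str] = None,
    seed: int = 0,
    sizes: RenderSizes = RenderSizes(),
    n_params: int = 2,
):
    """Render a truth into one reporting medium's payload.

    Sampled media (pairs, scatter, histogram) are deterministic given
    ``seed``; summary media are computed exactly from the truth, so their
    reconstruction should invert them exactly.
    """
    medium = medium or truth.medium
    mu_c, mu_e = truth.delta_cost_pp, truth.delta_benefit_pp
    sd_c, sd_e, rho = truth.sd_cost, truth.sd_benefit, truth.correlation
    rng = np.random.default_rng(seed)

    if medium == "none":
        raise FixtureError("medium 'none' has no payload to render")

    if medium == "mean_se":
        return MeanSEPayload(se_cost=sd_c, se_benefit=sd_e, rho=rho)

    if medium == "mean_ci":
        return MeanCIPayload(
            ci_cost=(mu_c - Z95 * sd_c, mu_c + Z95 * sd_c),
            ci_benefit=(mu_e - Z95 * sd_e, mu_e + Z95 * sd_e),
            level=0.95,
            rho=rho,
        )

    if medium in ("raw_pairs", "scatter_points"):
        n = sizes.n_raw_pairs if medium == "raw_pairs" else sizes.n_scatter_points
        z = rng.standard_normal((2, n))
        dc = mu_c + sd_c * z[0]
        de = mu_e + sd_e * (rho * z[0] + np.sqrt(1 - rho * rho) * z[1])
        return PairsPayload(medium=medium, pairs=tuple(zip(dc.tolist(), de.tolist())))

    if medium == "univariate_table":
        # Orthogonal parameter effects whose summed variances reproduce the
        # truth under the extremes_uniform convention: widths a_j (cost) and
        # b_j (benefit, signed) with Σa²/12 = σ_C², Σb²/12 = σ_E²,
        # Σ a·b/12 = ρ σ_C σ_E.
        if n_params < 2 and abs(abs(rho) - 1.0) > 1e-12 and sd_c > 0 and sd_e > 0:
            raise FixtureError(
                "a single varied parameter forces |rho| = 1; use >= 2 parameters"
            )
        s12 = np.sqrt(12.0)
        if n_params < 2:
            widths = [(s12 * sd_c, np.sign(rho or 1.0) * s12 * sd_e)]
        else:
            widths = [
                (s12 * sd_c, s12 * rho * sd_e),
                (0.0, s12 * np.sqrt(max(1 - rho * rho, 0.0)) * sd_e),
            ]
        rows = tuple(
            UnivariateRow(
                param_id=f"p{j + 1}",
                dc_low=mu_c - a / 2,
                dc_high=mu_c + a / 2,
                de_low=mu_e - b / 2,
                de_high=mu_e + b / 2,
            )
            for j, (a, b) in enumerate(widths)
        )
        return UnivariatePayload(rows=rows)

    if medium == "tornado_icer":
        # cost-attributed convention: all ICER spread comes from the cost
        # margin, split evenly over two independent bars
        if mu_e == 0:
            raise FixtureError("cannot render a tornado for zero incremental benefit")
        if sd_e > 0 or rho != 0:
            raise FixtureError(
                "tornado rendering is cost-attributed; truth must have sd_benefit=0, rho=0"
            )
        base = mu_c / mu_e
        sd_icer = sd_c / abs(mu_e)
        w = np.sqrt(12.0 * sd_icer**2 / 2.0)
        bars = tuple(
            TornadoBar(param_id=f"p{j + 1}", icer_low=base - w / 2, icer_high=base + w / 2)
            for j in range(2)
        )
        return TornadoICERPayload(bars=bars, base_icer=base)

    if medium == "icer_histogram":
        if mu_e == 0:
            raise FixtureError("ICER undefined for zero incremental benefit")
        z = rng.standard_normal((2, sizes.hist_draws))
        dc = mu_c + sd_c * z[0]
        de = mu_e + sd_e * (rho * z[0] + np.sqrt(1 - rho * rho) * z[1])
        ratio = dc / de
        # bin over the central 99% (a study's plot axis); tail mass folds
        # into the end bins, as with '<=' / '>=' edge bins
        lo_q, hi_q = np.quantile(ratio, [0.005, 0.995])
        counts, edges = np.histogram(np.clip(ratio, lo_q, hi_q), bins=sizes.hist_bins)
        return ICERHistogramPayload(
            bin_edges=tuple(edges.tolist()), counts=tuple(float(c) for c in counts), rho=None
        )

    if medium == "icer_cdf":
        if mu_e == 0:
            raise FixtureError("ICER undefined for zero incremental benefit")
        base = mu_c / mu_e
        sd_icer = _icer_sd(truth)
        probs = np.linspace(0.02, 0.98, sizes.cdf_points)
        t = base + sd_icer * stats.norm.ppf(probs)
        q = icer_ratio_cdf(t, mu_c, mu_e, sd_c, sd_e, rho)
        return ICERCDFPayload(
            points=tuple(zip(t.tolist(), q.tolist())), rho=None
        )

    if medium == "ceac":
        lam = np.asarray(sizes.ceac_lambdas, dtype=float)
        p = ceac_probability(lam, mu_c, mu_e, sd_c, sd_e, rho)
        return CEACPayload(points=tuple(zip(lam.tolist(), p.tolist())))

    raise FixtureError(f"unknown medium {medium!r}")


def truth_to_record(
    truth: InterventionTruth, seed: int, sizes: RenderSizes = RenderSizes()
) -> InterventionRecord:
    ev = (
        None
        if truth.medium == "none"
        else render_payload(truth, seed=derive_seed(seed, truth.id), sizes=sizes)
    )
    return InterventionRecord(
        id=truth.id,
        name=truth.name,
        delta_cost_pp=truth.delta_cost_pp,
        delta_benefit_pp=truth.delta_benefit_pp,
        eligible_population=truth.eligible_population,
        coverage=truth.coverage,
        evidence=ev,
    )


def build_evidence_base(spec: FixtureSpec) -> EvidenceBase:
    """Render every truth into an in-memory evidence base."""
    return EvidenceBase(
        context=spec.context,
        interventions=tuple(
            truth_to_record(t, spec.seed, spec.sizes) for t in spec.interventions
        ),
    )


def default_fixture_spec(
    seed: int = 0,
    n_simulations: int = 10_000,
    media_counts: Optional[dict[str, int]] = None,
) -> FixtureSpec:
    """The canonical 21-intervention fixture with the published medium mix.

    Decision regimes cycle through clear/uncertain on both sides of zero so
    every medium class contains both easy and genuinely uncertain calls.
    Truths honour each medium's identifiability limits: tornado plots carry
    cost-only uncertainty, and ICER histogram/CDF interventions use ρ = 0
    (the value the pipeline will hold fixed, up to the pooled average).
    """
    ctx = DecisionContext(n_simulations=n_simulations, seed=seed)
    k = ctx.opportunity_cost_per_daly
    counts = media_counts or TABLE1_MEDIA_COUNTS
    media: list[str] = []
    for m, c in counts.items():
        media.extend([m] * c)

    rho_cycle = (0.0, 0.3, -0.3, 0.2, 0.0, -0.2)
    sd_e_cycle = (0.12, 0.18, 0.25, 0.15)
    cov_cycle = (0.4, 0.6, 0.8)
    truths = []
    for i, medium in enumerate(media, start=1):
        regime = REGIMES[(i - 1) % 4]
        mu_c = 60.0 + 10.0 * i
        sd_c = 0.35 * mu_c
        if medium == "tornado_icer":
            sd_e, rho = 0.0, 0.0
        elif medium in ("icer_histogram", "icer_cdf"):
            # keep the denominator safely positive in every regime so the
            # ICER distribution is well behaved
            sd_c = 0.15 * mu_c
            sd_e, rho = sd_e_cycle[(i - 1) % 4], 0.0
        else:
            sd_e = sd_e_cycle[(i - 1) % 4]
            rho = rho_cycle[(i - 1) % 6]
        sd_pp = np.sqrt(sd_e**2 + (sd_c / k) ** 2 - 2 * rho * sd_e * sd_c / k)
        mu_e = _REGIME_SHIFT[regime] * sd_pp + mu_c / k
        truths.append(
            InterventionTruth(
                id=f"I{i:02d}",
                name=f"synthetic intervention {i:02d} ({medium})",
                delta_cost_pp=mu_c,
                delta_benefit_pp=float(mu_e),
                sd_cost=float(sd_c),
                sd_benefit=float(sd_e),
                correlation=float(rho),
                eligible_population=20_000.0 + 3_000.0 * i,
                coverage=cov_cycle[(i - 1) % 3],
                medium=medium,
                regime=regime,
            )
        )
    return FixtureSpec(context=ctx, interventions=tuple(truths), seed=seed)


def truth_table(spec: FixtureSpec) -> pd.DataFrame:
    rows = [
        {
            "intervention_id": t.id,
            "medium": t.medium,
            "regime": t.regime,
            "delta_cost_pp": t.delta_cost_pp,
            "delta_benefit_pp": t.delta_benefit_pp,
            "sd_cost": t.sd_cost,
            "sd_benefit": t.sd_benefit,
            "correlation": t.correlation,
            "eligible_population": t.eligible_population,
            "coverage": t.coverage,
        }
        for t in spec.interventions
    ]
    return pd.DataFrame(rows)


def generate_evidence_base(
    spec: FixtureSpec, out_path, format: str = "csv_dir"
) -> tuple[EvidenceBase, pd.DataFrame]:
    """Write a loadable evidence base plus a truth table for recovery tests.

    Deterministic given ``spec.seed``: rerunning with the same spec writes
    identical files (byte-identical in the CSV format).
    """
    eb = build_evidence_base(spec)
    out_path = Path(out_path)
    write_evidence_base(eb, out_path, format=format)
    truth = truth_table(spec)
    if format == "csv_dir":
        truth.to_csv(out_path / "truth.csv", index=False)
    else:
        truth.to_csv(out_path.with_suffix(".truth.csv"), index=False)
    return eb, truth
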