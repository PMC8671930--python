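"""Exploratory imputation for interventions without sensitivity analyses.

When a candidate intervention's source study reports no sensitivity
analysis, its joint uncertainty is borrowed from the informed set: the
arithmetic average of the reconstructed correlations and spreads. Two
averaging scales are provided — absolute standard deviations (the default)
and coefficients of variation rescaled by the intervention's own point
estimates — because averaging absolute variances across interventions with
very different cost scales can be misleading. Imputed results are flagged
``provenance='imputed'`` all the way to the output tables: they are
exploratory, not evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import InterventionRecord
from .errors import ImputationError, ReconstructionWarning
from .reconstruct import JointUncertainty


@dataclass(frozen=True)
class PooledUncertainty:
    """Averages over the interventions whose uncertainty was reconstructed."""

    mean_correlation: float
    mean_sd_cost: float
    mean_sd_benefit: float
    mean_cv_cost: float
    mean_cv_benefit: float
    n_contributing: int

    def __post_init__(self):
        if not -1 <= self.mean_correlation <= 1:
            raise ValueError("pooled correlation outside [-1, 1]")
        if min(self.mean_cv_cost, self.mean_cv_benefit) < 0:
            raise ValueError("pooled coefficients of variation must be >= 0")


def pool(
    reconstructed: Sequence[tuple[JointUncertainty, tuple[float, float]]]
) -> PooledUncertainty:
    """Average reconstructed (σ_C, σ_E, ρ) and CVs over the informed set.

    Parameters
    ----------
    reconstructed
        Pairs of (joint uncertainty, (Δc̄, Δē) point-estimate means).

    Degenerate entries (σ = 0) contribute to the σ averages but are excluded
    from the CV averages, as is any margin whose point estimate is zero.
    """
    entries = [(ju, m) for ju, m in reconstructed if np.isfinite(ju.sd_cost) and np.isfinite(ju.sd_benefit)]
    if not entries:
        raise ImputationError("cannot pool: no reconstructed uncertainties available")
    rhos = [ju.correlation for ju, _ in entries]
    sd_c = [ju.sd_cost for ju, _ in entries]
    sd_e = [ju.sd_benefit for ju, _ in entries]
    cv_c = [ju.sd_cost / abs(m[0]) for ju, m in entries if m[0] != 0 and ju.sd_cost > 0]
    cv_e = [ju.sd_benefit / abs(m[1]) for ju, m in entries if m[1] != 0 and ju.sd_benefit > 0]
    return PooledUncertainty(
        mean_correlation=float(np.mean(rhos)),
        mean_sd_cost=float(np.mean(sd_c)),
        mean_sd_benefit=float(np.mean(sd_e)),
        mean_cv_cost=float(np.mean(cv_c)) if cv_c else 0.0,
        mean_cv_benefit=float(np.mean(cv_e)) if cv_e else 0.0,
        n_contributing=len(entries),
    )


def impute(
    record: InterventionRecord,
    pooled: PooledUncertainty,
    mode: str = "absolute",
) -> JointUncertainty:
    """Assign pooled uncertainty to a record lacking a payload.

    ``mode='absolute'`` copies the pooled standard deviations verbatim;
    ``mode='relative'`` rescales the pooled CVs by the record's own point
    estimates (a zero point estimate then yields a degenerate margin, with a
    warning). Either way ρ = pooled mean and provenance is 'imputed'.
    """
    if record.evidence is not None:
        raise ValueError(
            f"intervention {record.id!r} has evidence; imputation is only for "
            "records without a payload"
        )
    if pooled.n_contributing < 1:
        raise ImputationError("pooled estimate has no contributing interventions")
    if mode == "absolute":
        sd_c, sd_e = pooled.mean_sd_cost, pooled.mean_sd_benefit
    elif mode == "relative":
        sd_c = pooled.mean_cv_cost * abs(record.delta_cost_pp)
        sd_e = pooled.mean_cv_benefit * abs(record.delta_benefit_pp)
        if record.delta_cost_pp == 0 or record.delta_benefit_pp == 0:
            warnings.warn(
                f"[{record.id}] zero point estimate: relative imputation gives a "
                "degenerate margin",
                ReconstructionWarning,
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown imputation mode {mode!r}")
    return JointUncertainty(
        sd_c, sd_e, pooled.mean_correlation, provenance="imputed"
    )
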