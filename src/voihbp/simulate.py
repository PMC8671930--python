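"""Monte Carlo propagation of per-patient uncertainty to population pNHE.

The population net health effect of funding an intervention is

    pNHE = A · N · c · (ΔE − ΔC / k)

where (ΔC, ΔE) are the per-patient incremental cost and DALYs averted, k is
the health opportunity cost (currency per DALY averted displaced at the
margin of the system), N the annual eligible cohort, c realistic coverage
and A the annuity factor over the delivery horizon. One (ΔC, ΔE) pair is
drawn per simulation and applied to all years: the uncertainty being
propagated is parameter uncertainty about the true values, not year-to-year
fluctuation.

Costs are converted to health (ΔC/k) *before* noise is added, so rescaling
all cost quantities and k by a common representable factor leaves every
draw bit-identical — a useful invariance check and a guarantee that results
do not depend on the currency unit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import DecisionContext, InterventionRecord
from .reconstruct import JointUncertainty


def annuity_factor(T: int, r: float) -> float:
    """Sum of discount factors over T annual cohorts, first year undiscounted.

    A = Σ_{t=0}^{T−1} (1+r)^{−t}; A = T when r = 0, A = 1 when T = 1.
    """
    if T < 1:
        raise ValueError("time horizon must be at least 1 year")
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    return float(np.sum((1.0 + r) ** -np.arange(T)))


def per_patient_nhe(delta_e: float, delta_c: float, k: float):
    """Net DALYs averted per patient: benefit minus cost-funded displacement."""
    if k <= 0:
        raise ValueError("opportunity cost k must be positive")
    return delta_e - delta_c / k


def population_scale(nhe_pp, N: float, c: float, A: float):
    """Scale a per-patient net effect to the covered population over time."""
    return nhe_pp * N * c * A


def derive_seed(global_seed: int, intervention_id: str) -> int:
    """Stable per-intervention seed, independent of processing order."""
    digest = hashlib.sha256(f"{global_seed}:{intervention_id}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)


@dataclass(frozen=True)
class PNHEDraws:
    """Simulated population net health effects for one intervention."""

    intervention_id: str
    draws: np.ndarray  # net DALYs averted, population level, discounted
    scale_factor: float  # A · N · c
    seed_used: int

    def __post_init__(self):
        arr = np.asarray(self.draws, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("pNHE draws must be finite")
        object.__setattr__(self, "draws", arr)


def sample_joint(
    ju: JointUncertainty,
    means: tuple[float, float],
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw n (Δc, Δe) pairs from a reconstructed joint distribution.

    Normal family: Cholesky-style construction Δc = μ_c + σ_C z₁,
    Δe = μ_e + σ_E (ρ z₁ + √(1−ρ²) z₂). Empirical family: resample the
    stored pairs with replacement, recentred to the point-estimate means.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    if not -1 <= ju.correlation <= 1:
        raise ValueError("invalid correlation")
    rng = np.random.default_rng(seed)
    mu_c, mu_e = means
    if ju.family == "empirical":
        src = ju.sample
        idx = rng.integers(0, src.shape[0], size=n)
        dc = mu_c + (src[idx, 0] - src[:, 0].mean())
        de = mu_e + (src[idx, 1] - src[:, 1].mean())
    else:
        z = rng.standard_normal((2, n))
        rho = ju.correlation
        dc = mu_c + ju.sd_cost * z[0]
        de = mu_e + ju.sd_benefit * (rho * z[0] + np.sqrt(1.0 - rho * rho) * z[1])
    return np.column_stack([dc, de])


def simulate_pnhe(
    record: InterventionRecord,
    ju: JointUncertainty,
    ctx: DecisionContext,
    *,
    population_model: str = "annual_cohort",
    seed: Optional[int] = None,
) -> PNHEDraws:
    """Simulate the population net health effect distribution for one record.

    The per-intervention stream is seeded from ``ctx.seed`` and the
    intervention id (override with ``seed=`` for seed-matched comparisons),
    so reordering the evidence base never changes any intervention's draws.
    ``population_model='one_off'`` treats N as a prevalent pool reached once
    (annuity replaced by 1) instead of an annual cohort treated for T years.

    Discounting note: with a separate benefit discount rate, costs displace
    health at their own annuity while benefits accrue at theirs; the two
    collapse to a single factor A when the rates coincide (the default).
    """
    k = ctx.opportunity_cost_per_daly
    n = ctx.n_simulations
    if population_model == "one_off":
        a_cost = a_ben = 1.0
    elif population_model == "annual_cohort":
        a_cost = annuity_factor(ctx.time_horizon_years, ctx.discount_rate)
        a_ben = annuity_factor(ctx.time_horizon_years, ctx.benefit_rate)
    else:
        raise ValueError(f"unknown population model {population_model!r}")
    seed_used = derive_seed(ctx.seed, record.id) if seed is None else int(seed)
    rng = np.random.default_rng(seed_used)

    # Convert the cost margin to health units (divide by k) before adding
    # noise: this is what makes the draws exactly invariant to a common
    # rescaling of all cost quantities and k.
    hc_mean = record.delta_cost_pp / k
    if ju.family == "empirical":
        src = ju.sample
        idx = rng.integers(0, src.shape[0], size=n)
        hc_src = src[:, 0] / k
        hc = hc_mean + (hc_src[idx] - hc_src.mean())
        de = record.delta_benefit_pp + (src[idx, 1] - src[:, 1].mean())
    else:
        z = rng.standard_normal((2, n))
        rho = ju.correlation
        hc = hc_mean + (ju.sd_cost / k) * z[0]
        de = record.delta_benefit_pp + ju.sd_benefit * (
            rho * z[0] + np.sqrt(1.0 - rho * rho) * z[1]
        )
    pop = record.eligible_population * record.coverage
    draws = de * (pop * a_ben) - hc * (pop * a_cost)
    return PNHEDraws(
        intervention_id=record.id,
        draws=draws,
        scale_factor=pop * a_ben,
        seed_used=seed_used,
    )
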