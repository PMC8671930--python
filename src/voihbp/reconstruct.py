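"""Reconstruct joint cost/benefit uncertainty from sensitivity-analysis media.

Published cost-effectiveness studies rarely report the joint distribution of
incremental cost ΔC and incremental benefit ΔE directly; they report one of
eight summaries (standard errors, confidence intervals, raw PSA pairs,
scatter points, univariate low/high tables, tornado plots of ICERs, ICER
histograms/CDFs, or a CEAC). Each ``from_*`` function here inverts one such
medium back to the three quantities that determine a bivariate normal on the
incremental scale: sd(ΔC) = σ_C, sd(ΔE) = σ_E and their correlation ρ.

Conventions that are this package's own choices (the source media
under-determine them) are documented inline and in docs/methods.md:
univariate/tornado ranges are read as extremes of a uniform by default
(variance = width²/12), parameters are summed as independent, tornado
uncertainty is attributed to the cost margin unless configured otherwise,
and the ICER histogram/CDF inversions hold ρ fixed because a single ratio
margin cannot identify three shape parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .datamodel import InterventionRecord
from .errors import (
    InsufficientDataError,
    ReconstructionError,
    ReconstructionWarning,
    SchemaError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .impute import PooledUncertainty

Z95 = float(stats.norm.ppf(0.975))  # 1.959964...

_FIT_TOL = 1e-8
_MAX_NFEV = 200
_POOR_FIT_RMS = 0.05


@dataclass(frozen=True)
class JointUncertainty:
    """Bivariate uncertainty in per-patient incremental cost and benefit.

    ``family='bivariate_normal'`` is fully described by (sd_cost, sd_benefit,
    correlation); ``family='empirical'`` additionally retains the raw pairs
    for resampling. ``provenance`` records whether the object was
    reconstructed from intervention-specific evidence or imputed from the
    pooled informed set.
    """

    sd_cost: float
    sd_benefit: float
    correlation: float
    family: str = "bivariate_normal"
    sample: Optional[np.ndarray] = None  # (n, 2) array of (Δc, Δe) pairs
    provenance: str = "reconstructed"
    diagnostics: tuple[str, ...] = field(default_factory=tuple)
    fit_residual: Optional[float] = None

    def __post_init__(self):
        if self.sd_cost < 0 or self.sd_benefit < 0:
            raise ValueError("standard deviations must be non-negative")
        # tolerate floating drift from fits, reject genuine violations
        rho = float(self.correlation)
        if not -1.0000001 <= rho <= 1.0000001:
            raise ValueError(f"correlation {rho} outside [-1, 1]")
        object.__setattr__(self, "correlation", float(np.clip(rho, -1.0, 1.0)))
        if self.family not in ("bivariate_normal", "empirical"):
            raise ValueError(f"unknown family {self.family!r}")
        if (self.sample is not None) != (self.family == "empirical"):
            raise ValueError("sample must be present iff family='empirical'")
        if self.sample is not None:
            object.__setattr__(
                self, "sample", np.asarray(self.sample, dtype=float).reshape(-1, 2)
            )


def _default_rho(rho: Optional[float], pooled: "Optional[PooledUncertainty]"):
    """Resolve an absent reported correlation from the pooled informed set."""
    if rho is not None:
        if not -1 <= rho <= 1:
            raise ValueError(f"correlation {rho} outside [-1, 1]")
        return float(rho), ()
    if pooled is not None and pooled.n_contributing >= 1:
        return float(pooled.mean_correlation), ("rho_imputed_from_pool",)
    warnings.warn(
        "no reported correlation and no pooled estimate; using rho=0",
        ReconstructionWarning,
        stacklevel=3,
    )
    return 0.0, ("rho_defaulted_zero",)


def from_mean_se(
    se_cost: float,
    se_benefit: float,
    rho: Optional[float] = None,
    pooled: "Optional[PooledUncertainty]" = None,
) -> JointUncertainty:
    """Standard errors map directly onto the normal margins."""
    if se_cost < 0 or se_benefit < 0:
        raise ValueError("standard errors must be non-negative")
    r, diag = _default_rho(rho, pooled)
    return JointUncertainty(float(se_cost), float(se_benefit), r, diagnostics=diag)


def from_mean_ci(
    ci_cost: tuple[float, float],
    ci_benefit: tuple[float, float],
    level: float = 0.95,
    rho: Optional[float] = None,
    pooled: "Optional[PooledUncertainty]" = None,
) -> JointUncertainty:
    """Symmetric normal intervals: sd = width / (2 z_{(1+level)/2})."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level {level} outside (0, 1)")
    for lo, hi in (ci_cost, ci_benefit):
        if lo > hi:
            raise ValueError(f"inverted interval ({lo}, {hi})")
    z = float(stats.norm.ppf(0.5 + level / 2))
    sd_c = (ci_cost[1] - ci_cost[0]) / (2 * z)
    sd_e = (ci_benefit[1] - ci_benefit[0]) / (2 * z)
    r, diag = _default_rho(rho, pooled)
    return JointUncertainty(sd_c, sd_e, r, diagnostics=diag)


def from_raw_pairs(
    pairs: Sequence[tuple[float, float]], mode: str = "parametric"
) -> JointUncertainty:
    """Sample moments (n-1 denominator) of raw or digitized (Δc, Δe) pairs.

    ``mode='empirical'`` keeps the pairs for resampling instead of collapsing
    them to a normal; the moments are still reported for pooling.
    """
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if arr.shape[0] < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {arr.shape[0]}")
    sd_c = float(np.std(arr[:, 0], ddof=1))
    sd_e = float(np.std(arr[:, 1], ddof=1))
    diag: tuple[str, ...] = ()
    if sd_c == 0 or sd_e == 0:
        rho = 0.0
        diag = ("degenerate_margin",)
        warnings.warn(
            "zero variance in one margin; correlation set to 0",
            ReconstructionWarning,
            stacklevel=2,
        )
    else:
        cov = float(np.cov(arr[:, 0], arr[:, 1], ddof=1)[0, 1])
        rho = float(np.clip(cov / (sd_c * sd_e), -1.0, 1.0))
    if mode == "empirical":
        return JointUncertainty(
            sd_c, sd_e, rho, family="empirical", sample=arr, diagnostics=diag
        )
    if mode != "parametric":
        raise ValueError(f"unknown pairs mode {mode!r}")
    return JointUncertainty(sd_c, sd_e, rho, diagnostics=diag)


def _range_scale(width: float, range_convention: str) -> float:
    """Map a low→high range to a standard deviation (keeps the sign)."""
    if range_convention == "extremes_uniform":
        return width / np.sqrt(12.0)
    if range_convention == "interval95":
        return width / (2 * Z95)
    raise ValueError(f"unknown range convention {range_convention!r}")


def from_univariate_table(
    rows: Sequence, range_convention: str = "extremes_uniform"
) -> JointUncertainty:
    """Sum independent per-parameter variance contributions.

    Each row gives ΔC and ΔE at a parameter's low and high setting. Under
    ``extremes_uniform`` the range is read as the support of a uniform
    (variance width²/12, covariance product-of-widths/12, signed by the
    direction of co-movement); under ``interval95`` half-ranges are divided
    by z = 1.96 first. A single varied parameter necessarily gives |ρ| = 1.
    """
    if len(rows) < 1:
        raise InsufficientDataError("univariate table is empty")
    var_c = var_e = cov = 0.0
    for row in rows:
        sc = _range_scale(row.dc_high - row.dc_low, range_convention)
        se = _range_scale(row.de_high - row.de_low, range_convention)
        var_c += sc * sc
        var_e += se * se
        cov += sc * se
    sd_c, sd_e = float(np.sqrt(var_c)), float(np.sqrt(var_e))
    diag: tuple[str, ...] = ()
    if sd_c == 0 or sd_e == 0:
        rho = 0.0
        if sd_c == 0 and sd_e == 0:
            diag = ("degenerate_margin",)
    else:
        rho = float(np.clip(cov / (sd_c * sd_e), -1.0, 1.0))
    return JointUncertainty(sd_c, sd_e, rho, diagnostics=diag)


def from_tornado_icer(
    base_icer: float,
    bars: Sequence[tuple[float, float]],
    delta_e_base: float,
    attribution: str = "cost",
    range_convention: str = "extremes_uniform",
) -> JointUncertainty:
    """Invert a tornado plot of ICERs to a single-margin uncertainty.

    The bars give the ICER at each parameter's low/high setting; their
    variance contributions are summed as independent to an ICER standard
    deviation s. The medium carries no information to split uncertainty
    between margins, so it is attributed to one of them:

    * ``attribution='cost'`` (default): σ_C = s·|Δe|, σ_E = 0 — the DALY
      point estimate is left untouched.
    * ``attribution='benefit'``: σ_E is chosen so the implied ICER interval
      Δc / (Δe ± z σ_E) spans base ± z·s at the matching 95% quantiles
      (solving the quadratic H x² + |Δc| x − H Δe² = 0 for x = z σ_E with
      H = z·s), σ_C = 0.
    """
    if delta_e_base == 0:
        raise ValueError("ICER undefined: incremental benefit is zero")
    if len(bars) < 1:
        raise InsufficientDataError("tornado plot has no bars")
    var_icer = 0.0
    for lo, hi in ((b[0], b[1]) if not hasattr(b, "icer_low") else (b.icer_low, b.icer_high) for b in bars):
        s = _range_scale(hi - lo, range_convention)
        var_icer += s * s
    sd_icer = float(np.sqrt(var_icer))
    if attribution == "cost":
        return JointUncertainty(sd_icer * abs(delta_e_base), 0.0, 0.0)
    if attribution != "benefit":
        raise ValueError(f"unknown tornado attribution {attribution!r}")
    if sd_icer == 0:
        return JointUncertainty(0.0, 0.0, 0.0)
    a = abs(delta_e_base)
    c = abs(base_icer * delta_e_base)
    h = Z95 * sd_icer
    x = (-c + np.sqrt(c * c + 4 * h * h * a * a)) / (2 * h)
    return JointUncertainty(0.0, float(x / Z95), 0.0)


# ---------------------------------------------------------------------------
# Ratio-of-correlated-normals machinery for ICER histogram / CDF inversion
# ---------------------------------------------------------------------------


def _bvn_cdf(h: np.ndarray, k: np.ndarray, r: np.ndarray) -> np.ndarray:
    """P(X ≤ h, Y ≤ k) for standard bivariate normals with correlation r.

    Owen's T identity: Φ₂(h, k, r) = ½[Φ(h) + Φ(k)] − T(h, a_h) − T(k, a_k)
    − ½·1[hk < 0], with a_h = (k − r h)/(h √(1−r²)). Exact comonotone /
    antithetic limits are substituted for |r| → 1, where the identity
    degenerates; exact zeros in h, k are nudged off the removable
    singularity. Accurate to ~1e-14 across the whole correlation range,
    which matters because the ICER fits explore correlations near ±1.
    """
    from scipy.special import owens_t

    h, k, r = np.broadcast_arrays(
        np.atleast_1d(np.asarray(h, dtype=float)),
        np.atleast_1d(np.asarray(k, dtype=float)),
        np.clip(np.atleast_1d(np.asarray(r, dtype=float)), -1.0, 1.0),
    )
    h = np.where(h == 0.0, 1e-14, h)
    k = np.where(k == 0.0, 1e-14, k)
    out = np.empty(h.shape, dtype=float)

    hi = r >= 1.0 - 1e-12
    lo = r <= -1.0 + 1e-12
    mid = ~(hi | lo)
    if np.any(hi):
        out[hi] = stats.norm.cdf(np.minimum(h[hi], k[hi]))
    if np.any(lo):
        out[lo] = np.maximum(stats.norm.cdf(h[lo]) + stats.norm.cdf(k[lo]) - 1.0, 0.0)
    if np.any(mid):
        hm, km, rm = h[mid], k[mid], r[mid]
        denom = np.sqrt((1.0 - rm) * (1.0 + rm))
        a_h = (km - rm * hm) / (hm * denom)
        a_k = (hm - rm * km) / (km * denom)
        delta = np.where(hm * km < 0, 0.5, 0.0)
        out[mid] = (
            0.5 * (stats.norm.cdf(hm) + stats.norm.cdf(km))
            - owens_t(hm, a_h)
            - owens_t(km, a_k)
            - delta
        )
    return np.clip(out, 0.0, 1.0)


def icer_ratio_cdf(
    t: np.ndarray,
    mean_cost: float,
    mean_benefit: float,
    sd_cost: float,
    sd_benefit: float,
    rho: float,
) -> np.ndarray:
    """Exact CDF of the ICER ΔC/ΔE for bivariate-normal (ΔC, ΔE).

    Decomposes P(ΔC/ΔE ≤ t) = P(U ≤ 0) + P(V ≤ 0) − 2 P(U ≤ 0, V ≤ 0) with
    U = ΔC − t ΔE and V = ΔE, which is valid for a denominator of either
    sign. Degenerate margins reduce to the corresponding indicator/normal
    limits.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    with np.errstate(over="ignore"):
        return _icer_ratio_cdf_impl(t, mean_cost, mean_benefit, sd_cost, sd_benefit, rho)


def _icer_ratio_cdf_impl(t, mean_cost, mean_benefit, sd_cost, sd_benefit, rho):
    mu_u = mean_cost - t * mean_benefit
    var_u = sd_cost**2 - 2 * t * rho * sd_cost * sd_benefit + (t * sd_benefit) ** 2
    var_u = np.maximum(var_u, 0.0)
    sd_u = np.sqrt(var_u)

    if sd_benefit == 0:
        if mean_benefit > 0:
            return _halfline_cdf(mu_u, sd_u, upper=False)
        return _halfline_cdf(mu_u, sd_u, upper=True)

    p_v = stats.norm.cdf(-mean_benefit / sd_benefit)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(sd_u > 0, -mu_u / np.where(sd_u > 0, sd_u, 1.0), 0.0)
    p_u = np.where(sd_u > 0, stats.norm.cdf(h), (mu_u <= 0).astype(float))
    cov_uv = rho * sd_cost * sd_benefit - t * sd_benefit**2
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(sd_u > 0, cov_uv / (np.where(sd_u > 0, sd_u, 1.0) * sd_benefit), 0.0)
    p_uv = _bvn_cdf(h, -mean_benefit / sd_benefit, r)
    # degenerate U: joint collapses to the indicator times the V margin
    p_uv = np.where(sd_u > 0, p_uv, (mu_u <= 0) * p_v)
    return np.clip(p_u + p_v - 2 * p_uv, 0.0, 1.0)


def _halfline_cdf(mu_u, sd_u, upper):
    out = np.empty_like(mu_u)
    pos = sd_u > 0
    z = np.where(pos, -mu_u / np.where(pos, sd_u, 1.0), 0.0)
    if upper:
        out = np.where(pos, stats.norm.sf(z), (mu_u >= 0).astype(float))
    else:
        out = np.where(pos, stats.norm.cdf(z), (mu_u <= 0).astype(float))
    return out


def _fit_sds_to_icer_cdf(
    t_points: np.ndarray,
    target_probs: np.ndarray,
    means: tuple[float, float],
    rho_fixed: float,
) -> tuple[float, float, float]:
    """Least-squares fit of (σ_C, σ_E) to ICER CDF data with ρ held fixed.

    Deterministic multi-start: a rough ICER standard deviation is read off
    the target CDF, and five starts allocate its variance between the cost
    and benefit margins in fractions {0, ¼, ½, ¾, 1}. Returns the
    lowest-residual solution (ties by smaller σ_C).
    """
    mean_c, mean_e = means
    if mean_e == 0:
        raise ValueError("ICER undefined: incremental benefit is zero")
    icer0 = mean_c / mean_e

    # rough spread of the ICER from the 10-90% span of the target CDF
    lo = np.interp(0.1, target_probs, t_points, left=t_points[0], right=t_points[-1])
    hi = np.interp(0.9, target_probs, t_points, left=t_points[0], right=t_points[-1])
    sd_icer = max((hi - lo) / 2.563, 1e-3 * max(abs(icer0), 1.0))

    def residual(x):
        sd_c, sd_e = x
        model = icer_ratio_cdf(t_points, mean_c, mean_e, sd_c, sd_e, rho_fixed)
        return model - target_probs

    ub_c = 100.0 * max(abs(mean_c), sd_icer * abs(mean_e), 1.0)
    ub_e = 100.0 * max(abs(mean_e), 1.0)
    best = None
    for f in (0.0, 0.25, 0.5, 0.75, 1.0):
        x0 = np.array(
            [
                max(np.sqrt(1 - f) * sd_icer * abs(mean_e), 1e-9),
                max(np.sqrt(f) * sd_icer * abs(mean_e) / max(abs(icer0), 1e-9), 1e-9),
            ]
        )
        x0 = np.minimum(x0, [ub_c * 0.99, ub_e * 0.99])
        try:
            sol = optimize.least_squares(
                residual,
                x0,
                bounds=([0.0, 0.0], [ub_c, ub_e]),
                xtol=_FIT_TOL,
                ftol=_FIT_TOL,
                gtol=_FIT_TOL,
                max_nfev=_MAX_NFEV,
            )
        except Exception:  # singular jacobian etc.: try the next start
            continue
        res = float(np.sum(sol.fun**2))
        cand = (res, float(sol.x[0]), float(sol.x[1]))
        if best is None or cand < best:
            best = cand
    if best is None:
        raise ReconstructionError("ICER distribution fit failed from every start")
    return best[1], best[2], best[0]


def from_icer_histogram(
    bin_edges: Sequence[float],
    counts: Sequence[float],
    means: tuple[float, float],
    rho_fixed: float = 0.0,
) -> JointUncertainty:
    """Invert an ICER histogram by matching its CDF at the bin edges.

    The empirical CDF is 0 at the first edge and cumulative-count based at
    the rest; (σ_C, σ_E) minimise the squared distance to the exact ratio
    CDF of the bivariate normal with the study's point-estimate means and ρ
    held at ``rho_fixed``. A poor fit is reported as a diagnostic (large
    ``fit_residual``), never silently discarded.
    """
    edges = np.asarray(bin_edges, dtype=float)
    cts = np.asarray(counts, dtype=float)
    if edges.size != cts.size + 1:
        raise ValueError("need len(bin_edges) == len(counts) + 1")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    if np.any(cts < 0) or cts.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    target = np.concatenate([[0.0], np.cumsum(cts)]) / cts.sum()
    sd_c, sd_e, res = _fit_sds_to_icer_cdf(edges, target, means, rho_fixed)
    diag = ("poor_fit",) if np.sqrt(res / edges.size) > _POOR_FIT_RMS else ()
    return JointUncertainty(
        sd_c, sd_e, rho_fixed if (sd_c > 0 and sd_e > 0) else 0.0,
        diagnostics=diag, fit_residual=res,
    )


def from_icer_cdf(
    points: Sequence[tuple[float, float]],
    means: tuple[float, float],
    rho_fixed: float = 0.0,
) -> JointUncertainty:
    """Invert tabulated ICER CDF points; same fit as :func:`from_icer_histogram`."""
    pts = sorted((float(t), float(p)) for t, p in points)
    if len(pts) < 3:
        raise InsufficientDataError(f"need at least 3 CDF points, got {len(pts)}")
    t = np.array([p[0] for p in pts])
    q = np.array([p[1] for p in pts])
    if np.any(np.diff(q) < 0) or np.any((q < 0) | (q > 1)):
        raise ValueError("cumulative probabilities must be non-decreasing in [0, 1]")
    sd_c, sd_e, res = _fit_sds_to_icer_cdf(t, q, means, rho_fixed)
    diag = ("poor_fit",) if np.sqrt(res / t.size) > _POOR_FIT_RMS else ()
    return JointUncertainty(
        sd_c, sd_e, rho_fixed if (sd_c > 0 and sd_e > 0) else 0.0,
        diagnostics=diag, fit_residual=res,
    )


# ---------------------------------------------------------------------------
# CEAC inversion
# ---------------------------------------------------------------------------


def ceac_probability(
    lam: np.ndarray,
    mean_cost: float,
    mean_benefit: float,
    sd_cost: float,
    sd_benefit: float,
    rho: float,
) -> np.ndarray:
    """P(λ ΔE − ΔC ≥ 0) = Φ(m(λ)/s(λ)) under bivariate normality.

    m(λ) = λ Δē − Δc̄ and s(λ)² = λ² σ_E² − 2 λ ρ σ_E σ_C + σ_C².
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    m = lam * mean_benefit - mean_cost
    s2 = (lam * sd_benefit) ** 2 - 2 * lam * rho * sd_benefit * sd_cost + sd_cost**2
    s = np.sqrt(np.maximum(s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, m / np.where(s > 0, s, 1.0), 0.0)
    out = np.where(s > 0, stats.norm.cdf(z), np.where(m > 0, 1.0, np.where(m < 0, 0.0, 0.5)))
    return out


def _ceac_probit_start(lam, probs, mean_c, mean_e):
    """Warm start: recover s(λ)² where the probit is informative, then fit
    its quadratic coefficients in λ by ordinary least squares."""
    m = lam * mean_e - mean_c
    z = stats.norm.ppf(np.clip(probs, 1e-6, 1 - 1e-6))
    keep = (np.abs(z) > 1e-6) & (np.abs(m) > 0)
    if keep.sum() < 3:
        return None
    s2 = (m[keep] / z[keep]) ** 2
    X = np.column_stack([lam[keep] ** 2, lam[keep], np.ones(keep.sum())])
    coef, *_ = np.linalg.lstsq(X, s2, rcond=None)
    a, b, c = coef
    if a <= 0 or c <= 0:
        return None
    sd_e, sd_c = np.sqrt(a), np.sqrt(c)
    rho = float(np.clip(-b / (2 * sd_e * sd_c), -0.999, 0.999))
    return np.array([sd_c, sd_e, rho])


def from_ceac(
    points: Sequence[tuple[float, float]], means: tuple[float, float]
) -> JointUncertainty:
    """Invert a cost-effectiveness acceptability curve to (σ_C, σ_E, ρ).

    Constrained least squares on the probability scale against
    :func:`ceac_probability`, multi-started from a probit-based warm start
    plus a deterministic grid. With exactly three points the fit must
    interpolate them (residual below tolerance) or the curve is declared
    inconsistent with the stated means.
    """
    pts = sorted((float(l), float(p)) for l, p in points)
    lam = np.array([p[0] for p in pts])
    probs = np.array([p[1] for p in pts])
    if len(set(lam.tolist())) < 3:
        raise InsufficientDataError("need at least 3 distinct willingness-to-pay values")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("acceptability probabilities must lie in [0, 1]")
    if np.allclose(probs, probs[0]):
        raise ReconstructionError(
            "CEAC is flat: the uncertainty scale is unidentifiable from it"
        )
    mean_c, mean_e = means

    def residual(x):
        return ceac_probability(lam, mean_c, mean_e, x[0], x[1], x[2]) - probs

    scale_c = max(abs(mean_c), np.max(np.abs(lam)) * max(abs(mean_e), 1e-9), 1.0)
    scale_e = max(abs(mean_e), 1.0)
    starts = [
        np.array([cv * scale_c, cv * scale_e, 0.0]) for cv in (0.05, 0.2, 0.5, 1.0)
    ]
    warm = _ceac_probit_start(lam, probs, mean_c, mean_e)
    if warm is not None:
        starts.insert(0, warm)
    ub = [100 * scale_c, 100 * scale_e, 1.0]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [1e-9, 1e-9, -0.999], [ub[0] * 0.99, ub[1] * 0.99, 0.999])
        try:
            sol = optimize.least_squares(
                residual,
                x0,
                bounds=([0.0, 0.0, -1.0], ub),
                xtol=_FIT_TOL,
                ftol=_FIT_TOL,
                gtol=_FIT_TOL,
                max_nfev=_MAX_NFEV,
            )
        except Exception:
            continue
        res = float(np.sum(sol.fun**2))
        cand = (res, float(sol.x[0]), float(sol.x[1]), float(sol.x[2]))
        if best is None or cand < best:
            best = cand
    if best is None:
        raise ReconstructionError("CEAC fit failed from every start")
    res, sd_c, sd_e, rho = best
    if lam.size == 3 and res > 1e-6:
        raise ReconstructionError(
            "three CEAC points could not be interpolated; probabilities are "
            "inconsistent with the stated means",
            residual=res,
        )
    diag = ("poor_fit",) if np.sqrt(res / lam.size) > _POOR_FIT_RMS else ()
    return JointUncertainty(sd_c, sd_e, rho, diagnostics=diag, fit_residual=res)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def needs_pooled(evidence) -> bool:
    """True when reconstructing this payload requires the pooled correlation."""
    if evidence is None:
        return True
    if evidence.medium in ("mean_se", "mean_ci", "icer_histogram", "icer_cdf"):
        return evidence.rho is None
    return False


def reconstruct(
    record: InterventionRecord,
    pooled: "Optional[PooledUncertainty]" = None,
    *,
    pairs_mode: str = "parametric",
    range_convention: str = "extremes_uniform",
    tornado_attribution: str = "cost",
) -> JointUncertainty:
    """Dispatch a record's payload to its medium-specific inversion.

    Raises the medium-specific error tagged with the intervention id; absent
    evidence is a caller error here (it is handled by exploratory imputation,
    not reconstruction).
    """
    ev = record.evidence
    if ev is None:
        raise ValueError(
            f"intervention {record.id!r} has no sensitivity-analysis payload; "
            "use exploratory imputation"
        )
    means = (record.delta_cost_pp, record.delta_benefit_pp)
    try:
        if ev.medium == "mean_se":
            ju = from_mean_se(ev.se_cost, ev.se_benefit, ev.rho, pooled)
        elif ev.medium == "mean_ci":
            ju = from_mean_ci(ev.ci_cost, ev.ci_benefit, ev.level, ev.rho, pooled)
            ju = _flag_asymmetric_ci(ju, ev, record)
        elif ev.medium in ("raw_pairs", "scatter_points"):
            ju = from_raw_pairs(ev.pairs, mode=pairs_mode)
        elif ev.medium == "univariate_table":
            ju = from_univariate_table(ev.rows, range_convention)
        elif ev.medium == "tornado_icer":
            base = ev.base_icer
            if base is None:
                if record.delta_benefit_pp == 0:
                    raise ValueError("ICER undefined: incremental benefit is zero")
                base = record.delta_cost_pp / record.delta_benefit_pp
            ju = from_tornado_icer(
                base, ev.bars, record.delta_benefit_pp,
                attribution=tornado_attribution, range_convention=range_convention,
            )
        elif ev.medium == "icer_histogram":
            rho, diag = _default_rho(ev.rho, pooled)
            ju = from_icer_histogram(ev.bin_edges, ev.counts, means, rho)
            ju = replace(ju, diagnostics=ju.diagnostics + diag)
        elif ev.medium == "icer_cdf":
            rho, diag = _default_rho(ev.rho, pooled)
            ju = from_icer_cdf(ev.points, means, rho)
            ju = replace(ju, diagnostics=ju.diagnostics + diag)
        elif ev.medium == "ceac":
            ju = from_ceac(ev.points, means)
        else:  # pragma: no cover - pydantic rejects unknown tags upstream
            raise SchemaError(f"unknown sensitivity-analysis medium {ev.medium!r}")
    except Exception as exc:
        if not getattr(exc, "_voihbp_tagged", False):
            exc.args = (f"[{record.id}] {exc.args[0] if exc.args else exc}",) + exc.args[1:]
            exc._voihbp_tagged = True
        raise
    return replace(ju, provenance="reconstructed")


def _flag_asymmetric_ci(ju, ev, record):
    """Flag intervals whose midpoint sits far from the point estimate.

    The symmetric-width formula is still applied, but an asymmetry beyond
    20% of the half-width suggests a non-normal reported distribution.
    """
    flags = []
    for (lo, hi), mean in (
        (ev.ci_cost, record.delta_cost_pp),
        (ev.ci_benefit, record.delta_benefit_pp),
    ):
        half = (hi - lo) / 2
        if half > 0 and abs((lo + hi) / 2 - mean) > 0.2 * half:
            flags.append("asymmetric_ci")
            break
    if flags:
        return replace(ju, diagnostics=ju.diagnostics + tuple(flags))
    return ju
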