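# Methods

This note documents the statistical model, the per-medium reconstruction
conventions, the simulation and value-of-information machinery, the
synthetic-data generator, and the numerical choices — including the places
where the problem is genuinely under-determined and the package had to fix
a convention.

## Decision model

For each candidate intervention the population net health effect over the
delivery horizon is

    pNHE = A · N · c · (ΔE − ΔC/k),

with ΔC the incremental cost per patient (currency), ΔE the incremental
DALYs averted per patient, k > 0 the health opportunity cost (currency per
DALY averted displaced at the margin of the health system), N ≥ 0 the
annual eligible population, c ∈ [0, 1] realistic coverage, and
A = Σ_{t=0}^{T−1}(1+r)^{−t} the annuity factor (first cohort undiscounted;
A = T at r = 0, A = 1 at T = 1).

Defaults follow the Malawi application that motivated the tool: T = 20
years, r = 3%/year for both costs and benefits, k = US$61 per DALY
averted. A separate benefit discount rate is accepted (each margin then
gets its own annuity); the population model treats N as an annual cohort
treated each year for T years, with a `one_off` option (A = 1) for a
prevalent pool reached once. Which of the two the original tool uses is
not stated; the annual-cohort reading matches "scaled to the target
population over the time horizon" with a single N input.

Decision rule: include iff E[pNHE] > 0 (strict; a point mass at zero is
excluded). Decision uncertainty: the equal-tail interval at
`interval_level` (default 95%, configurable — the level of published error
bars is rarely stated) strictly spans zero.

Value of research: per-decision EVPI,
E[max(pNHE, 0)] − max(E[pNHE], 0) ≥ 0, estimated by Monte Carlo and
cross-checked against the normal closed form
σφ(μ/σ) − |μ|Φ(−|μ|/σ) (valid because pNHE is a linear map of the
bivariate-normal uncertainty). EVPI is reported on the same discounted,
population scale as pNHE, with no research-lag or implementation-delay
adjustment. Per-parameter EVPPI and study-specific EVSI are out of scope:
the evidence base carries no parameter-level structure.

## Uncertainty reconstruction

The target object is the joint distribution of (ΔC, ΔE) per patient. The
parametric family is bivariate normal on the incremental scale — the
minimal assumption expressible from two variances and a correlation, which
is all any of the media can support. Raw simulation pairs may
alternatively be kept as an empirical distribution and resampled
(`pairs_mode=empirical`).

Per-medium conventions (each enforced to σ ≥ 0, ρ ∈ [−1, 1]):

* **Standard errors** map directly: σ_C = se_C, σ_E = se_E.
* **Confidence intervals** at level ℓ: σ = (upper − lower)/(2 z_{(1+ℓ)/2}),
  independently per margin. The symmetric-width formula is applied even to
  asymmetric intervals; when the interval midpoint sits more than 20% of
  the half-width away from the point estimate an `asymmetric_ci`
  diagnostic is attached (the reported distribution was probably not
  normal).
* **Raw pairs / scatter points**: sample moments with the n−1 denominator;
  at least 3 pairs. A zero-variance margin forces ρ = 0 with a warning
  rather than an error.
* **Univariate tables** (ΔC, ΔE at each parameter's low/high setting):
  each parameter contributes variance width²/12 per margin and covariance
  (product of signed widths)/12 — the "extremes of a uniform" reading,
  chosen because scenario endpoints are typically plausible extremes, not
  confidence limits; `range_convention=interval95` divides half-ranges by
  1.959964 instead. Parameters are summed as independent (univariate
  analyses provide no joint information). One varied parameter necessarily
  yields |ρ| = 1.
* **Tornado plots of ICERs**: bar widths are converted to an ICER variance
  (same range conventions) and summed as independent. The medium cannot
  split uncertainty between margins, so it is attributed entirely to one:
  `cost` (default, σ_C = sd(ICER)·|Δē|, keeps the DALY estimate fixed) or
  `benefit` (σ_E solves the quadratic making Δc̄/(Δē ± zσ_E) span the
  ICER interval at matching 95% quantiles).
* **ICER histogram / CDF**: (σ_C, σ_E) minimize the squared distance
  between the reported cumulative distribution and the exact CDF of the
  ratio ΔC/ΔE under the bivariate normal with the study's point-estimate
  means. The ratio CDF is evaluated exactly via
  P(U ≤ 0) + P(V ≤ 0) − 2P(U ≤ 0, V ≤ 0) with U = ΔC − tΔE, V = ΔE,
  valid for a denominator of either sign; the bivariate normal rectangle
  probability uses Owen's T function (accurate at the near-unit
  correlations the fit explores; naive quadrature demonstrably admits
  spurious optima there). ρ is held fixed, not fitted: one ratio margin
  cannot identify three shape parameters. It defaults to the pooled
  average (0 with a warning if no pool exists).
* **CEAC**: under bivariate normality
  P(λΔE − ΔC ≥ 0) = Φ(m(λ)/s(λ)), m(λ) = λΔē − Δc̄,
  s(λ)² = λ²σ_E² − 2λρσ_Eσ_C + σ_C². All three parameters are fitted by
  constrained least squares on the probability scale. A flat curve is
  rejected as unidentifiable; with exactly three points the fit must
  interpolate (residual < 1e−6) or the curve is declared inconsistent with
  the stated means.

Fitting: `scipy.optimize.least_squares` with bounds (σ ≥ 0, ρ ∈ [−1, 1]),
tolerances 1e−8, at most 200 function evaluations per start, multi-started
from deterministic initial points (a rough ICER spread read off the target
CDF, allocated to the margins in fractions {0, ¼, ½, ¾, 1}; the CEAC adds
a probit-based warm start that recovers s(λ)² by linear least squares).
The lowest residual wins, ties by smaller σ_C. A poor but convergent fit
(RMS residual > 0.05) is returned with a `poor_fit` diagnostic and the
residual attached — reported, never silently accepted or discarded; an
error is raised only when every start fails.

### Pooling and exploratory imputation

Reconstruction runs in two passes so pooling never feeds on its own
output: media that determine their own ρ are inverted first, and the
average of their correlations fills ρ for the media that cannot identify
it. Interventions with no payload at all receive the arithmetic average of
the informed set's (σ_C, σ_E, ρ) — `imputation_mode=absolute`, the
literal reading of averaging "the values extracted" — or, with
`imputation_mode=relative`, the average coefficients of variation rescaled
by their own point estimates. Both are provided because averaging absolute
variances across interventions with very different cost scales is
statistically questionable; the choice is recorded in the run manifest.
Imputed results carry `provenance=imputed` into every output row: they are
exploratory, to be complemented with expert judgement, not evidence.
Degenerate entries (σ = 0) count toward the σ averages but not the CV
averages.

## Simulation

One (ΔC, ΔE) pair is drawn per simulation and applied to all T years:
the propagated uncertainty is parameter uncertainty about the true values,
not year-to-year fluctuation. Negative draws on either margin are allowed
(incremental quantities can legitimately be negative); nothing is
truncated. The normal family uses the explicit construction
Δc = μ_c + σ_C z₁, Δe = μ_e + σ_E(ρz₁ + √(1−ρ²) z₂); the empirical family
resamples stored pairs with replacement recentred to the point-estimate
means.

Costs are divided by k *before* noise is added (the draw is built from
μ_c/k and σ_C/k). This makes the pNHE draws exactly invariant — bit for
bit — under a common rescaling of all cost quantities and k, i.e. under a
change of currency unit.

Per-intervention random streams are seeded by SHA-256 of
`(global seed, intervention id)`, so every intervention's draws are
independent of the order in which the workbook lists them, and reruns are
exactly reproducible. Default 10 000 simulations; the package's own
validation runs use 10⁵, where Monte Carlo error on the EVPI of an
uncertain decision is well under 1%.

## Synthetic evidence bases

The generator draws a ground-truth (Δc̄, Δē, σ_C, σ_E, ρ, N, c) per
intervention and renders it in a chosen medium exactly as a study would
report it: summary media computed exactly; pairs and histograms sampled
(10⁴ raw pairs, 500 scatter points, 10⁵ histogram draws over 20 bins
spanning the central 99% with tail mass folded into the end bins — the
axis truncation any real plot applies, and without which a histogram of a
heavy-tailed ICER carries almost no shape information); CDFs and CEACs
evaluated from the exact ratio/acceptability formulas. Univariate tables
use two orthogonal parameter effects whose summed variances and covariance
reproduce (σ_C, σ_E, ρ); tornado truths carry cost-only uncertainty
(σ_E = 0) matching the cost-attributed convention; histogram/CDF truths
use ρ = 0, the value the pipeline will (approximately) hold fixed.

The default spec has 21 interventions in the published medium mix
(5 univariate / 2 tornado / 2 raw / 1 scatter / 1 histogram / 1 CDF /
8 CI / 1 SE) with expected pNHE placed at ±4 or ±0.5 population standard
deviations — the four qualitative regimes: clearly cost-effective, clearly
not, and genuinely uncertain on either side. Costs span ~US$70–270 per
patient with 35% cost CV (15% for the ratio media, keeping the ICER
denominator safely positive), benefit SDs 0.12–0.25 DALYs, correlations in
[−0.3, 0.3], populations 23k–83k/year at 40–80% coverage.

What passing recovery tests on these fixtures shows — and what it does
not: the generator emulates *reporting*, not *modelling*. Real studies
have non-normal joint distributions, asymmetric intervals, correlated
parameters behind their univariate ranges, digitization error, and
histograms with unknown truncation rules. Exact recovery here certifies
the inversions against their own stated assumptions; on real data the
conventions above are assumptions to be varied (`range_convention`,
`tornado_attribution`, `imputation_mode`, `pairs_mode` exist for exactly
that purpose).

## Numerical and interface details

* Quantiles: linear interpolation of order statistics (numpy default).
* EVPI is clamped at zero against floating rounding only; the estimator is
  non-negative in exact arithmetic.
* All ranking ties break by intervention id ascending; reruns of
  `voihbp run` are byte-identical, and the manifest records the input
  hash, seeds, configuration and pooled values.
* Workbook schema: sheets `globals` (key/value), `interventions`, and one
  `payload_*` sheet per medium keyed by `intervention_id`; a CSV directory
  with the same names is equivalent (and is the byte-deterministic fixture
  format — XLSX metadata timestamps are pinned so workbook fixtures
  compare equal on load). An intervention may appear in at most one
  payload sheet; appearing in none marks it for exploratory imputation.
  Loading refuses invalid files with one diagnostic per violation;
  `validate_evidence_base` returns the same diagnostics programmatically.
* Degenerate inputs: zero-width intervals, single occupied histogram bins
  and step CDFs reconstruct to (near-)point masses; zero-variance margins
  force ρ = 0 with a warning; a flat CEAC and a zero incremental benefit
  under any ICER medium are errors.

## Known limitations

* Bivariate normality is an assumption of convenience; no lognormal-cost
  or other skewed option in this version.
* The ICER histogram/CDF inversion is only as identified as the ratio
  distribution's shape: when the denominator CV is very small the split
  between σ_C and σ_E is weakly determined (the fit then still matches the
  induced ICER spread well).
* Pooled imputation borrows indiscriminately across disease areas; no
  covariate-based borrowing or hierarchical shrinkage.
* No correlation of uncertainty across interventions, no dynamic
  transmission effects, no coverage ramp-up, no research cost or delay in
  the EVPI.
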