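# voihbp

**Value-of-information analysis for health benefits package (HBP) design,
from the sensitivity-analysis summaries that cost-effectiveness studies
actually publish.**

Governments designing a health benefits package must decide, under an
uncertain evidence base, which interventions to fund — and which of those
decisions are worth de-risking with further research. The natural decision
metric is the *population net health effect* (pNHE) of funding an
intervention, in net DALYs averted:

```
pNHE = A · N · c · (ΔE − ΔC / k)
```

where ΔC and ΔE are the per-patient incremental cost and incremental DALYs
averted against the status quo, k is the health opportunity cost (spending
k displaces one DALY averted elsewhere in the health system), N the annual
eligible population, c realistic coverage, and A = Σ_{t=0}^{T−1} (1+r)^{−t}
the discounted annuity over the delivery horizon T. An intervention with
E[pNHE] > 0 belongs in the package; the decision is *uncertain* when the
plausible range of pNHE spans both net gains and net losses.

The value of resolving that uncertainty is the expected value of perfect
information for the include/exclude decision,

```
EVPI = E[max(pNHE, 0)] − max(E[pNHE], 0)
```

— the expected net DALYs forgone by deciding on current evidence. Ranking
interventions by EVPI ranks them as research priorities on the same scale
as the funding decision itself.

The obstacle in practice is that published studies almost never report the
joint distribution of (ΔC, ΔE). They report one of eight summaries, and
`voihbp` inverts each of them back to the variances σ_C, σ_E and
correlation ρ of a bivariate normal on the incremental scale (or keeps the
raw pairs as an empirical distribution):

| reported medium | inversion |
|---|---|
| standard errors of ΔC, ΔE | identity |
| confidence intervals | σ = width / (2 z) |
| raw PSA simulations / digitized scatter | sample moments (or resampling) |
| univariate low/high table | per-parameter variances width²/12, summed as independent; covariance signed by co-movement |
| tornado plot of ICERs | summed ICER variance attributed to one margin (cost by default) |
| ICER histogram | least-squares fit of the exact ratio-of-correlated-normals CDF at the bin edges |
| ICER cumulative distribution | same fit against the tabulated points |
| CEAC | constrained least squares on P(λΔE − ΔC ≥ 0) = Φ(m(λ)/s(λ)) |

Interventions whose studies report no sensitivity analysis at all get an
*exploratory* uncertainty imputed from the average of the reconstructed
ones, and stay flagged `imputed` in every output.

## Worked example

```python
import voihbp as v

eb = v.EvidenceBase(
    context=v.DecisionContext(time_horizon_years=20, discount_rate=0.03,
                              opportunity_cost_per_daly=61.0,
                              n_simulations=100_000, seed=1),
    interventions=(
        v.InterventionRecord(
            id="circumcision", name="male circumcision",
            delta_cost_pp=120.0, delta_benefit_pp=2.4,
            eligible_population=40_000, coverage=0.6,
            evidence=v.datamodel.MeanCIPayload(
                ci_cost=(10.0, 230.0), ci_benefit=(0.4, 4.4), rho=0.2),
        ),
        v.InterventionRecord(
            id="tb_firstline", name="first-line TB management",
            delta_cost_pp=90.0, delta_benefit_pp=3.0,
            eligible_population=25_000, coverage=0.7,
            evidence=v.datamodel.MeanSEPayload(se_cost=20.0, se_benefit=0.3, rho=0.0),
        ),
        v.InterventionRecord(
            id="new_programme", name="programme without sensitivity analysis",
            delta_cost_pp=150.0, delta_benefit_pp=1.0,
            eligible_population=30_000, coverage=0.5,
        ),
    ),
)
res = v.run_analysis(eb)
for r in res.views.by_pnhe:
    print(f"{r.intervention_id:14s} pNHE={r.expected_pnhe:12.0f} "
          f"[{r.interval[0]:12.0f}, {r.interval[1]:12.0f}] "
          f"{r.decision:7s} uncertain={r.decision_uncertain!s:5s} "
          f"EVPI={r.evpi:10.0f}  ({r.provenance})")
```

prints

```
tb_firstline   pNHE=      408742 [      174779,       641973] include uncertain=False EVPI=        10  (reconstructed)
circumcision   pNHE=      157659 [     -726451,      1040671] include uncertain=True  EVPI=    112032  (reconstructed)
new_programme  pNHE=     -335091 [     -722289,        54250] exclude uncertain=True  EVPI=      3768  (imputed)
```

Reading: first-line TB management is a safe buy — even its pessimistic
bound averts ~175k net DALYs, so research on it is worthless (EVPI ≈ 10).
Circumcision is expected to be cost-effective but could plausibly cause a
large net loss; resolving that uncertainty is worth up to ~112k net DALYs,
making it the research priority. The third programme reported no
sensitivity analysis; its exploratory (imputed) result suggests exclusion,
with modest value in checking.

## Command line

```bash
voihbp fixture --out eb/ --seed 0            # synthetic 21-intervention base + truth table
voihbp validate --input eb/                  # schema + invariant diagnostics
voihbp run --input eb/ --out results/ --seed 7 --nsim 100000
```

`run` writes three CSV rankings (by gross population health benefit, by
pNHE, by EVPI) plus a JSON manifest with the input hash, seeds,
configuration and pooled values; reruns are byte-identical. Evidence bases
can be a single XLSX workbook or a directory of CSVs (see
`docs/methods.md` for the sheet schema and all method switches).

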