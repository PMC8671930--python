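"""Read and write evidence bases and result tables.

The on-disk evidence base is either a single XLSX workbook or a directory of
identically named CSV files, one table per sheet:

* ``globals`` — two columns (key, value): time_horizon_years, discount_rate,
  optional benefit_discount_rate, opportunity_cost_per_daly, n_simulations,
  seed, interval_level. Missing keys fall back to the package defaults.
* ``interventions`` — intervention_id, name, delta_cost_pp,
  delta_benefit_pp, eligible_population, coverage.
* one ``payload_*`` sheet per reporting medium, keyed by intervention_id; an
  intervention may appear in at most one payload sheet, and appearing in
  none simply marks it for exploratory imputation.

Results are written as three CSV rankings plus a JSON run manifest (input
hash, seeds, configuration, pooled values) so a run can be audited and
reproduced byte for byte.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

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
    validate_evidence_base,
)
from .errors import EvidenceValidationError, ParseError, SchemaError

SHEETS = (
    "globals",
    "interventions",
    "payload_mean_se",
    "payload_mean_ci",
    "payload_pairs",
    "payload_univariate",
    "payload_tornado_icer",
    "payload_icer_histogram",
    "payload_icer_cdf",
    "payload_ceac",
)

_GLOBAL_KEYS = {
    "time_horizon_years": int,
    "discount_rate": float,
    "benefit_discount_rate": float,
    "opportunity_cost_per_daly": float,
    "n_simulations": int,
    "seed": int,
    "interval_level": float,
}

_PAYLOAD_COLUMNS = {
    "payload_mean_se": ["intervention_id", "se_cost", "se_benefit", "rho"],
    "payload_mean_ci": [
        "intervention_id",
        "ci_cost_lower",
        "ci_cost_upper",
        "ci_benefit_lower",
        "ci_benefit_upper",
        "level",
        "rho",
    ],
    "payload_pairs": ["intervention_id", "delta_cost", "delta_benefit", "source"],
    "payload_univariate": [
        "intervention_id",
        "param_id",
        "dc_low",
        "dc_high",
        "de_low",
        "de_high",
    ],
    "payload_tornado_icer": [
        "intervention_id",
        "param_id",
        "icer_low",
        "icer_high",
        "base_icer",
    ],
    "payload_icer_histogram": ["intervention_id", "bin_lower", "bin_upper", "count", "rho"],
    "payload_icer_cdf": ["intervention_id", "icer", "cumulative_probability", "rho"],
    "payload_ceac": ["intervention_id", "wtp", "prob_ce"],
}

# columns that may legitimately be blank
_OPTIONAL_COLUMNS = {"rho", "level", "base_icer", "source", "benefit_discount_rate", "name"}


def _read_tables(path: Path, fmt: Optional[str]) -> dict[str, pd.DataFrame]:
    path = Path(path)
    if fmt is None:
        fmt = "csv_dir" if path.is_dir() else "workbook"
    if fmt == "workbook":
        if not path.exists():
            raise FileNotFoundError(path)
        sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
        return {name: df for name, df in sheets.items()}
    if fmt == "csv_dir":
        if not path.is_dir():
            raise FileNotFoundError(path)
        out = {}
        for name in SHEETS:
            f = path / f"{name}.csv"
            if f.exists():
                out[name] = pd.read_csv(f)
        return out
    raise ValueError(f"unknown format {fmt!r}")


def _require_columns(df: pd.DataFrame, sheet: str, cols: Sequence[str]):
    for col in cols:
        if col in _OPTIONAL_COLUMNS:
            continue
        if col not in df.columns:
            raise SchemaError(f"sheet {sheet!r} is missing required column {col!r}")


def _num(df: pd.DataFrame, sheet: str, col: str, optional: bool = False):
    if col not in df.columns:
        if optional:
            return pd.Series([np.nan] * len(df), index=df.index)
        raise SchemaError(f"sheet {sheet!r} is missing required column {col!r}")
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(
            f"sheet {sheet!r}, column {col!r}, row {row + 2}: "
            f"expected a number, got {raw[row]!r}"
        )
    return coerced


def _opt_float(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def _parse_globals(tables: dict[str, pd.DataFrame]) -> DecisionContext:
    if "globals" not in tables:
        raise SchemaError("required sheet 'globals' is missing")
    df = tables["globals"]
    _require_columns(df, "globals", ["key", "value"])
    kwargs = {}
    for _, row in df.iterrows():
        key = str(row["key"]).strip()
        if key not in _GLOBAL_KEYS:
            raise SchemaError(f"sheet 'globals': unknown parameter {key!r}")
        if pd.isna(row["value"]):
            continue
        try:
            kwargs[key] = _GLOBAL_KEYS[key](row["value"])
        except (TypeError, ValueError):
            raise ParseError(
                f"sheet 'globals', parameter {key!r}: expected a number, "
                f"got {row['value']!r}"
            ) from None
    return DecisionContext(**kwargs)


def _parse_payloads(tables: dict[str, pd.DataFrame]) -> dict[str, object]:
    """Map intervention_id -> payload model; error on duplicates across media."""
    payloads: dict[str, object] = {}

    def put(iid, payload, sheet):
        if iid in payloads:
            raise EvidenceValidationError(
                [f"intervention {iid!r} has payloads in more than one medium (sheet {sheet!r})"]
            )
        payloads[iid] = payload

    def get(sheet):
        df = tables.get(sheet)
        if df is None or df.empty:
            return None
        _require_columns(df, sheet, _PAYLOAD_COLUMNS[sheet])
        return df

    df = get("payload_mean_se")
    if df is not None:
        se_c = _num(df, "payload_mean_se", "se_cost")
        se_e = _num(df, "payload_mean_se", "se_benefit")
        rho = _num(df, "payload_mean_se", "rho", optional=True)
        for i in df.index:
            put(
                str(df.loc[i, "intervention_id"]),
                MeanSEPayload(
                    se_cost=float(se_c[i]),
                    se_benefit=float(se_e[i]),
                    rho=_opt_float(rho[i]),
                ),
                "payload_mean_se",
            )

    df = get("payload_mean_ci")
    if df is not None:
        cols = {
            c: _num(df, "payload_mean_ci", c)
            for c in ("ci_cost_lower", "ci_cost_upper", "ci_benefit_lower", "ci_benefit_upper")
        }
        level = _num(df, "payload_mean_ci", "level", optional=True)
        rho = _num(df, "payload_mean_ci", "rho", optional=True)
        for i in df.index:
            put(
                str(df.loc[i, "intervention_id"]),
                MeanCIPayload(
                    ci_cost=(float(cols["ci_cost_lower"][i]), float(cols["ci_cost_upper"][i])),
                    ci_benefit=(
                        float(cols["ci_benefit_lower"][i]),
                        float(cols["ci_benefit_upper"][i]),
                    ),
                    level=float(level[i]) if not pd.isna(level[i]) else 0.95,
                    rho=_opt_float(rho[i]),
                ),
                "payload_mean_ci",
            )

    df = get("payload_pairs")
    if df is not None:
        dc = _num(df, "payload_pairs", "delta_cost")
        de = _num(df, "payload_pairs", "delta_benefit")
        for iid, grp in df.groupby("intervention_id", sort=False):
            source = "simulation"
            if "source" in df.columns:
                vals = grp["source"].dropna().unique()
                if len(vals):
                    source = str(vals[0])
            medium = "scatter_points" if source == "scatter" else "raw_pairs"
            pairs = tuple((float(dc[i]), float(de[i])) for i in grp.index)
            put(str(iid), PairsPayload(medium=medium, pairs=pairs), "payload_pairs")

    df = get("payload_univariate")
    if df is not None:
        cols = {c: _num(df, "payload_univariate", c) for c in ("dc_low", "dc_high", "de_low", "de_high")}
        for iid, grp in df.groupby("intervention_id", sort=False):
            rows = tuple(
                UnivariateRow(
                    param_id=str(df.loc[i, "param_id"]),
                    dc_low=float(cols["dc_low"][i]),
                    dc_high=float(cols["dc_high"][i]),
                    de_low=float(cols["de_low"][i]),
                    de_high=float(cols["de_high"][i]),
                )
                for i in grp.index
            )
            put(str(iid), UnivariatePayload(rows=rows), "payload_univariate")

    df = get("payload_tornado_icer")
    if df is not None:
        lo = _num(df, "payload_tornado_icer", "icer_low")
        hi = _num(df, "payload_tornado_icer", "icer_high")
        base = _num(df, "payload_tornado_icer", "base_icer", optional=True)
        for iid, grp in df.groupby("intervention_id", sort=False):
            bars = tuple(
                TornadoBar(
                    param_id=str(df.loc[i, "param_id"]),
                    icer_low=float(lo[i]),
                    icer_high=float(hi[i]),
                )
                for i in grp.index
            )
            b = base[grp.index].dropna()
            put(
                str(iid),
                TornadoICERPayload(
                    bars=bars, base_icer=float(b.iloc[0]) if len(b) else None
                ),
                "payload_tornado_icer",
            )

    df = get("payload_icer_histogram")
    if df is not None:
        lo = _num(df, "payload_icer_histogram", "bin_lower")
        hi = _num(df, "payload_icer_histogram", "bin_upper")
        ct = _num(df, "payload_icer_histogram", "count")
        rho = _num(df, "payload_icer_histogram", "rho", optional=True)
        for iid, grp in df.groupby("intervention_id", sort=False):
            idx = list(grp.index)
            edges = [float(lo[i]) for i in idx] + [float(hi[idx[-1]])]
            r = rho[idx].dropna()
            put(
                str(iid),
                ICERHistogramPayload(
                    bin_edges=tuple(edges),
                    counts=tuple(float(ct[i]) for i in idx),
                    rho=float(r.iloc[0]) if len(r) else None,
                ),
                "payload_icer_histogram",
            )

    df = get("payload_icer_cdf")
    if df is not None:
        icer = _num(df, "payload_icer_cdf", "icer")
        q = _num(df, "payload_icer_cdf", "cumulative_probability")
        rho = _num(df, "payload_icer_cdf", "rho", optional=True)
        for iid, grp in df.groupby("intervention_id", sort=False):
            r = rho[grp.index].dropna()
            put(
                str(iid),
                ICERCDFPayload(
                    points=tuple((float(icer[i]), float(q[i])) for i in grp.index),
                    rho=float(r.iloc[0]) if len(r) else None,
                ),
                "payload_icer_cdf",
            )

    df = get("payload_ceac")
    if df is not None:
        wtp = _num(df, "payload_ceac", "wtp")
        p = _num(df, "payload_ceac", "prob_ce")
        for iid, grp in df.groupby("intervention_id", sort=False):
            put(
                str(iid),
                CEACPayload(points=tuple((float(wtp[i]), float(p[i])) for i in grp.index)),
                "payload_ceac",
            )

    return payloads


def load_evidence_base(path, format: Optional[str] = None) -> EvidenceBase:
    """Load and validate an evidence base from a workbook or CSV directory.

    Raises :class:`SchemaError` / :class:`ParseError` for structural
    problems and :class:`EvidenceValidationError` (carrying every
    diagnostic) when the parsed base violates its invariants.
    """
    tables = _read_tables(Path(path), format)
    ctx = _parse_globals(tables)
    if "interventions" not in tables:
        raise SchemaError("required sheet 'interventions' is missing")
    df = tables["interventions"]
    _require_columns(
        df,
        "interventions",
        ["intervention_id", "name", "delta_cost_pp", "delta_benefit_pp", "eligible_population", "coverage"],
    )
    num = {
        c: _num(df, "interventions", c)
        for c in ("delta_cost_pp", "delta_benefit_pp", "eligible_population", "coverage")
    }
    payloads = _parse_payloads(tables)
    records = []
    seen = set()
    for i in df.index:
        iid = str(df.loc[i, "intervention_id"])
        if iid in seen:
            raise EvidenceValidationError([f"duplicate intervention id {iid!r}"])
        seen.add(iid)
        name = "" if "name" not in df.columns or pd.isna(df.loc[i, "name"]) else str(df.loc[i, "name"])
        records.append(
            InterventionRecord(
                id=iid,
                name=name,
                delta_cost_pp=float(num["delta_cost_pp"][i]),
                delta_benefit_pp=float(num["delta_benefit_pp"][i]),
                eligible_population=float(num["eligible_population"][i]),
                coverage=float(num["coverage"][i]),
                evidence=payloads.pop(iid, None),
            )
        )
    if payloads:
        raise EvidenceValidationError(
            [f"payload refers to unknown intervention id {k!r}" for k in sorted(payloads)]
        )
    eb = EvidenceBase(context=ctx, interventions=tuple(records))
    diags = validate_evidence_base(eb)
    if diags:
        raise EvidenceValidationError(diags)
    return eb


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def evidence_base_tables(eb: EvidenceBase) -> dict[str, pd.DataFrame]:
    """Render an in-memory evidence base to its on-disk table layout."""
    ctx = eb.context
    globals_rows = [
        ("time_horizon_years", ctx.time_horizon_years),
        ("discount_rate", ctx.discount_rate),
        ("opportunity_cost_per_daly", ctx.opportunity_cost_per_daly),
        ("n_simulations", ctx.n_simulations),
        ("seed", ctx.seed),
        ("interval_level", ctx.interval_level),
    ]
    if ctx.benefit_discount_rate is not None:
        globals_rows.insert(2, ("benefit_discount_rate", ctx.benefit_discount_rate))
    tables: dict[str, list[dict]] = {s: [] for s in SHEETS if s.startswith("payload_")}
    inter_rows = []
    for rec in eb.interventions:
        inter_rows.append(
            {
                "intervention_id": rec.id,
                "name": rec.name,
                "delta_cost_pp": rec.delta_cost_pp,
                "delta_benefit_pp": rec.delta_benefit_pp,
                "eligible_population": rec.eligible_population,
                "coverage": rec.coverage,
            }
        )
        ev = rec.evidence
        if ev is None:
            continue
        if ev.medium == "mean_se":
            tables["payload_mean_se"].append(
                {"intervention_id": rec.id, "se_cost": ev.se_cost, "se_benefit": ev.se_benefit, "rho": ev.rho}
            )
        elif ev.medium == "mean_ci":
            tables["payload_mean_ci"].append(
                {
                    "intervention_id": rec.id,
                    "ci_cost_lower": ev.ci_cost[0],
                    "ci_cost_upper": ev.ci_cost[1],
                    "ci_benefit_lower": ev.ci_benefit[0],
                    "ci_benefit_upper": ev.ci_benefit[1],
                    "level": ev.level,
                    "rho": ev.rho,
                }
            )
        elif ev.medium in ("raw_pairs", "scatter_points"):
            src = "scatter" if ev.medium == "scatter_points" else "simulation"
            for dc, de in ev.pairs:
                tables["payload_pairs"].append(
                    {"intervention_id": rec.id, "delta_cost": dc, "delta_benefit": de, "source": src}
                )
        elif ev.medium == "univariate_table":
            for row in ev.rows:
                tables["payload_univariate"].append(
                    {
                        "intervention_id": rec.id,
                        "param_id": row.param_id,
                        "dc_low": row.dc_low,
                        "dc_high": row.dc_high,
                        "de_low": row.de_low,
                        "de_high": row.de_high,
                    }
                )
        elif ev.medium == "tornado_icer":
            for bar in ev.bars:
                tables["payload_tornado_icer"].append(
                    {
                        "intervention_id": rec.id,
                        "param_id": bar.param_id,
                        "icer_low": bar.icer_low,
                        "icer_high": bar.icer_high,
                        "base_icer": ev.base_icer,
                    }
                )
        elif ev.medium == "icer_histogram":
            for j, c in enumerate(ev.counts):
                tables["payload_icer_histogram"].append(
                    {
                        "intervention_id": rec.id,
                        "bin_lower": ev.bin_edges[j],
                        "bin_upper": ev.bin_edges[j + 1],
                        "count": c,
                        "rho": ev.rho if j == 0 else None,
                    }
                )
        elif ev.medium == "icer_cdf":
            for j, (t, q) in enumerate(ev.points):
                tables["payload_icer_cdf"].append(
                    {
                        "intervention_id": rec.id,
                        "icer": t,
                        "cumulative_probability": q,
                        "rho": ev.rho if j == 0 else None,
                    }
                )
        elif ev.medium == "ceac":
            for lam, p in ev.points:
                tables["payload_ceac"].append({"intervention_id": rec.id, "wtp": lam, "prob_ce": p})

    out = {
        "globals": pd.DataFrame(globals_rows, columns=["key", "value"]),
        "interventions": pd.DataFrame(inter_rows),
    }
    for sheet, rows in tables.items():
        if rows:
            out[sheet] = pd.DataFrame(rows, columns=_PAYLOAD_COLUMNS[sheet])
    return out


def write_evidence_base(eb: EvidenceBase, path, format: str = "csv_dir") -> Path:
    """Write an evidence base to disk in the documented schema.

    CSV output is byte-deterministic; XLSX output has its workbook metadata
    pinned to a fixed timestamp so repeated writes compare equal on load.
    """
    path = Path(path)
    tables = evidence_base_tables(eb)
    if format == "csv_dir":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(path / f"{name}.csv", index=False)
        return path
    if format == "workbook":
        path.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for name, df in tables.items():
                df.to_excel(writer, sheet_name=name, index=False)
            props = writer.book.properties
            props.created = datetime.datetime(2000, 1, 1)
            props.modified = datetime.datetime(2000, 1, 1)
        return path
    raise ValueError(f"unknown format {format!r}")


RESULT_COLUMNS = [
    "rank",
    "intervention_id",
    "name",
    "expected_pop_benefit",
    "expected_pnhe",
    "pnhe_lower",
    "pnhe_upper",
    "decision",
    "decision_uncertain",
    "prob_cost_effective",
    "evpi",
    "provenance",
]


def _results_frame(results) -> pd.DataFrame:
    rows = []
    for rank, r in enumerate(results, start=1):
        rows.append(
            {
                "rank": rank,
                "intervention_id": r.intervention_id,
                "name": r.name,
                "expected_pop_benefit": r.expected_pop_benefit,
                "expected_pnhe": r.expected_pnhe,
                "pnhe_lower": r.interval[0],
                "pnhe_upper": r.interval[1],
                "decision": r.decision,
                "decision_uncertain": r.decision_uncertain,
                "prob_cost_effective": r.prob_cost_effective,
                "evpi": r.evpi,
                "provenance": r.provenance,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def sha256_of(path) -> str:
    path = Path(path)
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    results,
    out_dir,
    *,
    context=None,
    config=None,
    pooled=None,
    input_path=None,
) -> dict:
    """Write the three ranking tables and the run manifest; return the manifest.

    Tables: ``rank_by_population_benefit.csv`` (gross health gain),
    ``rank_by_pnhe.csv`` (net of opportunity costs, with EVPI attached in the
    same order) and ``rank_by_evpi.csv`` (research priority). Sort ties break
    by intervention id, so reruns are byte-identical.
    """
    from . import __version__
    from .voi import rank_interventions

    if not results:
        raise ValueError("no results to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    views = rank_interventions(results)
    files = {
        "rank_by_population_benefit.csv": views.by_population_benefit,
        "rank_by_pnhe.csv": views.by_pnhe,
        "rank_by_evpi.csv": views.by_evpi,
    }
    for fname, view in files.items():
        _results_frame(view).to_csv(out_dir / fname, index=False)
    n_uncertain = sum(r.decision_uncertain for r in results)
    manifest = {
        "package": "voihbp",
        "version": __version__,
        "input_sha256": sha256_of(input_path) if input_path else None,
        "context": context.model_dump() if context is not None else None,
        "config": dict(config) if config is not None else None,
        "pooled": None
        if pooled is None
        else {
            "mean_correlation": pooled.mean_correlation,
            "mean_sd_cost": pooled.mean_sd_cost,
            "mean_sd_benefit": pooled.mean_sd_benefit,
            "mean_cv_cost": pooled.mean_cv_cost,
            "mean_cv_benefit": pooled.mean_cv_benefit,
            "n_contributing": pooled.n_contributing,
        },
        "counts": {
            "interventions": len(results),
            "include": sum(r.decision == "include" for r in results),
            "exclude": sum(r.decision == "exclude" for r in results),
            "decision_uncertain": n_uncertain,
            "imputed": sum(r.provenance == "imputed" for r in results),
        },
        "files": sorted(files),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
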