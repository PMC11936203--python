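"""End-to-end orchestration: config, stage running, artifact manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import variables as V
from .decomposition import aggregate_contributions, decompose
from .descriptives import descriptive_table
from .inequality import analyze, cix_by_group, fractional_rank
from .regression import average_marginal_effects, fit_weighted_logit
from .selection import all_subsets, best_subset_aic
from .survey import (
    CountryMeta,
    PooledDataset,
    filter_eligible,
    pool_surveys,
    read_survey_csv,
    write_pooled_csv,
)
from .synthetic import default_spec, simulate_outcome, simulate_women


@dataclasses.dataclass
class RunConfig:
    """One source of records (synthetic spec or input files) plus options."""

    out: Path
    seed: int | None = None
    synthetic: dict | None = None  # {"n_per_country": int, "target_prevalence": float}
    inputs: list[Path] | None = None  # per-country CSVs with a country column
    country_meta: dict[str, dict] | None = None  # country -> {total_population, sample_n}
    stratifiers: tuple[str, ...] = ("wealth", "education")
    stages: tuple[str, ...] = (
        "simulate", "describe", "select", "regress", "cix", "decompose"
    )
    variables: list[str] | None = None  # explicit model; else selection or default
    select_max_size: int | None = None  # best-subset width when "select" runs
    per_country: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be set")
        if self.synthetic is not None and self.seed is None:
            raise ValueError("seed required for a synthetic run")
        unknown = set(self.stratifiers) - set(V.STRATIFIERS)
        if unknown:
            raise ValueError(f"unknown stratifiers: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["out"] = Path(raw["out"])
        if raw.get("inputs"):
            raw["inputs"] = [Path(p) for p in raw["inputs"]]
        for key in ("stratifiers", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(event: str, **fields: Any) -> None:
    print(json.dumps({"event": event, **fields}), file=sys.stderr)


def _write_csv(frame: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
    return path


def _write_json(obj: Any, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def _load_records(config: RunConfig) -> PooledDataset:
    if config.synthetic is not None:
        opts = dict(config.synthetic)
        spec = default_spec(
            seed=int(config.seed),
            n_per_country=int(opts.get("n_per_country", 2500)),
            target_prevalence=opts.get("target_prevalence", 0.09),
        )
        survey = simulate_outcome(simulate_women(spec))
        frames = {
            c.country: survey.women[survey.women[V.COUNTRY] == c.country]
            .drop(columns=[V.COUNTRY])
            .reset_index(drop=True)
            for c in spec.countries
        }
        meta = {
            c.country: CountryMeta(c.country, c.total_population, c.n_women)
            for c in spec.countries
        }
        return pool_surveys(frames, meta)
    frames = {}
    for path in config.inputs:
        frame = read_survey_csv(path)
        for country, part in frame.groupby(V.COUNTRY):
            frames[str(country)] = part.drop(columns=[V.COUNTRY]).reset_index(
                drop=True
            )
    meta = {
        c: CountryMeta(
            c,
            int(config.country_meta[c]["total_population"]),
            config.country_meta[c].get("sample_n"),
        )
        for c in frames
    }
    return pool_surveys(frames, meta)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the artifact manifest."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name: str) -> bool:
        return name in config.stages

    t0 = time.perf_counter()
    try:
        pooled = _load_records(config)
    except Exception as exc:  # surface the failing stage
        raise RuntimeError(f"stage 'prepare' failed: {exc}") from exc
    records, exclusions = filter_eligible(pooled.records)
    timings["prepare"] = time.perf_counter() - t0
    _log("prepare", n=len(records), exclusions=exclusions)
    artifacts["pooled"] = write_pooled_csv(
        PooledDataset(records=records, meta=pooled.meta), out / "pooled.csv"
    )
    _write_json(
        {"exclusions": exclusions, "n_records": len(records)},
        out / "prepare_log.json",
    )
    artifacts["prepare_log"] = out / "prepare_log.json"

    available = [v for v in V.COVARIATES if v in records.columns]
    model_vars = list(config.variables) if config.variables else available

    if stage("describe"):
        t = time.perf_counter()
        try:
            table = descriptive_table(records)
            shares = (
                PooledDataset(records=records, meta=pooled.meta)
                .country_shares()
                .rename("weighted_pct")
                .reset_index()
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'describe' failed: {exc}") from exc
        artifacts["descriptives"] = _write_csv(table, out / "descriptives.csv")
        artifacts["country_shares"] = _write_csv(shares, out / "country_shares.csv")
        timings["describe"] = time.perf_counter() - t

    if stage("select") and config.select_max_size:
        t = time.perf_counter()
        try:
            candidates = all_subsets(model_vars, max_size=config.select_max_size)
            result = best_subset_aic(records, candidates)
        except Exception as exc:
            raise RuntimeError(f"stage 'select' failed: {exc}") from exc
        model_vars = list(result.selected)
        artifacts["selection"] = _write_json(result.to_dict(), out / "selection.json")
        timings["select"] = time.perf_counter() - t

    fit = effects = None
    if stage("regress") or stage("decompose"):
        t = time.perf_counter()
        try:
            fit = fit_weighted_logit(records, model_vars)
            effects = average_marginal_effects(fit)
        except Exception as exc:
            raise RuntimeError(f"stage 'regress' failed: {exc}") from exc
        if stage("regress"):
            artifacts["odds_ratios"] = _write_csv(
                fit.odds_ratios().rename_axis("term").reset_index(),
                out / "odds_ratios.csv",
            )
            _write_json(
                {
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "n_obs": fit.n_obs,
                    "weighted_n": fit.weighted_n,
                    "variables": model_vars,
                    "reference": fit.reference,
                    "coefficients": {k: float(v) for k, v in fit.params.items()},
                },
                out / "fit.json",
            )
            artifacts["fit"] = out / "fit.json"
        timings["regress"] = time.perf_counter() - t

    if stage("cix") or stage("decompose"):
        for strat_name in config.stratifiers:
            column = V.STRATIFIERS[strat_name]
            t = time.perf_counter()
            try:
                results = (
                    cix_by_group(records, column)
                    if config.per_country
                    else [
                        analyze(
                            records[column].to_numpy(),
                            records[V.OUTCOME].to_numpy(dtype=float),
                            records[V.WEIGHT_POOLED].to_numpy(dtype=float),
                            name=column,
                        )
                    ]
                )
            except Exception as exc:
                raise RuntimeError(f"stage 'cix' failed: {exc}") from exc
            if stage("cix"):
                summary = [
                    {
                        "stratifier": strat_name,
                        "group": r.group,
                        "cix": r.cix,
                        "se": r.se,
                        "p_value": r.p_value,
                        "p_value_text": r.p_value_text(),
                    }
                    for r in results
                ]
                artifacts[f"cix_{strat_name}"] = _write_json(
                    summary, out / f"cix_{strat_name}.json"
                )
                for r in results:
                    path = out / f"curve_{strat_name}_{r.group}.csv"
                    artifacts[f"curve_{strat_name}_{r.group}"] = _write_csv(
                        r.curve, path
                    )
            timings[f"cix_{strat_name}"] = time.perf_counter() - t

            if stage("decompose"):
                t = time.perf_counter()
                try:
                    ranked = fractional_rank(
                        records[column].to_numpy(),
                        records[V.WEIGHT_POOLED].to_numpy(dtype=float),
                        y=records[V.OUTCOME].to_numpy(dtype=float),
                        name=column,
                    )
                    table = decompose(effects, ranked, fit.design, stratifier=column)
                except Exception as exc:
                    raise RuntimeError(f"stage 'decompose' failed: {exc}") from exc
                artifacts[f"decomposition_{strat_name}"] = _write_csv(
                    render_decomposition(table), out / f"decomposition_{strat_name}.csv"
                )
                grouping = {
                    var: [
                        f"{var}={lab}" for lab in V.CATEGORIES[var][1:]
                        if f"{var}={lab}" in table.percentages()
                    ]
                    for var in model_vars
                }
                grouping = {k: v for k, v in grouping.items() if v}
                agg = aggregate_contributions(table, grouping, rounding="2dp")
                artifacts[f"aggregate_{strat_name}"] = _write_json(
                    agg, out / f"aggregate_{strat_name}.json"
                )
                timings[f"decompose_{strat_name}"] = time.perf_counter() - t

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "artifacts": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    _write_json(manifest, out / "manifest.json")
    _log("done", artifacts=len(artifacts))
    return manifest


def render_decomposition(table) -> pd.DataFrame:
    """Decomposition CSV in published column order, with reference rows."""
    frame = table.to_frame()
    rows = []
    for var in dict.fromkeys(frame["variable"]):
        ref_label = V.CATEGORIES[var][0] if var in V.CATEGORIES else "reference"
        rows.append(
            {
                "variable": var,
                "category": ref_label,
                "elasticity": None,
                "concentration_index": None,
                "absolute_contribution": None,
                "percentage_contribution": None,
                "note": "Reference",
            }
        )
        part = frame[frame["variable"] == var].copy()
        part["note"] = ""
        rows.extend(part.to_dict("records"))
    rows.append(
        {
            "variable": "residual",
            "category": "",
            "elasticity": None,
            "concentration_index": None,
            "absolute_contribution": table.residual,
            "percentage_contribution": table.residual_percentage,
            "note": "",
        }
    )
    return pd.DataFrame(rows)
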