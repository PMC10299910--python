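"""Config-driven orchestration: harmonize, fit, decompose, bootstrap, report.

One :func:`run` call reads (or simulates) the cohorts, fits the path model
separately for each requested outcome (the two outcome systems share the
harmonized table but are estimated and bootstrapped independently),
decomposes the five standard exposure -> outcome pathways, classifies the
mediation pattern of every mediator, executes the sensitivity plan
(leave-one-cohort-out, assessment-timing subsets), and writes CSV tables,
a JSON report, DOT diagrams and a plain-text log.  Given a fixed seed the
JSON report is byte-identical across runs (timestamps live only in the log).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import bootstrap as bs
from . import effects as fx
from .derivations import PooledTable, as_frame, pool_cohorts
from .exceptions import ValidationError
from .model import (BF, BMI, BW, GeneralizedPathModel, standard_pathways, to_dot)

#: named cohort-subset rules for the timing sensitivity analyses,
#: applied to per-cohort mean assessment ages
SUBSET_PRESETS = {
    "infancy_ge_1y": {"variable": "age_infancy", "op": ">=", "value": 1.0},
    "childhood_3_4y": {"variable": "age_child", "op": "<", "value": 4.5},
    "childhood_5y": {"variable": "age_child", "op": ">=", "value": 4.5},
}


def five_pathways(outcome: str) -> list:
    """The five decomposed exposure -> outcome pathways per outcome model."""
    return [(BMI, outcome), (BMI, "rwg"), (BMI, BF), (BW, outcome), (BF, outcome)]


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs; YAML-serializable."""

    # data source: either per-cohort CSVs ...
    inputs: list = field(default_factory=list)  # [{cohort_id, path, column_map}]
    # ... or the synthetic generator
    simulate: bool = False
    simulate_scale: float = 1.0
    simulate_mode: str = "flags"
    fixture: str | None = None  # YAML file overriding the packaged calibration

    outcomes: tuple = ("bmiz_child", "overweight")
    with_education: bool = False
    grouping: str = "single"
    seed: int = 0

    bootstrap: bool = True
    bootstrap_B: int = 1000
    ci_method: str = "bc"  # "bc" | "normal" | "both"
    stratified: bool = True
    ridge_fallback: bool = True

    leave_one_out: bool = False
    subsets: tuple = ()  # names from SUBSET_PRESETS or inline rule dicts

    outdir: str | None = None

    def validate(self) -> None:
        if not self.simulate and not self.inputs:
            raise ValidationError("config needs either input files or simulate: true")
        for item in self.inputs:
            if not Path(item["path"]).exists():
                raise ValidationError(f"input file not found: {item['path']}")
        if self.bootstrap and self.bootstrap_B < 100:
            raise ValidationError("bootstrap_B must be >= 100 when the bootstrap is enabled")
        if self.ci_method not in ("bc", "normal", "both"):
            raise ValidationError("ci_method must be 'bc', 'normal' or 'both'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.outcomes, list):
            cfg.outcomes = tuple(cfg.outcomes)
        if isinstance(cfg.subsets, list):
            cfg.subsets = tuple(cfg.subsets)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcomes"] = list(self.outcomes)
        d["subsets"] = list(self.subsets)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_data(config: RunConfig):
    from .simulate import GeneratorParams, default_params, generate_pooled

    if config.simulate:
        params = (GeneratorParams.from_yaml(Path(config.fixture).read_text())
                  if config.fixture else default_params())
        return generate_pooled(params, seed=config.seed, mode=config.simulate_mode,
                               scale=config.simulate_scale)
    tables = {item["cohort_id"]: pd.read_csv(item["path"]) for item in config.inputs}
    maps = {item["cohort_id"]: item.get("column_map", {}) for item in config.inputs}
    spec = standard_pathways(config.outcomes[0], config.with_education)
    return pool_cohorts(tables, spec, column_maps=maps)


def _decompose_outcome(data, outcome: str, config: RunConfig, log: list) -> dict:
    """Fit one outcome system, decompose its five pathways, bootstrap CIs."""
    spec = standard_pathways(outcome, config.with_education)
    model = GeneralizedPathModel(spec=spec).fit(data)
    pairs = five_pathways(outcome)
    decomps = {f"{e}->{o}": fx.decompose(model, e, o, grouping=config.grouping)
               for e, o in pairs}
    result = {
        "fit": {
            "n": model.n_, "loglik": model.loglik_, "aic": model.aic_,
            "bic": model.bic_, "n_params": model.n_params_,
            "equations": {
                node: {"params": eq.params.to_dict(), "se": eq.se.to_dict(),
                       "loglik": eq.loglik, "family": eq.family}
                for node, eq in model.equations_.items()
            },
        },
        "pathways": {},
    }
    summaries = {}
    if config.bootstrap:
        boot = bs.bootstrap_effects(
            data, spec, pairs=pairs, B=config.bootstrap_B, seed=config.seed,
            stratified=config.stratified, grouping=config.grouping,
            ridge_fallback=config.ridge_fallback)
        log.append(f"{outcome}: bootstrap B={boot.B}, failed={len(boot.failures)}, "
                   f"ridged={boot.n_ridged}")
        methods = ("bc", "normal") if config.ci_method == "both" else (config.ci_method,)
        for method in methods:
            summaries[method] = bs.summarize(boot, method=method)
    primary = summaries.get("bc")
    if primary is None:
        primary = summaries.get("normal")
    for key, decomp in decomps.items():
        entry = {
            "scale": decomp.scale, "grouping": decomp.grouping,
            "effects": decomp.effects(), "reported": decomp.reported(),
        }
        if primary is not None:
            sig = {}
            cis = {}
            for eff in decomp.effects():
                row = primary.loc[f"{key}:{eff}"]
                cis[eff] = [float(row["low"]), float(row["high"])]
                sig[eff] = bool(row["significant"])
            entry["ci"] = cis
            entry["significant"] = sig
            entry["ci_method"] = primary["method"].iloc[0]
            entry["classification"] = fx.classify_decomposition(decomp, sig)
            if "normal" in summaries and config.ci_method == "both":
                entry["ci_normal"] = {
                    eff: [float(summaries["normal"].loc[f"{key}:{eff}", "low"]),
                          float(summaries["normal"].loc[f"{key}:{eff}", "high"])]
                    for eff in decomp.effects()
                }
        else:
            entry["ci"] = None
            entry["classification"] = "point-estimate only"
        # conservation identity re-asserted at the reporting layer
        eff = entry["effects"]
        ies = sum(v for k, v in eff.items() if k.startswith("indirect_via_"))
        if decomp.additive:
            assert abs(eff["total"] - eff["direct"] - ies) < 1e-10
        result["pathways"][key] = entry
    result["dot"] = to_dot(model)
    return result


def select_cohorts(cohort_meta: pd.DataFrame, rule) -> list:
    """Cohort ids whose metadata satisfy a rule (name or inline dict)."""
    if isinstance(rule, str):
        try:
            rule = SUBSET_PRESETS[rule]
        except KeyError as exc:
            raise ValidationError(
                f"unknown subset rule {rule!r}; presets: {sorted(SUBSET_PRESETS)}") from exc
    col = cohort_meta[rule["variable"]]
    op = rule["op"]
    val = rule["value"]
    if op == ">=":
        mask = col >= val
    elif op == "<=":
        mask = col <= val
    elif op == ">":
        mask = col > val
    elif op == "<":
        mask = col < val
    else:
        raise ValidationError(f"unknown comparison {op!r}")
    return sorted(cohort_meta.index[mask].tolist())


def _signs(effects_map: dict) -> dict:
    return {k: int(np.sign(v)) for k, v in effects_map.items()}


def sensitivity_leave_one_out(data, config: RunConfig, pooled_result: dict,
                              log: list, min_effect: float = 0.05) -> dict:
    """Refit excluding one cohort at a time; flag sign/significance changes.

    Every sign change relative to the pooled run is recorded; the global
    ``all_same_direction`` verdict, however, only weighs effects whose pooled
    estimate is non-negligible (|estimate| >= ``min_effect`` on the
    estimation scale, matching the 2-decimal reporting resolution) or, when
    the bootstrap ran, significant in the pooled analysis — the sign of an
    effect indistinguishable from zero is sampling noise, not heterogeneity.
    """
    frame = as_frame(data)
    cohorts = sorted(frame["cohort_id"].unique())
    if len(cohorts) < 3:
        raise ValidationError("leave-one-cohort-out needs at least 3 cohorts")
    out = {"runs": {}, "all_same_direction": True}
    for cid in cohorts:
        sub = frame[frame["cohort_id"] != cid]
        run_entry = {}
        for outcome in config.outcomes:
            spec = standard_pathways(outcome, config.with_education)
            model = GeneralizedPathModel(spec=spec).fit(sub)
            discordant, discordant_material = [], []
            for e, o in five_pathways(outcome):
                decomp = fx.decompose(model, e, o, grouping=config.grouping)
                pooled_entry = pooled_result[outcome]["pathways"][f"{e}->{o}"]
                pooled = pooled_entry["effects"]
                pooled_sig = pooled_entry.get("significant") or {}
                for eff, val in decomp.effects().items():
                    if int(np.sign(val)) == int(np.sign(pooled[eff])):
                        continue
                    key = f"{e}->{o}:{eff}"
                    discordant.append(key)
                    material = (pooled_sig.get(eff, False)
                                or abs(pooled[eff]) >= min_effect)
                    if material:
                        discordant_material.append(key)
            run_entry[outcome] = {"n": model.n_, "sign_changes": discordant,
                                  "discordant": discordant_material}
            if discordant_material:
                out["all_same_direction"] = False
        out["runs"][cid] = run_entry
        log.append(f"leave-one-out: excluded {cid}")
    return out


def sensitivity_subset(data, rule, config: RunConfig, log: list) -> dict:
    """Re-run the decomposition on a cohort subset selected by a timing rule."""
    if isinstance(data, PooledTable) and data.cohort_meta is not None:
        meta = data.cohort_meta
    else:
        frame = as_frame(data)
        meta = pd.DataFrame({
            "age_infancy": frame.groupby("cohort_id")["age_infancy"].mean(),
            "age_child": frame.groupby("cohort_id")["age_child"].mean(),
        })
    selected = select_cohorts(meta, rule)
    if len(selected) < 2:
        raise ValidationError(f"subset rule {rule!r} selects fewer than 2 cohorts: {selected}")
    frame = as_frame(data)
    sub = frame[frame["cohort_id"].isin(selected)]
    log.append(f"subset {rule!r}: cohorts {selected}")
    out = {"cohorts": selected, "outcomes": {}}
    for outcome in config.outcomes:
        spec = standard_pathways(outcome, config.with_education)
        model = GeneralizedPathModel(spec=spec).fit(sub)
        out["outcomes"][outcome] = {
            f"{e}->{o}": fx.decompose(model, e, o, grouping=config.grouping).effects()
            for e, o in five_pathways(outcome)
        }
    return out


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report."""
    config.validate()
    t0 = time.time()
    log: list = []
    data = _load_data(config)
    frame = as_frame(data)
    log.append(f"data: {len(frame)} records, {frame['cohort_id'].nunique()} cohorts")

    report = {
        "provenance": {
            "package": "growthpaths", "version": __version__,
            "config_hash": config.digest(), "seed": config.seed,
            "config": config.to_dict(),
        },
        "n": int(len(frame)),
        "drop_report": data.drop_report if isinstance(data, PooledTable) else {},
        "outcomes": {},
        "sensitivity": {},
    }
    for outcome in config.outcomes:
        report["outcomes"][outcome] = _decompose_outcome(data, outcome, config, log)
    if config.leave_one_out:
        report["sensitivity"]["leave_one_out"] = sensitivity_leave_one_out(
            data, config, report["outcomes"], log)
    for rule in config.subsets:
        name = rule if isinstance(rule, str) else json.dumps(rule, sort_keys=True)
        report["sensitivity"][name] = sensitivity_subset(data, rule, config, log)
    log.append(f"total wall time {time.time() - t0:.1f}s")

    if config.outdir:
        _write_outputs(report, config, log)
    return report


def _write_outputs(report: dict, config: RunConfig, log: list) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, default=float) + "\n")
    for outcome, entry in report["outcomes"].items():
        (outdir / f"model_{outcome}.dot").write_text(entry["dot"] + "\n")
        rows = []
        for key, pw in entry["pathways"].items():
            for eff, val in pw["effects"].items():
                row = {"pathway": key, "effect": eff,
                       "estimate": round(val, 2),
                       "reported": round(pw["reported"][eff], 2)}
                if pw.get("ci"):
                    row["ci_low"] = round(pw["ci"][eff][0], 2)
                    row["ci_high"] = round(pw["ci"][eff][1], 2)
                    row["significant"] = pw["significant"][eff]
                rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / f"effects_{outcome}.csv", index=False)
    stamp = time.strftime("%Y-%m-%d %H:%M:%S")
    (outdir / "run.log").write_text(
        f"# run at {stamp}\n" + "\n".join(log) + "\n")
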