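"""Synthetic multi-cohort generator.

Emulates a pooled set of early-childhood cohorts so that every pipeline
stage is testable without any individual-level data (the cohorts this
package is designed for cannot be redistributed).  Sampling follows the
structural DAG in topological order:

    maternal BMI, covariates  ->  birth weight  ->  breastfeeding >= 6 mo
        ->  rapid weight gain  ->  BMI z-score and overweight status

Maternal BMI is a truncated normal per cohort (one cohort is an
overweight-only pregnancy trial, so its truncation floor sits at the
overweight bound); binary nodes are Bernoulli-logit draws whose per-cohort
intercepts are *calibrated* by root-finding so the simulated marginal
prevalences hit the cohort profiles; Gaussian nodes get intercepts matched
to the profile means.  The overweight flag is generated from its own
logistic equation (not by thresholding the generated BMI z-score), because
the two outcomes are modelled as separate systems downstream; a
threshold mode is available for realism experiments.

In ``growth-curves`` mode the generator additionally emits raw
weight-for-age z-score pairs and breastfeeding months that re-derive to
exactly the drawn flags, exercising the harmonization layer end to end.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .derivations import PooledTable
from .exceptions import ValidationError
from .model import BF, BMI, BMIZ, BW, OW, RWG

_GAUSSIAN_NODES = (BW, BMIZ)
_LOGIT_NODES = (BF, RWG, OW)
_NODE_ORDER = (BW, BF, RWG, BMIZ, OW)


@dataclass
class CohortProfile:
    """Marginal description of one cohort (sizes, moments, prevalences)."""

    cohort_id: str
    n: int
    intervention_prop: float
    maternal_age_mean: float
    maternal_age_sd: float
    maternal_bmi_mean: float
    maternal_bmi_sd: float
    bmi_floor: float
    male_prop: float
    age_infancy_mean: float
    age_infancy_sd: float
    age_child_mean: float
    age_child_sd: float
    birth_weight_mean: float
    bmiz_mean: float
    prev_bf_ge6: float
    prev_rwg: float
    prev_overweight: float
    observational: bool = False
    tertiary_education_prop: float | None = None

    def __post_init__(self):
        if self.n <= 0:
            raise ValidationError(f"cohort {self.cohort_id!r}: n must be positive")
        for name in ("intervention_prop", "male_prop", "prev_bf_ge6", "prev_rwg",
                     "prev_overweight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"cohort {self.cohort_id!r}: {name} outside [0, 1]")
        if self.maternal_bmi_sd <= 0 or self.maternal_age_sd <= 0:
            raise ValidationError(f"cohort {self.cohort_id!r}: BMI/age SDs must be positive")
        # assessment-age SDs may be zero (some cohorts assessed at one fixed age)
        if self.age_infancy_sd < 0 or self.age_child_sd < 0:
            raise ValidationError(f"cohort {self.cohort_id!r}: negative assessment-age SD")


@dataclass
class GeneratorParams:
    """Structural coefficients + cohort profiles driving the generator.

    ``edges`` map (parent, child) to a coefficient on the estimation scale
    (linear for Gaussian children, log-odds for logit children); every edge
    of the default path specification (both outcomes) must be present.
    """

    edges: dict
    covariate_effects: dict
    noise_sd: dict
    profiles: list = field(default_factory=list)

    def __post_init__(self):
        for node in _GAUSSIAN_NODES:
            if self.noise_sd.get(node, 0.0) <= 0.0:
                raise ValidationError(f"noise SD for {node!r} must be positive")
        required = {
            (BMI, BW), (BMI, BF), (BMI, RWG), (BMI, BMIZ), (BMI, OW),
            (BW, BF), (BW, RWG), (BW, BMIZ), (BW, OW),
            (BF, RWG), (BF, BMIZ), (BF, OW),
            (RWG, BMIZ), (RWG, OW),
        }
        missing = required - set(self.edges)
        if missing:
            raise ValidationError(f"generator is missing edge coefficient(s): {sorted(missing)}")

    @property
    def total_n(self) -> int:
        return sum(p.n for p in self.profiles)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        edges = {}
        for e in d["edges"]:
            val = float(e["value"])
            if e.get("scale", "beta") == "or":
                val = float(np.log(val))
            edges[(e["parent"], e["child"])] = val
        profiles = []
        for c in d.get("cohorts", []):
            profiles.append(CohortProfile(
                cohort_id=c["cohort_id"], n=int(c["n"]),
                observational=bool(c.get("observational", False)),
                intervention_prop=float(c["intervention_prop"]),
                maternal_age_mean=float(c["maternal_age"]["mean"]),
                maternal_age_sd=float(c["maternal_age"]["sd"]),
                maternal_bmi_mean=float(c["maternal_bmi"]["mean"]),
                maternal_bmi_sd=float(c["maternal_bmi"]["sd"]),
                bmi_floor=float(c["maternal_bmi"].get("floor", 15.0)),
                tertiary_education_prop=(
                    None if c.get("tertiary_education_prop") is None
                    else float(c["tertiary_education_prop"])),
                male_prop=float(c["male_prop"]),
                age_infancy_mean=float(c["age_infancy"]["mean"]),
                age_infancy_sd=float(c["age_infancy"]["sd"]),
                age_child_mean=float(c["age_child"]["mean"]),
                age_child_sd=float(c["age_child"]["sd"]),
                birth_weight_mean=float(c["birth_weight_mean"]),
                bmiz_mean=float(c["bmiz_mean"]),
                prev_bf_ge6=float(c["prevalence"]["bf_ge6"]),
                prev_rwg=float(c["prevalence"]["rwg"]),
                prev_overweight=float(c["prevalence"]["overweight"]),
            ))
        return cls(
            edges=edges,
            covariate_effects={k: dict(v) for k, v in d.get("covariate_effects", {}).items()},
            noise_sd=dict(d["noise_sd"]),
            profiles=profiles,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorParams":
        return cls.from_dict(yaml.safe_load(text))

    def with_edges(self, **overrides) -> "GeneratorParams":
        """Copy with edge coefficients replaced, keys as 'parent->child'."""
        edges = dict(self.edges)
        for key, val in overrides.items():
            parent, child = key.split("->")
            edges[(parent, child)] = float(val)
        return GeneratorParams(edges=edges, covariate_effects=self.covariate_effects,
                               noise_sd=self.noise_sd, profiles=self.profiles)

    def null_edges(self) -> "GeneratorParams":
        """Copy with every structural edge zeroed (null generator)."""
        return GeneratorParams(edges={k: 0.0 for k in self.edges},
                               covariate_effects=self.covariate_effects,
                               noise_sd=self.noise_sd, profiles=self.profiles)


def default_params() -> GeneratorParams:
    """Calibration shipped with the package: seven cohorts, total n = 3572.

    Edge coefficients are the pooled point estimates of the reference
    seven-cohort analysis; cohort profiles are its descriptive marginals.
    Stored as a version-controlled data file, not hard-coded.
    """
    text = (importlib.resources.files("growthpaths") / "data" / "default_fixture.yaml").read_text()
    return GeneratorParams.from_yaml(text)


def calibrate_intercept(target_prevalence: float, eta: np.ndarray, tol: float = 1e-6) -> float:
    """Intercept c with mean(expit(c + eta)) = target, by monotone root-finding."""
    eta = np.asarray(eta, dtype=float)
    if not 0.0 < target_prevalence < 1.0:
        raise ValidationError("target prevalence must lie strictly inside (0, 1)")
    if eta.size == 0 or not np.isfinite(eta).all():
        raise ValidationError("linear-predictor sample must be finite and non-empty")

    def f(c):
        return float(expit(c + eta).mean() - target_prevalence)

    lo, hi = -40.0, 40.0
    c = brentq(f, lo, hi, xtol=1e-12)
    if abs(f(c)) > tol:
        raise ValidationError("target prevalence unreachable on this linear-predictor sample")
    return float(c)


def _eta(child: str, params: GeneratorParams, values: dict, n: int) -> np.ndarray:
    out = np.zeros(n)
    for (parent, c), coef in params.edges.items():
        if c == child and coef != 0.0:
            out = out + coef * values[parent]
    for cov, coef in params.covariate_effects.get(child, {}).items():
        if coef != 0.0:
            out = out + coef * values[cov]
    return out


def generate_pooled(params: GeneratorParams, seed: int, mode: str = "flags",
                    scale: float = 1.0, missing_rate: float = 0.0,
                    overweight_from_bmiz: bool = False) -> PooledTable:
    """Draw one pooled synthetic dataset.

    Parameters
    ----------
    seed
        Master seed; identical seeds give identical tables.
    mode
        ``"flags"`` emits the derived analysis flags only; ``"growth-curves"``
        additionally emits weight-for-age z-score pairs and breastfeeding
        months consistent with the drawn flags.
    scale
        Multiplies every cohort size (floored at 2), for reduced experiments.
    missing_rate
        Optional MCAR missingness injected into the analysis columns, to
        exercise the complete-case filter.
    overweight_from_bmiz
        Generate the overweight flag by thresholding the generated BMI
        z-score at the cohort-calibrated quantile instead of from its own
        logistic equation (realism mode; not the default).
    """
    if mode not in ("flags", "growth-curves"):
        raise ValidationError(f"unknown mode {mode!r}")
    if not params.profiles:
        raise ValidationError("generator has no cohort profiles")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parts = []
    for prof in params.profiles:
        n = max(int(round(prof.n * scale)), 2)
        v: dict = {}
        a = (prof.bmi_floor - prof.maternal_bmi_mean) / prof.maternal_bmi_sd
        v[BMI] = truncnorm.rvs(a, np.inf, loc=prof.maternal_bmi_mean,
                               scale=prof.maternal_bmi_sd, size=n, random_state=rng)
        v["maternal_age"] = rng.normal(prof.maternal_age_mean, prof.maternal_age_sd, n)
        v["sex"] = rng.binomial(1, prof.male_prop, n).astype(float)
        v["intervention"] = (np.zeros(n) if prof.observational
                             else rng.binomial(1, prof.intervention_prop, n).astype(float))
        if prof.tertiary_education_prop is None:
            v["maternal_education"] = np.full(n, np.nan)
        else:
            v["maternal_education"] = rng.binomial(1, prof.tertiary_education_prop, n).astype(float)
        v["age_infancy"] = rng.normal(prof.age_infancy_mean, prof.age_infancy_sd, n)
        v["age_child"] = rng.normal(prof.age_child_mean, prof.age_child_sd, n)

        eta_bw = _eta(BW, params, v, n)
        v[BW] = (prof.birth_weight_mean - eta_bw.mean()) + eta_bw + rng.normal(
            0.0, params.noise_sd[BW], n)

        eta_bf = _eta(BF, params, v, n)
        v[BF] = rng.binomial(1, expit(calibrate_intercept(prof.prev_bf_ge6, eta_bf) + eta_bf)
                             ).astype(float)

        eta_rwg = _eta(RWG, params, v, n)
        v[RWG] = rng.binomial(1, expit(calibrate_intercept(prof.prev_rwg, eta_rwg) + eta_rwg)
                              ).astype(float)

        eta_bz = _eta(BMIZ, params, v, n)
        v[BMIZ] = (prof.bmiz_mean - eta_bz.mean()) + eta_bz + rng.normal(
            0.0, params.noise_sd[BMIZ], n)

        if overweight_from_bmiz:
            cut = np.quantile(v[BMIZ], 1.0 - prof.prev_overweight)
            v[OW] = (v[BMIZ] >= cut).astype(float)
        else:
            eta_ow = _eta(OW, params, v, n)
            v[OW] = rng.binomial(1, expit(calibrate_intercept(prof.prev_overweight, eta_ow)
                                          + eta_ow)).astype(float)

        if mode == "growth-curves":
            v["waz_birth"] = rng.normal(0.0, 1.0, n)
            jump = np.abs(rng.normal(0.0, 0.4, n)) + 1e-6
            delta = np.where(v[RWG] == 1.0, 0.67 + jump, 0.67 - jump)
            v["waz_infancy"] = v["waz_birth"] + delta
            v["bf_months"] = np.where(v[BF] == 1.0,
                                      6.0 + rng.exponential(4.0, n),
                                      rng.uniform(0.0, 6.0, n))

        frame = pd.DataFrame(v)
        frame.insert(0, "cohort_id", prof.cohort_id)
        parts.append(frame)
    pooled = pd.concat(parts, ignore_index=True)

    if missing_rate > 0.0:
        cols = [BW, BF, RWG, BMIZ, OW, "maternal_bmi", "maternal_age"]
        mask = rng.random((len(pooled), len(cols))) < missing_rate
        for j, col in enumerate(cols):
            pooled.loc[mask[:, j], col] = np.nan

    meta = pd.DataFrame({
        "n": pooled.groupby("cohort_id", sort=False).size(),
        "age_infancy": pooled.groupby("cohort_id", sort=False)["age_infancy"].mean(),
        "age_child": pooled.groupby("cohort_id", sort=False)["age_child"].mean(),
    })
    return PooledTable(data=pooled, schema=tuple(pooled.columns),
                       drop_report={}, cohort_meta=meta)
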