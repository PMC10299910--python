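"""Nonparametric bootstrap of the fit-and-decompose pipeline.

Resampling draws individual records with replacement, stratified by cohort by
default so every replicate preserves the per-cohort sizes the cohort fixed
effects condition on (an unstratified mode exists behind a flag).  Each
replicate re-runs the whole estimation — resample, refit every needed
structural equation, re-decompose — and stores every direct/indirect/total
effect on the estimation scale.  Intervals: bias-corrected percentile
(primary) and normal-approximation, both computed from the same replicate
matrix.  Randomness comes from one master seed whose per-replicate streams
are derived by a counter-based spawn, so results do not depend on execution
order or chunking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import effects as fx
from . import glm
from .derivations import PooledTable, as_frame
from .exceptions import ValidationError
from .model import GeneralizedPathModel, PathSpec


def resample(data, rng, stratified: bool = True):
    """One bootstrap replicate of the pooled table (rows with replacement).

    With ``stratified=True`` each cohort is resampled to its own size.
    Returns the same container type it was given.
    """
    frame = as_frame(data)
    if len(frame) == 0:
        raise ValidationError("cannot resample an empty table")
    idx = _resample_indices(frame, rng, stratified)
    out = frame.iloc[idx].reset_index(drop=True)
    if isinstance(data, PooledTable):
        return PooledTable(data=out, schema=data.schema, drop_report={},
                          cohort_meta=data.cohort_meta)
    return out


def _resample_indices(frame: pd.DataFrame, rng, stratified: bool) -> np.ndarray:
    n = len(frame)
    if not stratified or "cohort_id" not in frame.columns:
        return rng.integers(0, n, n)
    parts = []
    for _, idx in frame.groupby("cohort_id", sort=True).indices.items():
        if len(idx) == 0:
            raise ValidationError("empty cohort stratum")
        parts.append(idx[rng.integers(0, len(idx), len(idx))])
    return np.concatenate(parts)


class _ReplicateFit:
    """Minimal stand-in for a fitted path model inside the bootstrap loop."""

    __slots__ = ("spec_", "_params")

    def __init__(self, spec: PathSpec, params: dict):
        self.spec_ = spec
        self._params = params

    def edge_coef(self, parent: str, child: str) -> float:
        try:
            return float(self._params[child][parent])
        except KeyError as exc:
            raise ValidationError(f"no fitted coefficient for edge {parent!r} -> {child!r}") from exc


@dataclass
class BootstrapResult:
    """Replicate matrix plus full-sample point estimates, estimation scale."""

    estimates: dict            # key -> point estimate
    scales: dict               # key -> "linear" | "log-odds"
    replicates: dict           # key -> ndarray of length b_effective
    B: int
    seed: int
    stratified: bool
    grouping: str
    failures: list = field(default_factory=list)
    n_ridged: int = 0

    @property
    def b_effective(self) -> int:
        return self.B - len(self.failures)

    def keys(self):
        return list(self.estimates)


def effect_keys(exposure: str, outcome: str, decomp: fx.EffectDecomposition) -> dict:
    return {f"{exposure}->{outcome}:{k}": v for k, v in decomp.effects().items()}


def bootstrap_effects(data, spec: PathSpec, pairs=None, B: int = 1000, seed: int = 0,
                      stratified: bool = True, grouping: str = "single",
                      ridge_fallback: bool = False, max_failure_frac: float = 0.10,
                      ) -> BootstrapResult:
    """Bootstrap every DE/IE/TE of the requested exposure -> outcome pairs.

    Refits only the equations that feed the requested effects (the others
    cannot change them); replicate failures (separation, rank loss) are
    skipped and counted, with an optional one-shot ridge retry per replicate
    when ``ridge_fallback`` is set.  Aborts if more than ``max_failure_frac``
    of replicates fail.
    """
    model = GeneralizedPathModel(spec=spec).fit(data)
    pairs = list(pairs) if pairs is not None else [(spec.exposure, spec.outcome)]

    estimates: dict = {}
    scales: dict = {}
    for exposure, outcome in pairs:
        decomp = fx.decompose(model, exposure, outcome, grouping=grouping)
        for key, val in effect_keys(exposure, outcome, decomp).items():
            estimates[key] = val
            scales[key] = decomp.scale

    needed: set = set()
    for exposure, outcome in pairs:
        for path in fx.enumerate_paths(spec, exposure, outcome):
            needed.update(path.nodes[1:])
    needed_order = [n for n in spec.endogenous() if n in needed]

    designs = model.designs_
    frame = model.frame_
    reps: dict = {k: [] for k in estimates}
    failures: list = []
    n_ridged = 0
    streams = np.random.SeedSequence(seed).spawn(B)
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        idx = _resample_indices(frame, rng, stratified)
        fitted = None
        for ridge in ((0.0, 1e-4) if ridge_fallback else (0.0,)):
            try:
                params = {}
                for node in needed_order:
                    d = designs[node]
                    sub = glm.DesignMatrix(d.y[idx], d.X[idx], d.columns, d.family)
                    kwargs = {"check_rank": False}
                    if d.family == glm.LOGIT:
                        kwargs["ridge"] = ridge
                    params[node] = glm.fit_equation(sub, name=node, **kwargs).params
                fitted = _ReplicateFit(spec, params)
                if ridge > 0.0:
                    n_ridged += 1
                break
            except (ValidationError, glm.SeparationError, glm.ConvergenceError,
                    np.linalg.LinAlgError) as exc:
                last_exc = exc
        if fitted is None:
            failures.append(f"replicate {b}: {last_exc}")
            continue
        for exposure, outcome in pairs:
            decomp = fx.decompose(fitted, exposure, outcome, grouping=grouping)
            for key, val in effect_keys(exposure, outcome, decomp).items():
                reps[key].append(val)
    if len(failures) > max_failure_frac * B:
        raise RuntimeError(
            f"{len(failures)}/{B} bootstrap replicates failed (> {max_failure_frac:.0%}); "
            f"first failure: {failures[0]}"
        )
    return BootstrapResult(
        estimates=estimates, scales=scales,
        replicates={k: np.asarray(v, dtype=float) for k, v in reps.items()},
        B=B, seed=seed, stratified=stratified, grouping=grouping,
        failures=failures, n_ridged=n_ridged,
    )


def bc_ci(replicates, point_estimate: float, level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected percentile interval.

    The bias-correction constant is z0 = ndtri(share of replicates below the
    point estimate), with ties at the point estimate counted as half below;
    interval bounds sit at the ndtr(2*z0 +/- z_alpha) percentiles of the
    replicate distribution, by linear interpolation of order statistics at
    the k/(B+1) plotting positions — the standard convention for
    bootstrap percentile-type intervals, which keeps the tails honest at
    moderate B.  No jackknife acceleration is applied.
    """
    reps = np.asarray(replicates, dtype=float)
    b = reps.size
    if b < 100:
        raise ValidationError(f"bias-corrected interval needs >= 100 replicates, got {b}")
    if np.ptp(reps) == 0.0:
        warnings.warn("all bootstrap replicates identical; degenerate interval", stacklevel=2)
        return float(reps[0]), float(reps[0])
    prop = (np.sum(reps < point_estimate) + 0.5 * np.sum(reps == point_estimate)) / b
    prop = min(max(prop, 0.5 / b), 1.0 - 0.5 / b)
    z0 = ndtri(prop)
    za = ndtri(0.5 + level / 2.0)
    lo_p, hi_p = ndtr(2.0 * z0 - za), ndtr(2.0 * z0 + za)
    lo, hi = np.quantile(reps, [lo_p, hi_p], method="weibull")
    return float(lo), float(hi)


def normal_ci(replicates, point_estimate: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation interval: point +/- z * SD(replicates)."""
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValidationError("normal interval needs >= 2 replicates")
    sd = float(np.std(reps, ddof=1))
    za = ndtri(0.5 + level / 2.0)
    return point_estimate - za * sd, point_estimate + za * sd


def significance(ci: tuple[float, float]) -> bool:
    """True iff the estimation-scale interval excludes zero (boundary counts as inclusion)."""
    low, high = ci
    return bool(low > 0.0 or high < 0.0)


def summarize(result: BootstrapResult, method: str = "bc", level: float = 0.95) -> pd.DataFrame:
    """CI table for every bootstrapped effect.

    OR-scale columns (exp of the estimation-scale values) are filled for
    log-odds effects; significance is always judged on the estimation scale,
    equivalent to the OR interval excluding one.
    """
    if method not in ("bc", "normal"):
        raise ValidationError("method must be 'bc' or 'normal'")
    fn = bc_ci if method == "bc" else normal_ci
    rows = []
    for key in result.keys():
        est = result.estimates[key]
        lo, hi = fn(result.replicates[key], est, level=level)
        row = {
            "effect": key, "estimate": est, "low": lo, "high": hi,
            "significant": significance((lo, hi)), "scale": result.scales[key],
            "method": method,
        }
        if result.scales[key] == "log-odds":
            row["or"], row["or_low"], row["or_high"] = np.exp([est, lo, hi])
        rows.append(row)
    return pd.DataFrame(rows).set_index("effect")
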