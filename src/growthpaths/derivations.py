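"""Analysis-variable derivation and multi-cohort harmonization.

Cohort files arrive with heterogeneous column names and varying levels of
pre-processing: some ship a precomputed rapid-weight-gain (RWG) flag, others
only the weight-for-age z-scores it is derived from; some record breastfeeding
duration in months, others only the >= 6-month indicator.  This module maps
everything onto one canonical schema, derives the categorical analysis
variables, and pools cohorts into a single complete-case table.

Boundary conventions (documented, overridable via the ``threshold`` keywords):

* RWG is a *strict* inequality: z-score change > 0.67 (one centile band).
* Breastfeeding >= 6 months is *inclusive* at 6.0 months.
* The overweight flag is *inclusive* at the age/sex BMI cutpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

RWG_THRESHOLD = 0.67
BF_THRESHOLD_MONTHS = 6.0


def _as_float_array(x, name: str):
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    return np.atleast_1d(arr), scalar


def _maybe_scalar(out: np.ndarray, scalar: bool):
    return out.item() if scalar else out


def flag_rwg(waz_birth, waz_infancy, threshold: float = RWG_THRESHOLD):
    """Flag rapid weight gain: weight-for-age z change from birth > ``threshold``.

    Strict inequality; a change of exactly 0.67 is *not* rapid weight gain.
    Accepts scalars or arrays; raises :class:`ValidationError` on non-finite
    input, naming the offending record positions.
    """
    wb, s1 = _as_float_array(waz_birth, "waz_birth")
    wi, s2 = _as_float_array(waz_infancy, "waz_infancy")
    bad = ~(np.isfinite(wb) & np.isfinite(wi))
    if bad.any():
        where = np.flatnonzero(bad)[:10].tolist()
        raise ValidationError(
            f"non-finite weight-for-age z-score at record position(s) {where}"
        )
    out = ((wi - wb) > threshold).astype(int)
    return _maybe_scalar(out, s1 and s2)


def dichotomize_breastfeeding(bf_months, threshold: float = BF_THRESHOLD_MONTHS):
    """1 iff any-breastfeeding duration >= ``threshold`` months (inclusive)."""
    bf, scalar = _as_float_array(bf_months, "bf_months")
    bad = ~np.isfinite(bf) | (bf < 0)
    if bad.any():
        where = np.flatnonzero(bad)[:10].tolist()
        raise ValidationError(
            f"negative or non-finite breastfeeding duration at record position(s) {where}"
        )
    out = (bf >= threshold).astype(int)
    return _maybe_scalar(out, scalar)


def flag_overweight(bmi, age, sex, cutoff_table) -> np.ndarray | int:
    """Flag overweight against a caller-supplied age/sex BMI cutpoint table.

    ``cutoff_table`` must have columns ``age_years``, ``sex``, ``bmi_cutpoint``
    (e.g. the IOTF child cutpoints, which are licensed content and therefore
    never shipped with this package — tests use a synthetic toy table).  The
    cutpoint is linearly interpolated in age between tabulated rows, and the
    flag is inclusive at the cutpoint.
    """
    tab = pd.DataFrame(cutoff_table)
    for col in ("age_years", "sex", "bmi_cutpoint"):
        if col not in tab.columns:
            raise SchemaError(f"cutoff table lacks required column {col!r}")
    b, s1 = _as_float_array(bmi, "bmi")
    a, s2 = _as_float_array(age, "age")
    sexes = np.atleast_1d(np.asarray(sex))
    if sexes.shape != a.shape:
        sexes = np.broadcast_to(sexes, a.shape)
    out = np.empty(a.shape, dtype=int)
    for sval in np.unique(sexes):
        rows = tab[tab["sex"] == sval].sort_values("age_years")
        if rows.empty:
            raise ValidationError(f"no cutoff rows for sex {sval!r}")
        mask = sexes == sval
        lo, hi = rows["age_years"].iloc[0], rows["age_years"].iloc[-1]
        if (a[mask] < lo).any() or (a[mask] > hi).any():
            raise ValidationError(
                f"age outside cutoff table range [{lo}, {hi}] for sex {sval!r}"
            )
        cut = np.interp(a[mask], rows["age_years"].to_numpy(), rows["bmi_cutpoint"].to_numpy())
        out[mask] = (b[mask] >= cut).astype(int)
    return _maybe_scalar(out, s1 and s2)


@dataclass
class PooledTable:
    """Harmonized individual-level records pooled across cohorts.

    ``data`` is the complete-case analysis table; ``schema`` the canonical
    columns the active path specification requires; ``drop_report`` accounts
    for every excluded row; ``cohort_meta`` summarizes per-cohort size and
    assessment ages (used by the timing-subset sensitivity analyses).
    """

    data: pd.DataFrame
    schema: tuple[str, ...] = ()
    drop_report: dict = field(default_factory=dict)
    cohort_meta: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.data)


def as_frame(obj) -> pd.DataFrame:
    """Accept a :class:`PooledTable` or a plain DataFrame."""
    return obj.data if isinstance(obj, PooledTable) else pd.DataFrame(obj)


def derive_analysis_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Fill in ``rwg`` / ``bf_ge6`` from raw columns where possible.

    When both the raw columns and the derived flag are present, the flag is
    checked against re-derivation and a mismatch raises — silent disagreement
    between a shipped flag and its defining rule would corrupt pooled coding.
    """
    out = frame.copy()
    if {"waz_birth", "waz_infancy"}.issubset(out.columns):
        complete = out["waz_birth"].notna() & out["waz_infancy"].notna()
        if complete.any():
            derived = flag_rwg(
                out.loc[complete, "waz_birth"].to_numpy(),
                out.loc[complete, "waz_infancy"].to_numpy(),
            )
            if "rwg" in out.columns and out.loc[complete, "rwg"].notna().any():
                have = out.loc[complete, "rwg"].notna()
                ok = out.loc[complete, "rwg"].to_numpy()[have.to_numpy()] == derived[have.to_numpy()]
                if not np.all(ok):
                    raise ValidationError(
                        "rwg flag disagrees with re-derivation from weight-for-age z-scores"
                    )
            col = out["rwg"].copy() if "rwg" in out.columns else pd.Series(np.nan, index=out.index)
            col.loc[complete] = derived
            out["rwg"] = col
    if "bf_months" in out.columns:
        complete = out["bf_months"].notna()
        if complete.any():
            derived = dichotomize_breastfeeding(out.loc[complete, "bf_months"].to_numpy())
            if "bf_ge6" in out.columns and out.loc[complete, "bf_ge6"].notna().any():
                have = out.loc[complete, "bf_ge6"].notna()
                ok = out.loc[complete, "bf_ge6"].to_numpy()[have.to_numpy()] == derived[have.to_numpy()]
                if not np.all(ok):
                    raise ValidationError(
                        "bf_ge6 flag disagrees with re-derivation from bf_months"
                    )
            col = out["bf_ge6"].copy() if "bf_ge6" in out.columns else pd.Series(np.nan, index=out.index)
            col.loc[complete] = derived
            out["bf_ge6"] = col
    return out


_DERIVABLE = {
    "rwg": ("waz_birth", "waz_infancy"),
    "bf_ge6": ("bf_months",),
}


def pool_cohorts(
    tables: Mapping[str, pd.DataFrame],
    spec,
    column_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> PooledTable:
    """Harmonize and concatenate per-cohort tables, complete-case on ``spec``.

    Parameters
    ----------
    tables
        Mapping cohort_id -> raw table.
    spec
        A :class:`~growthpaths.model.PathSpec`; its ``variables()`` define the
        complete-case set.
    column_maps
        Optional per-cohort ``{source_name: canonical_name}`` renames.
    """
    column_maps = column_maps or {}
    required = [v for v in spec.variables() if v != "cohort_id"]
    parts: list[pd.DataFrame] = []
    per_cohort: dict[str, int] = {}
    per_variable: dict[str, int] = {v: 0 for v in required}
    rows_in = 0
    for cid, raw in tables.items():
        frame = pd.DataFrame(raw).rename(columns=dict(column_maps.get(cid, {})))
        frame = derive_analysis_columns(frame)
        for col in required:
            if col not in frame.columns:
                need = _DERIVABLE.get(col)
                raise SchemaError(
                    f"cohort {cid!r}: required column {col!r} missing"
                    + (f" (and raw column(s) {need} absent)" if need else "")
                )
        frame = frame.copy()
        frame["cohort_id"] = cid
        rows_in += len(frame)
        keep = frame[required].notna().all(axis=1)
        for col in required:
            per_variable[col] += int(frame[col].isna().sum())
        per_cohort[cid] = int((~keep).sum())
        parts.append(frame.loc[keep])
    pooled = pd.concat(parts, ignore_index=True)
    meta_cols = {"n": pooled.groupby("cohort_id").size()}
    for col in ("age_infancy", "age_child"):
        if col in pooled.columns:
            meta_cols[col] = pooled.groupby("cohort_id")[col].mean()
    meta = pd.DataFrame(meta_cols)
    report = {
        "per_cohort": per_cohort,
        "per_variable": per_variable,
        "rows_in": rows_in,
        "rows_out": len(pooled),
        "dropped": rows_in - len(pooled),
    }
    return PooledTable(
        data=pooled,
        schema=tuple(required) + ("cohort_id",),
        drop_report=report,
        cohort_meta=meta,
    )
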