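"""Effect decomposition by the product of coefficients.

Direct, indirect and total effects are computed on the linear-predictor
("estimation") scale: linear coefficients for Gaussian nodes, log-odds for
logit nodes.  An indirect effect is a product of edge coefficients along a
mediated path; cross-scale products (e.g. a log-odds coefficient into a
binary mediator times the mediator's linear coefficient on a continuous
outcome) are taken as-is, reproducing derived-coefficient computation on the
fitted parameters.  For binary mediators such products are approximations to
counterfactual mediation effects (rare-outcome caveat) — they mirror the
product-method estimand, not a counterfactual estimator.

Three "via M" grouping conventions are offered:

* ``"single"`` (default) — the two-edge product exposure -> M -> outcome for
  every mediator M adjacent to both ends.  The total effect is defined as
  DE + sum of these products.  This is the convention under which the
  reference decomposition tables are internally consistent.
* ``"first"`` — all simple paths partitioned by their first mediator; the
  total equals the full sum over simple paths (and, in an all-linear DAG,
  the covariance-algebra total from (I - B)^-1).
* ``"containing"`` — every path containing M contributes to M's group; the
  groups overlap, so they do not sum to TE - DE (``additive`` is False).

On every decomposition TE = DE + sum(IE) holds to machine precision for the
additive conventions; this conservation identity is asserted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

GROUPINGS = ("single", "first", "containing")


@dataclass(frozen=True)
class DirectedPath:
    """A simple directed path exposure -> ... -> outcome."""

    nodes: tuple

    @property
    def first_mediator(self) -> str:
        return "direct" if len(self.nodes) == 2 else self.nodes[1]

    @property
    def mediators(self) -> tuple:
        return self.nodes[1:-1]


def enumerate_paths(spec, exposure: str, outcome: str) -> list:
    """All simple directed paths, depth-first in lexicographic child order."""
    if exposure not in spec.families or outcome not in spec.families:
        raise ValidationError(f"{exposure!r} or {outcome!r} is not a node of the specification")
    if exposure == outcome:
        raise ValidationError("exposure and outcome must differ")
    children: dict = {}
    for p, c in spec.edges:
        children.setdefault(p, []).append(c)
    for p in children:
        children[p] = sorted(children[p])
    out: list = []

    def dfs(node, trail):
        if node == outcome:
            out.append(DirectedPath(tuple(trail)))
            return
        for nxt in children.get(node, ()):  # lexicographic => deterministic
            if nxt not in trail:
                dfs(nxt, trail + [nxt])

    dfs(exposure, [exposure])
    if not out:
        warnings.warn(f"outcome {outcome!r} unreachable from {exposure!r}", stacklevel=2)
    return out


def path_product(fit, path) -> float:
    """Product of the path's edge coefficients on the estimation scale."""
    nodes = path.nodes if isinstance(path, DirectedPath) else tuple(path)
    prod = 1.0
    for parent, child in zip(nodes[:-1], nodes[1:]):
        prod *= fit.edge_coef(parent, child)
    return prod


@dataclass
class EffectDecomposition:
    """Direct/indirect/total effects for one exposure -> outcome pathway.

    All stored values live on the estimation scale; :meth:`reported` applies
    ``exp`` for log-odds outcomes so they read as odds ratios.
    """

    exposure: str
    outcome: str
    scale: str  # "linear" | "log-odds"
    grouping: str
    direct: float
    indirect: dict
    total: float
    additive: bool = True
    n_paths: int = 0
    cis: dict | None = None
    significant: dict | None = None
    classification: dict | None = None

    def effects(self) -> dict:
        out = {"total": self.total, "direct": self.direct}
        for m, v in self.indirect.items():
            out[f"indirect_via_{m}"] = v
        return out

    def reported(self) -> dict:
        """Effects on the reporting scale (odds ratios for logit outcomes)."""
        if self.scale == "linear":
            return self.effects()
        return {k: math.exp(v) for k, v in self.effects().items()}

    def as_frame(self) -> pd.DataFrame:
        eff = self.effects()
        rep = self.reported()
        rows = []
        for key in eff:
            row = {"effect": key, "estimate": eff[key], "reported": rep[key]}
            if self.cis and key in self.cis:
                row["ci_low"], row["ci_high"] = self.cis[key]
            if self.significant and key in self.significant:
                row["significant"] = self.significant[key]
            rows.append(row)
        return pd.DataFrame(rows).set_index("effect")


def decompose(fit, exposure: str | None = None, outcome: str | None = None,
              grouping: str = "single") -> EffectDecomposition:
    """Product-method decomposition of an exposure -> outcome pathway.

    ``fit`` is a fitted :class:`~growthpaths.model.GeneralizedPathModel` (or
    any object exposing ``spec_`` and ``edge_coef``).
    """
    if grouping not in GROUPINGS:
        raise ValidationError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    spec = fit.spec_
    exposure = exposure or spec.exposure
    outcome = outcome or spec.outcome
    order = spec.topological_order()
    if exposure in order and outcome in order:
        if order.index(exposure) > order.index(outcome):
            raise ValidationError(f"{exposure!r} does not precede {outcome!r} in the DAG")
    paths = enumerate_paths(spec, exposure, outcome)
    edge_set = set(spec.edges)
    direct = fit.edge_coef(exposure, outcome) if (exposure, outcome) in edge_set else 0.0

    indirect: dict = {}
    if grouping == "single":
        for m in order:
            if (exposure, m) in edge_set and (m, outcome) in edge_set and m not in (exposure, outcome):
                indirect[m] = fit.edge_coef(exposure, m) * fit.edge_coef(m, outcome)
        total = direct + sum(indirect.values())
        additive = True
    elif grouping == "first":
        for path in paths:
            if len(path.nodes) == 2:
                continue
            m = path.first_mediator
            indirect[m] = indirect.get(m, 0.0) + path_product(fit, path)
        total = direct + sum(indirect.values())
        additive = True
    else:  # "containing": overlapping groups, double counts shared paths
        mediators = sorted({m for p in paths for m in p.mediators})
        for m in mediators:
            indirect[m] = sum(path_product(fit, p) for p in paths if m in p.mediators)
        total = direct + sum(path_product(fit, p) for p in paths if len(p.nodes) > 2)
        additive = False

    if additive:
        resid = total - (direct + sum(indirect.values()))
        assert abs(resid) <= 1e-12 * max(1.0, abs(total)), "TE != DE + sum(IE)"
    scale = "log-odds" if spec.families[outcome] == "logit" else "linear"
    return EffectDecomposition(
        exposure=exposure, outcome=outcome, scale=scale, grouping=grouping,
        direct=direct, indirect=indirect, total=total, additive=additive,
        n_paths=len(paths),
    )


def classify_mediation(direct: float, indirect: float, total: float,
                       direct_sig: bool, indirect_sig: bool, total_sig: bool) -> str:
    """MacKinnon-style mediation pattern from bootstrap significance flags.

    full        IE significant, DE not, TE significant
    partial     IE and DE significant, same sign
    suppression IE and DE significant, opposite signs (inconsistent mediation)
    none        IE not significant (or nothing else applies)
    """
    if not indirect_sig:
        return "none"
    if direct_sig:
        return "partial" if np.sign(direct) == np.sign(indirect) else "suppression"
    return "full" if total_sig else "none"


def classify_decomposition(decomp: EffectDecomposition, significant: dict) -> dict:
    """Per-mediator classification given a ``{effect_key: bool}`` flag map."""
    out = {}
    for m, ie in decomp.indirect.items():
        out[m] = classify_mediation(
            decomp.direct, ie, decomp.total,
            bool(significant.get("direct", False)),
            bool(significant.get(f"indirect_via_{m}", False)),
            bool(significant.get("total", False)),
        )
    return out
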