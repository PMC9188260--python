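"""Expression-to-flux mapping and the weighted L1 fit problem.

The method assumes the flux through a reaction scales linearly with the
(log2) expression of its coding genes.  Per fitted reaction ``ri`` and
condition ``c`` an expression-based target flux is interpolated between the
reaction's attainable flux range (from FVA) using the position of the mean
expression within its cross-condition range:

    v_fit = V_min + (g_bar - g_min) * (V_max - V_min) / (g_max - g_min)

The fit then minimises, subject to steady state, bounds, optional growth
floors and the medium uptake cap,

    sum_{ri,c} w_ri * |v_{ri,c} - v_fit_{ri,c}|  +  alpha * sum_{ro,c} |v_{ro,c}|

where ``ri`` runs over core (CR) and associated (AR) reactions, ``ro`` over
everything else, w = 1/V_weight for CR and 1/(V_weight+100) for AR with
V_weight = max(|V_max|, |V_min|).  Conditions share no variables, so each is
an independent LP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._solver import LinearProblem
from .core import FEASIBILITY_TOL, add_biomass_floor, add_exchange_cap, extract_fluxes, flux_problem
from .model import FluxSolution, MetabolicNetwork, validate_fluxes

__all__ = [
    "ReactionPartition",
    "ExpressionSummary",
    "FitTargets",
    "FitConfig",
    "DiscrepancyReport",
    "summarize_expression",
    "map_expression_to_flux",
    "compute_weights",
    "select_associated",
    "solve_fit",
    "total_discrepancy",
]

logger = logging.getLogger(__name__)

ASSOCIATED_WEIGHT_OFFSET = 100.0


@dataclass
class ReactionPartition:
    """Disjoint split of the reaction set into core / associated / other."""

    core: list[str]
    associated: list[str]
    other: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.core), set(self.associated), set(self.other)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("core, associated and other must be disjoint")

    @property
    def fitted(self) -> list[str]:
        return list(self.core) + list(self.associated)

    @classmethod
    def from_sets(
        cls,
        net: MetabolicNetwork,
        core: list[str],
        associated: list[str] | None = None,
        fva: pd.DataFrame | None = None,
    ) -> "ReactionPartition":
        """Build a partition, discarding fitted reactions whose FVA range is
        identically zero (they cannot carry flux, so fitting them is vacuous).
        """
        associated = list(associated or [])
        unknown = [r for r in list(core) + associated if r not in net.reaction_ids]
        if unknown:
            raise KeyError(f"partition reactions not in network: {unknown}")

        def alive(rid: str) -> bool:
            if fva is None or rid not in fva.index:
                return True
            lo, hi = fva.loc[rid, "min"], fva.loc[rid, "max"]
            return not (lo == 0.0 and hi == 0.0)

        kept_core = [r for r in core if alive(r)]
        kept_assoc = [r for r in associated if alive(r)]
        dropped = (set(core) - set(kept_core)) | (set(associated) - set(kept_assoc))
        if dropped:
            logger.warning("discarding blocked fitted reactions: %s", sorted(dropped))
        fitted = set(kept_core) | set(kept_assoc)
        other = [r for r in net.reaction_ids if r not in fitted]
        return cls(kept_core, kept_assoc, other)


@dataclass
class ExpressionSummary:
    """Per-reaction mean expression and its range across conditions.

    ``gbar`` is reactions × conditions; ``gmin``/``gmax`` are the row-wise
    extremes.  ``dropped`` lists reactions excluded because none of their
    mapped genes had data.
    """

    gbar: pd.DataFrame
    gmin: pd.Series
    gmax: pd.Series
    dropped: list[str] = field(default_factory=list)


@dataclass
class FitTargets:
    """Expression-derived target fluxes and the flux ranges used to map them."""

    vfit: pd.DataFrame
    vmin: pd.Series
    vmax: pd.Series


@dataclass
class FitConfig:
    """Tunable parameters of the fit objective.

    alpha           weight of the flux penalty on non-fitted reactions
                    (dimensionless, default 0.01)
    weights         per-fitted-reaction residual weights (from compute_weights)
    biomass_floors  condition -> minimum growth rate, applied as v_bio >= B_c
    exchange_cap    total uptake allowed through non-designated exchanges
    designated      exchange ids exempt from the cap (candidate carbon sources)
    """

    alpha: float = 0.01
    weights: pd.Series | None = None
    biomass_floors: dict[str, float] = field(default_factory=dict)
    exchange_cap: float | None = None
    designated: frozenset[str] = frozenset()
    tolerance: float = FEASIBILITY_TOL

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.weights is not None and (self.weights <= 0).any():
            raise ValueError("all residual weights must be > 0")


@dataclass
class DiscrepancyReport:
    """Unweighted residuals |v - v_fit| and their sums."""

    residuals: pd.DataFrame
    per_condition: pd.Series
    total: float


# ---------------------------------------------------------------------------
# expression summarisation and mapping
# ---------------------------------------------------------------------------

def summarize_expression(
    expression: pd.DataFrame,
    gpr: dict[str, list[str]],
    reactions: list[str],
) -> ExpressionSummary:
    """Average each reaction's mapped genes per condition.

    Genes absent from the matrix are ignored (with a warning); a reaction
    whose genes are all absent is dropped from the fit set.  The per-reaction
    min/max are taken across all supplied conditions.
    """
    if not reactions:
        raise ValueError("empty reaction set")
    rows = {}
    dropped = []
    for rid in reactions:
        genes = gpr.get(rid, [])
        present = [g for g in genes if g in expression.index]
        absent = set(genes) - set(present)
        if absent:
            logger.warning("reaction %s: genes without data ignored: %s", rid, sorted(absent))
        if not present:
            dropped.append(rid)
            continue
        rows[rid] = expression.loc[present].mean(axis=0)
    if dropped:
        logger.warning("reactions with no expressed gene dropped from fit: %s", dropped)
    gbar = pd.DataFrame(rows).T
    gbar.index.name = "reaction"
    if not np.isfinite(gbar.to_numpy()).all():
        raise ValueError("non-finite expression summary; check input matrix")
    return ExpressionSummary(
        gbar=gbar, gmin=gbar.min(axis=1), gmax=gbar.max(axis=1), dropped=dropped
    )


def map_expression_to_flux(
    summary: ExpressionSummary, fva: pd.DataFrame
) -> FitTargets:
    """Interpolate expression linearly into the attainable flux range.

    A degenerate expression range (g_max == g_min) leaves the interpolation
    undefined; the midpoint of the flux range is used instead (and collapses
    to the single attainable value when that range is degenerate too).
    """
    common = [r for r in summary.gbar.index if r in fva.index]
    vfit = pd.DataFrame(index=common, columns=summary.gbar.columns, dtype=float)
    vmin = fva.loc[common, "min"].astype(float)
    vmax = fva.loc[common, "max"].astype(float)
    for rid in common:
        lo, hi = vmin[rid], vmax[rid]
        glo, ghi = summary.gmin[rid], summary.gmax[rid]
        if ghi > glo:
            frac = (summary.gbar.loc[rid] - glo) / (ghi - glo)
            vfit.loc[rid] = lo + frac * (hi - lo)
        else:
            logger.info("reaction %s: flat expression, targeting flux-range midpoint", rid)
            vfit.loc[rid] = 0.5 * (lo + hi)
    vfit = vfit.clip(lower=vmin, upper=vmax, axis=0)  # guard float round-off
    return FitTargets(vfit=vfit, vmin=vmin, vmax=vmax)


def compute_weights(
    fva: pd.DataFrame, partition: ReactionPartition
) -> pd.Series:
    """Residual weights: 1/V_weight (core) or 1/(V_weight+100) (associated).

    V_weight = max(|V_max|, |V_min|) equalises the influence of high- and
    low-variance reactions; the +100 offset down-weights associated
    reactions.  A zero V_weight in the fit set means the reaction should
    have been discarded upstream and is an error.
    """
    weights = {}
    for rid in partition.fitted:
        vw = max(abs(fva.loc[rid, "max"]), abs(fva.loc[rid, "min"]))
        if rid in set(partition.associated):
            weights[rid] = 1.0 / (vw + ASSOCIATED_WEIGHT_OFFSET)
        else:
            if vw == 0.0:
                raise ValueError(
                    f"core reaction {rid!r} has zero flux range; discard it first"
                )
            weights[rid] = 1.0 / vw
    return pd.Series(weights, dtype=float)


# ---------------------------------------------------------------------------
# associated-reaction selection
# ---------------------------------------------------------------------------

def select_associated(
    expression: pd.DataFrame,
    control: pd.DataFrame,
    candidates: list[str],
    gpr: dict[str, list[str]],
    replicate_map: dict[str, list[str]],
    fdr: float = 0.05,
) -> list[str]:
    """Keep candidates with >=1 differentially expressed gene in >=1 condition.

    Per gene and condition a two-sample t-test compares the condition's
    replicate columns of ``expression`` against all columns of ``control``;
    Benjamini-Hochberg correction is applied across the pooled gene ×
    condition tests and a candidate reaction is kept when any of its mapped
    genes reaches adjusted p < ``fdr`` in any condition.  Network-adjacency
    and key-metabolite filters are the caller's business: they define
    ``candidates``.
    """
    if control.shape[1] < 2:
        raise ValueError("control group needs >=2 replicate columns")
    for cond, cols in replicate_map.items():
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} needs >=2 replicates for the t-test")
    genes = sorted({g for rid in candidates for g in gpr.get(rid, [])})
    genes = [g for g in genes if g in expression.index and g in control.index]
    keys, pvals = [], []
    for cond, cols in replicate_map.items():
        a = expression.loc[genes, cols].to_numpy(dtype=float)
        b = control.loc[genes].to_numpy(dtype=float)
        with warnings.catch_warnings():
            # zero within-group variance yields t = ±inf, p = 0; that is the
            # intended verdict, not a numerical problem worth reporting
            warnings.simplefilter("ignore", RuntimeWarning)
            t = stats.ttest_ind(a, b, axis=1)
        p = np.asarray(t.pvalue, dtype=float)
        # identical groups yield 0/0 -> NaN; no evidence of change
        p = np.where(np.isnan(p), 1.0, p)
        pvals.extend(p.tolist())
        keys.extend((g, cond) for g in genes)
    adjusted = _benjamini_hochberg(np.asarray(pvals))
    significant = {g for (g, _), q in zip(keys, adjusted) if q < fdr}
    return [
        rid
        for rid in candidates
        if any(g in significant for g in gpr.get(rid, []))
    ]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Standard step-up FDR adjustment."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# the L1 fit LP
# ---------------------------------------------------------------------------

def build_fit_problem(
    net: MetabolicNetwork,
    targets: FitTargets,
    partition: ReactionPartition,
    config: FitConfig,
    condition: str,
) -> LinearProblem:
    """Assemble one condition's fit LP with split-variable |.| linearisation.

    Residuals of fitted reactions enter as v - p + n = v_fit with p, n >= 0
    and objective w*(p+n); each penalised reaction gets a >= |v| via two
    inequalities and objective alpha*a.
    """
    if config.weights is None:
        raise ValueError("FitConfig.weights must be set (see compute_weights)")
    prob = flux_problem(net, f"fit[{condition}]")
    if condition in config.biomass_floors:
        add_biomass_floor(prob, net, config.biomass_floors[condition])
    if config.exchange_cap is not None:
        add_exchange_cap(prob, net, config.designated, config.exchange_cap)
    for rid in partition.fitted:
        if rid not in targets.vfit.index:
            continue  # reaction lost its expression data; nothing to fit
        w = float(config.weights[rid])
        v, p, n = f"v[{rid}]", f"pos[{rid}]", f"neg[{rid}]"
        prob.add_variable(p, 0.0, np.inf)
        prob.add_variable(n, 0.0, np.inf)
        prob.add_constraint(
            {v: 1.0, p: -1.0, n: 1.0},
            lb=float(targets.vfit.loc[rid, condition]),
            ub=float(targets.vfit.loc[rid, condition]),
        )
        prob.add_objective_term(p, w)
        prob.add_objective_term(n, w)
    if config.alpha > 0:
        for rid in partition.other:
            v, a = f"v[{rid}]", f"abs[{rid}]"
            prob.add_variable(a, 0.0, np.inf)
            prob.add_constraint({a: 1.0, v: -1.0}, lb=0.0)  # a >= v
            prob.add_constraint({a: 1.0, v: 1.0}, lb=0.0)  # a >= -v
            prob.add_objective_term(a, config.alpha)
    return prob


def _objective_parts(
    net: MetabolicNetwork,
    fluxes: pd.Series,
    targets: FitTargets,
    partition: ReactionPartition,
    config: FitConfig,
    condition: str,
) -> tuple[float, float]:
    fitted = [r for r in partition.fitted if r in targets.vfit.index]
    resid = (fluxes[fitted] - targets.vfit.loc[fitted, condition]).abs()
    fit_term = float((resid * config.weights[fitted]).sum())
    penalty = float(fluxes[partition.other].abs().sum())
    return fit_term, penalty


def solve_fit(
    net: MetabolicNetwork,
    targets: FitTargets,
    partition: ReactionPartition,
    config: FitConfig,
    conditions: list[str] | None = None,
) -> tuple[FluxSolution, DiscrepancyReport]:
    """Solve the per-condition fit LPs and report the mapping discrepancy.

    Conditions share no variables, so the summed objective decomposes
    exactly into independent solves.  Every solution is validated against
    mass balance and bounds before being returned; an infeasible condition
    is reported in the status map, never silently.
    """
    conditions = list(conditions or targets.vfit.columns)
    cols, objective, status, fit_terms, penalties = {}, {}, {}, {}, {}
    for cond in conditions:
        prob = build_fit_problem(net, targets, partition, config, cond)
        res = prob.solve()
        status[cond] = res.status
        if not res.ok:
            cols[cond] = pd.Series(np.nan, index=net.reaction_ids)
            continue
        v = extract_fluxes(net, res)
        validate_fluxes(net, v, config.tolerance)
        cols[cond] = v
        objective[cond] = res.objective
        fit_terms[cond], penalties[cond] = _objective_parts(
            net, v, targets, partition, config, cond
        )
    solution = FluxSolution(
        fluxes=pd.DataFrame(cols),
        objective=objective,
        status=status,
        fit_term=fit_terms,
        penalty_term=penalties,
    )
    report = total_discrepancy(solution, targets, partition)
    return solution, report


def total_discrepancy(
    solution: FluxSolution,
    targets: FitTargets,
    partition: ReactionPartition | None = None,
) -> DiscrepancyReport:
    """Total model mapping discrepancy d = Σ_c Σ_ri |v - v_fit| (unweighted)."""
    fitted = list(targets.vfit.index)
    if partition is not None:
        fitted = [r for r in partition.fitted if r in targets.vfit.index]
    conds = [c for c in solution.conditions if c in targets.vfit.columns]
    if not conds:
        raise ValueError("no overlapping conditions between solution and targets")
    missing = [r for r in fitted if r not in solution.fluxes.index]
    if missing:
        raise ValueError(f"solution lacks fitted reactions: {missing}")
    resid = (solution.fluxes.loc[fitted, conds] - targets.vfit.loc[fitted, conds]).abs()
    per_condition = resid.sum(axis=0)
    return DiscrepancyReport(
        residuals=resid,
        per_condition=per_condition,
        total=float(per_condition.sum()),
    )
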