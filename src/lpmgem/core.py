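"""FBA, FVA and the shared auxiliary constraints.

All flux problems share the same skeleton: one variable per reaction with
the network bounds, one mass-balance row S·v = 0 per metabolite.  The
helpers here add the optional constraints used throughout the pipeline —
a growth floor on the biomass reaction, a cap on the summed uptake of
non-designated exchange reactions, and opened uptake bounds for a set of
candidate carbon transporters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._solver import LinearProblem, SolveResult
from .model import FluxSolution, MetabolicNetwork, validate_fluxes

__all__ = [
    "flux_problem",
    "run_fba",
    "run_fva",
    "add_exchange_cap",
    "add_biomass_floor",
    "configure_carbon_uptake_bounds",
    "InfeasibleError",
]

FEASIBILITY_TOL = 1e-6


class InfeasibleError(RuntimeError):
    """A required base problem has no feasible point."""


def flux_problem(net: MetabolicNetwork, name: str = "fba") -> LinearProblem:
    """Build the steady-state skeleton: flux variables + S·v = 0 rows."""
    prob = LinearProblem(name)
    for rid, lo, hi in zip(net.reaction_ids, net.lb, net.ub):
        prob.add_variable(f"v[{rid}]", lo, hi)
    for i, met in enumerate(net.metabolite_ids):
        row = {
            f"v[{net.reaction_ids[j]}]": net.S[i, j]
            for j in np.flatnonzero(net.S[i, :])
        }
        if row:
            prob.add_constraint(row, 0.0, 0.0)
    return prob


def extract_fluxes(net: MetabolicNetwork, result: SolveResult) -> pd.Series:
    return pd.Series(
        [result.values[f"v[{rid}]"] for rid in net.reaction_ids],
        index=net.reaction_ids,
        dtype=float,
    )


def add_biomass_floor(
    prob: LinearProblem, net: MetabolicNetwork, floor: float
) -> None:
    """Add the growth constraint v_biomass ≥ floor (a lower limit, h⁻¹)."""
    if net.biomass_reaction_id is None:
        raise ValueError("network has no biomass reaction")
    if floor < 0:
        raise ValueError(f"biomass floor must be >= 0, got {floor}")
    prob.add_constraint({f"v[{net.biomass_reaction_id}]": 1.0}, lb=floor)


def add_exchange_cap(
    prob: LinearProblem,
    net: MetabolicNetwork,
    designated: set[str] | frozenset[str],
    cap: float,
) -> None:
    """Cap the summed uptake magnitude of non-designated exchange reactions.

    For each exchange reaction e outside ``designated`` an auxiliary
    u_e ≥ max(0, −v_e) is introduced and Σ u_e ≤ cap added, so only influx
    counts against the cap.  Designated exchanges (the candidate carbon
    sources of the medium) are exempt.
    """
    if cap < 0:
        raise ValueError(f"exchange cap must be >= 0, got {cap}")
    unknown = set(designated) - set(net.exchange_ids)
    if unknown:
        raise ValueError(f"designated ids are not exchange reactions: {sorted(unknown)}")
    if not np.isfinite(cap):
        return
    total: dict[str, float] = {}
    for rid in net.exchange_ids:
        if rid in designated:
            continue
        u = f"uptake[{rid}]"
        prob.add_variable(u, 0.0, np.inf)
        prob.add_constraint({u: 1.0, f"v[{rid}]": 1.0}, lb=0.0)  # u >= -v
        total[u] = 1.0
    if total:
        prob.add_constraint(total, ub=cap)


def configure_carbon_uptake_bounds(
    net: MetabolicNetwork, transporters: dict[str, float]
) -> MetabolicNetwork:
    """Open the uptake bound of every listed carbon exchange simultaneously.

    Each listed exchange gets lb = −rate in all conditions, so the model can
    draw any candidate source and no prior knowledge of the true source
    enters the problem.  Rates must be non-negative uptake magnitudes.
    """
    exchange = set(net.exchange_ids)
    overrides = {}
    for rid, rate in transporters.items():
        if rid not in exchange:
            raise ValueError(f"{rid!r} is not an exchange reaction")
        if rate < 0:
            raise ValueError(f"uptake rate for {rid!r} must be >= 0, got {rate}")
        overrides[rid] = (-float(rate), float(net.ub[net.index(rid)]))
    return net.with_bounds(overrides) if overrides else net


def run_fba(
    net: MetabolicNetwork,
    objective: str,
    sense: str = "max",
    *,
    biomass_floor: float | None = None,
    exchange_cap: float | None = None,
    designated: set[str] = frozenset(),
    label: str = "fba",
) -> FluxSolution:
    """Solve one flux balance problem optimising a single reaction's flux."""
    if sense not in {"max", "min"}:
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    net.index(objective)  # raises KeyError for unknown reaction
    prob = flux_problem(net)
    if biomass_floor is not None:
        add_biomass_floor(prob, net, biomass_floor)
    if exchange_cap is not None:
        add_exchange_cap(prob, net, designated, exchange_cap)
    prob.set_objective({f"v[{objective}]": -1.0 if sense == "max" else 1.0})
    res = prob.solve()
    if res.ok:
        fluxes = extract_fluxes(net, res).to_frame(label)
        validate_fluxes(net, fluxes, FEASIBILITY_TOL)
        obj = {label: (-res.objective if sense == "max" else res.objective)}
    else:
        fluxes = pd.DataFrame(index=net.reaction_ids, columns=[label], dtype=float)
        obj = {}
    return FluxSolution(fluxes=fluxes, objective=obj, status={label: res.status})


def run_fva(
    net: MetabolicNetwork,
    reactions: list[str] | None = None,
) -> pd.DataFrame:
    """Flux variability analysis: per-reaction attainable (min, max).

    Two LPs per requested reaction over the globally-bounded steady-state
    polytope (no condition-specific constraints).  Returns a DataFrame
    indexed by reaction with columns ``min`` and ``max``.
    """
    reactions = list(reactions) if reactions is not None else list(net.reaction_ids)
    if not reactions:
        raise ValueError("empty reaction set for FVA")
    base = flux_problem(net)
    base.set_objective({})
    feas = base.solve()
    if not feas.ok:
        raise InfeasibleError(f"base network is {feas.status}; FVA aborted")
    out = pd.DataFrame(index=reactions, columns=["min", "max"], dtype=float)
    for rid in reactions:
        net.index(rid)  # raises for unknown ids
        var = f"v[{rid}]"
        lo_hi = []
        for sign in (1.0, -1.0):
            base.set_objective({var: sign})
            res = base.solve()
            if not res.ok:  # pragma: no cover - bounded problems stay solvable
                raise InfeasibleError(f"FVA LP for {rid!r} ended {res.status}")
            lo_hi.append(sign * res.objective)
        out.loc[rid, "min"], out.loc[rid, "max"] = lo_hi
    # numerical guard: clamp into declared bounds and enforce min <= max
    for rid in reactions:
        j = net.index(rid)
        out.loc[rid, "min"] = min(max(out.loc[rid, "min"], net.lb[j]), net.ub[j])
        out.loc[rid, "max"] = min(max(out.loc[rid, "max"], out.loc[rid, "min"]), net.ub[j])
    return out
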