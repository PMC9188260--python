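"""RED-TIL: iterative removal of thermodynamically infeasible loops.

The loop law states that at steady state no closed cycle of internal
reactions may carry a nonzero net flux.  A single large MILP enforcing this
globally (the loopless-FBA construction, available here as
:func:`full_loopless_reference`) is expensive; RED-TIL instead works
bottom-up: solve the fit, look for a smallest flux-carrying internal cycle
within the solution's support, forbid it with a cut, re-solve, and repeat
until no cycle above a flux threshold remains.

Loop detection is a small MILP over the oriented support columns
(S columns sign-flipped for reactions carrying negative flux, so cycle flux
variables λ are nonnegative in the solution's direction):

    minimise Σ λ_r   s.t.   Σ S_r λ_r = 0,   λ_r ≥ inFC_r,
                            λ_r ≤ cap · inFC_r,   Σ inFC_r ≥ 2,
                            inFC_r ∈ {0,1}

Infeasibility certifies the support carries no circulation.  A detected
loop of length k is excluded by requiring at least one member to carry less
than the threshold flux in the loop's direction, encoded with big-M
indicator binaries on the continuous fit problem.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import null_space

from ._solver import LinearProblem
from .core import extract_fluxes
from .fit import (
    DiscrepancyReport,
    FitConfig,
    FitTargets,
    ReactionPartition,
    build_fit_problem,
    total_discrepancy,
)
from .model import FluxSolution, MetabolicNetwork, validate_fluxes

__all__ = [
    "LoopCut",
    "OracleDisagreement",
    "support_set",
    "detect_min_loop",
    "run_redtil",
    "loopless_check",
    "full_loopless_reference",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.01
LAMBDA_CAP = 1000.0


class OracleDisagreement(RuntimeError):
    """The MILP and cycle-enumeration loop oracles returned different verdicts."""


@dataclass(frozen=True)
class LoopCut:
    """A detected infeasible loop: oriented members and its exclusion cut."""

    members: tuple[tuple[str, int], ...]  # (reaction id, direction sign)

    @property
    def k(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("a loop involves at least two reactions")


def support_set(
    fluxes: pd.Series, net: MetabolicNetwork, threshold: float = DEFAULT_THRESHOLD
) -> list[tuple[str, int]]:
    """Internal reactions with |v| >= threshold, tagged with the flux sign.

    Exchange reactions cross the boundary and cannot be part of an internal
    cycle, so they are never included.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = []
    for rid in net.internal_ids:
        v = float(fluxes[rid])
        if abs(v) >= threshold:
            out.append((rid, 1 if v > 0 else -1))
    return out


def detect_min_loop(
    net: MetabolicNetwork,
    support: list[tuple[str, int]],
    lam_cap: float = LAMBDA_CAP,
) -> LoopCut | None:
    """Find a minimum-total-flux circulation within the oriented support.

    Returns the loop as the reactions whose membership indicator is active,
    or ``None`` when the MILP is infeasible (no circulation exists).  The
    λ ≤ cap·inFC link ties membership to the circulation's support so the
    returned set is exactly the cycle carrying flux.
    """
    if not support:
        return None
    prob = LinearProblem("min-loop")
    for rid, _ in support:
        prob.add_variable(f"lam[{rid}]", 0.0, lam_cap)
        prob.add_variable(f"in[{rid}]", 0.0, 1.0, integer=True)
        prob.add_constraint({f"lam[{rid}]": 1.0, f"in[{rid}]": -1.0}, lb=0.0)
        prob.add_constraint({f"lam[{rid}]": 1.0, f"in[{rid}]": -lam_cap}, ub=0.0)
        prob.add_objective_term(f"lam[{rid}]", 1.0)
    cols = {rid: sign * net.column(rid) for rid, sign in support}
    for i in range(net.n_metabolites):
        row = {f"lam[{rid}]": col[i] for rid, col in cols.items() if col[i] != 0.0}
        if row:
            prob.add_constraint(row, 0.0, 0.0)
    prob.add_constraint({f"in[{rid}]": 1.0 for rid, _ in support}, lb=2.0)
    res = prob.solve()
    if res.status == "infeasible":
        return None
    if not res.ok:
        raise RuntimeError(f"loop-detection MILP ended with status {res.status}")
    signs = dict(support)
    members = tuple(
        sorted((rid, signs[rid]) for rid, _ in support if res[f"in[{rid}]"] > 0.5)
    )
    return LoopCut(members=members)


# ---------------------------------------------------------------------------
# the iterative removal loop
# ---------------------------------------------------------------------------

@dataclass
class RedtilResult:
    solution: FluxSolution
    report: DiscrepancyReport
    cuts: dict[str, list[LoopCut]]
    log: pd.DataFrame = field(default_factory=pd.DataFrame)


def _solve_with_cuts(
    net: MetabolicNetwork,
    targets: FitTargets,
    partition: ReactionPartition,
    config: FitConfig,
    condition: str,
    cuts: list[LoopCut],
    threshold: float,
):
    """Re-solve one condition's fit with the accumulated loop cuts.

    Each oriented reaction occurring in a cut gets an indicator binary y,
    with y = 0 forcing its flux in the loop's direction to zero; per cut at
    most k−1 members may keep loop-direction flux, so at least one member
    drops out of the cycle entirely.  Big-M is the largest bound magnitude
    in the network.
    """
    prob = build_fit_problem(net, targets, partition, config, condition)
    if cuts:
        big_m = float(max(np.max(np.abs(net.lb)), np.max(np.abs(net.ub)))) + threshold
        allow = 0.0  # an excluded member carries no loop-direction flux
        seen: set[tuple[str, int]] = set()
        for cut in cuts:
            for rid, sign in cut.members:
                if (rid, sign) in seen:
                    continue
                seen.add((rid, sign))
                y = f"y[{rid},{sign:+d}]"
                prob.add_variable(y, 0.0, 1.0, integer=True)
                # sign*v <= allow + M*y
                prob.add_constraint({f"v[{rid}]": float(sign), y: -big_m}, ub=allow)
            prob.add_constraint(
                {f"y[{rid},{sign:+d}]": 1.0 for rid, sign in cut.members},
                ub=cut.k - 1,
            )
    return prob.solve()


def run_redtil(
    net: MetabolicNetwork,
    targets: FitTargets,
    partition: ReactionPartition,
    config: FitConfig,
    threshold: float = DEFAULT_THRESHOLD,
    conditions: list[str] | None = None,
) -> RedtilResult:
    """Alternate fit re-optimisation and loop exclusion until loop-free.

    Loops are detected against the support of each fresh solution, and cuts
    are condition-specific (a loop found in one condition's solution only
    constrains that condition).  Zero flux on every internal cycle is always
    feasible, so the cut accumulation terminates with a solution whose
    support carries no circulation at the given threshold.
    """
    conditions = list(conditions or targets.vfit.columns)
    cols, objective, status = {}, {}, {}
    all_cuts: dict[str, list[LoopCut]] = {}
    log_rows = []
    for cond in conditions:
        cuts: list[LoopCut] = []
        seen: set[tuple] = set()
        prev_objective = -np.inf
        while True:
            res = _solve_with_cuts(net, targets, partition, config, cond, cuts, threshold)
            if not res.ok:
                raise RuntimeError(
                    f"condition {cond!r}: fit with {len(cuts)} cuts ended "
                    f"{res.status}; cuts: {cuts}"
                )
            if res.objective < prev_objective - 1e-7:
                raise AssertionError(
                    "objective decreased after adding a cut (relaxation grew)"
                )
            prev_objective = res.objective
            v = extract_fluxes(net, res)
            loop = detect_min_loop(net, support_set(v, net, threshold))
            if loop is None:
                validate_fluxes(net, v, config.tolerance)
                cols[cond] = v
                objective[cond] = res.objective
                status[cond] = "optimal"
                break
            if loop.members in seen:
                raise AssertionError(f"cut repeated: {loop.members}")
            seen.add(loop.members)
            cuts.append(loop)
            log_rows.append(
                {
                    "condition": cond,
                    "iteration": len(cuts),
                    "k": loop.k,
                    "members": ";".join(f"{r}{'+' if s > 0 else '-'}" for r, s in loop.members),
                    "objective": res.objective,
                }
            )
            logger.info("condition %s: excluded loop %s", cond, loop.members)
        all_cuts[cond] = cuts
    solution = FluxSolution(
        fluxes=pd.DataFrame(cols), objective=objective, status=status
    )
    report = total_discrepancy(solution, targets, partition)
    return RedtilResult(
        solution=solution,
        report=report,
        cuts=all_cuts,
        log=pd.DataFrame(log_rows, columns=["condition", "iteration", "k", "members", "objective"]),
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _enumerate_balanced_cycles(
    net: MetabolicNetwork, support: list[tuple[str, int]]
) -> list[tuple[str, ...]]:
    """Enumerate stoichiometrically balanced directed cycles in the support.

    The support is viewed as a gain graph on metabolites: each oriented
    reaction must consume exactly one metabolite and produce exactly one
    (the topology of all fixtures here); an edge carries the produced/
    consumed coefficient ratio, and a simple cycle is balanced iff the gain
    product around it is 1.  Reactions with other topologies make the
    enumeration inapplicable and raise ``NotImplementedError``.
    """
    edges: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for rid, sign in support:
        col = sign * net.column(rid)
        consumed = np.flatnonzero(col < 0)
        produced = np.flatnonzero(col > 0)
        if len(consumed) != 1 or len(produced) != 1:
            raise NotImplementedError(
                f"cycle enumeration needs 1-in/1-out reactions; {rid!r} is not"
            )
        src = net.metabolite_ids[consumed[0]]
        dst = net.metabolite_ids[produced[0]]
        gain = float(col[produced[0]] / -col[consumed[0]])
        edges.setdefault((src, dst), []).append((rid, gain))
    graph = nx.DiGraph(list(edges))
    balanced = []
    for node_cycle in nx.simple_cycles(graph):
        pairs = [
            (node_cycle[i], node_cycle[(i + 1) % len(node_cycle)])
            for i in range(len(node_cycle))
        ]
        for combo in itertools.product(*(edges[p] for p in pairs)):
            gain = float(np.prod([g for _, g in combo]))
            if abs(gain - 1.0) < 1e-9:
                balanced.append(tuple(sorted(r for r, _ in combo)))
    return balanced


def loopless_check(
    fluxes: pd.Series,
    net: MetabolicNetwork,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[bool, list]:
    """Certify that a solution's support carries no infeasible loop.

    Two independent routes must agree: (a) the loop-detection MILP is
    infeasible over the oriented support; (b) exhaustive enumeration of
    balanced directed cycles in the support graph finds none.  Disagreement
    raises :class:`OracleDisagreement`.  Returns (verdict, certificate)
    where the certificate lists the offending cycles when the verdict is
    False.
    """
    support = support_set(fluxes, net, threshold)
    milp_loop = detect_min_loop(net, support)
    milp_free = milp_loop is None
    cycles = _enumerate_balanced_cycles(net, support)
    enum_free = not cycles
    if milp_free != enum_free:
        raise OracleDisagreement(
            f"MILP says loop-free={milp_free}, enumeration says {enum_free} "
            f"(MILP loop: {milp_loop}, cycles: {cycles})"
        )
    return milp_free, cycles


def full_loopless_reference(
    net: MetabolicNetwork,
    targets: FitTargets,
    partition: ReactionPartition,
    config: FitConfig,
    conditions: list[str] | None = None,
    max_reactions: int = 200,
) -> FluxSolution:
    """Single-MILP loopless fit: the classical direction-binary construction.

    Every internal reaction gets a direction binary a and a potential-like
    variable G forced to the sign opposite the flux; G is constrained
    orthogonal to the nullspace of the internal stoichiometric columns, so
    no flux-carrying internal circulation can exist at all.  This enforces
    exactly-zero loop flux (stricter than the thresholded iterative method)
    and serves as the validation reference on small networks only — the
    MILP grows quickly, hence the size guard.
    """
    if net.n_reactions > max_reactions:
        raise ValueError(
            f"reference loopless solver is guarded to <= {max_reactions} reactions"
        )
    conditions = list(conditions or targets.vfit.columns)
    internal = net.internal_ids
    S_int = net.S[:, [net.index(r) for r in internal]]
    N = null_space(S_int)
    big_m = float(max(np.max(np.abs(net.lb)), np.max(np.abs(net.ub)), 1.0))
    K = 1000.0
    cols, objective, status = {}, {}, {}
    for cond in conditions:
        prob = build_fit_problem(net, targets, partition, config, cond)
        for rid in internal:
            a, g, v = f"dir[{rid}]", f"G[{rid}]", f"v[{rid}]"
            prob.add_variable(a, 0.0, 1.0, integer=True)
            prob.add_variable(g, -K, K)
            prob.add_constraint({v: 1.0, a: -big_m}, ub=0.0)  # v <= M*a
            prob.add_constraint({v: 1.0, a: -big_m}, lb=-big_m)  # v >= -M*(1-a)
            prob.add_constraint({g: 1.0, a: K + 1.0}, ub=K)  # a=1 -> G <= -1
            prob.add_constraint({g: 1.0, a: K + 1.0}, lb=1.0)  # a=0 -> G >= 1
        for col in range(N.shape[1]):
            row = {
                f"G[{rid}]": float(N[i, col])
                for i, rid in enumerate(internal)
                if abs(N[i, col]) > 1e-12
            }
            if row:
                prob.add_constraint(row, 0.0, 0.0)
        res = prob.solve()
        status[cond] = res.status
        if res.ok:
            v = extract_fluxes(net, res)
            validate_fluxes(net, v, config.tolerance)
            cols[cond] = v
            objective[cond] = res.objective
        else:
            cols[cond] = pd.Series(np.nan, index=net.reaction_ids)
    return FluxSolution(fluxes=pd.DataFrame(cols), objective=objective, status=status)
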