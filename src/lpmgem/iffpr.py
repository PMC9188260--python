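"""Iterative Feasible Flux Space Reduction (IFFPR).

FVA-derived flux ranges on a genome-scale network are often inflated far
beyond physiological values, mostly by internal cycles, which makes the
linear expression→flux mapping aim at unrealistically large targets.  IFFPR
shrinks the mapping ranges reaction by reaction: reactions are ranked by
their representative maximal bound max(|V_max|, |V_min|) and, starting from
the top, each reaction's range is repeatedly halved — both bounds when they
straddle zero, otherwise only the bound further from zero — with the
expression targets re-derived and the fit re-solved after every halving.  A
halving is kept only if the total model mapping discrepancy d strictly
decreases; otherwise the previous range is restored and the next reaction
is processed.  The run stops when d has been stable over a window of
processed reactions, when every reaction has been processed, or at an
iteration cap.  By construction the accepted-step d sequence never
increases.

The reduction is a training-phase step: the narrowed ranges it outputs are
reused unchanged when predicting new conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .fit import (
    DiscrepancyReport,
    FitConfig,
    FitTargets,
    ExpressionSummary,
    ReactionPartition,
    map_expression_to_flux,
    solve_fit,
)
from .model import FluxSolution, MetabolicNetwork

__all__ = ["BoundsState", "IffprResult", "rank_reactions", "halve_bounds", "run_iffpr"]

STABILITY_TOL = 1e-4
STABILITY_WINDOW = 10


@dataclass
class BoundsState:
    """Mapping bounds evolved by IFFPR, with provenance for inspection.

    ``bounds`` has columns ``min``/``max``; ``history`` records every
    evaluated halving as (reaction, iteration, Vmin, Vmax, d, accepted).
    """

    bounds: pd.DataFrame
    initial: pd.DataFrame
    iteration: int = 0
    history: list[dict] = field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.history,
            columns=["reaction", "iteration", "Vmin", "Vmax", "d", "accepted"],
        )

    def write_history(self, path: str | Path) -> Path:
        path = Path(path)
        self.history_frame().to_csv(path, sep="\t", index=False)
        return path


def rank_reactions(fva: pd.DataFrame) -> list[str]:
    """Order reactions by representative maximal bound, largest first.

    The representative bound is max(|V_max|, |V_min|); ties break on the
    reaction id so the ordering is deterministic.
    """
    if fva.empty:
        raise ValueError("empty FVA table")
    rep = fva[["min", "max"]].abs().max(axis=1)
    return sorted(rep.index, key=lambda rid: (-rep[rid], rid))


def halve_bounds(vmin: float, vmax: float) -> tuple[float, float]:
    """One halving step of a mapping range.

    Ranges straddling zero have both bounds halved; a non-negative range has
    only V_max halved, a non-positive one only V_min — always the bound
    further from zero, so the range shrinks.  If halving would cross the
    fixed bound the moving bound clamps onto it (the range cannot invert).
    """
    if vmin <= 0.0 <= vmax:
        new = (0.5 * vmin, 0.5 * vmax)
    elif vmin > 0.0:  # both positive
        new = (vmin, max(0.5 * vmax, vmin))
    else:  # both negative
        new = (min(0.5 * vmin, vmax), vmax)
    return new


@dataclass
class IffprResult:
    state: BoundsState
    solution: FluxSolution
    report: DiscrepancyReport
    targets: FitTargets
    initial_discrepancy: float

    @property
    def final_discrepancy(self) -> float:
        return self.report.total


def run_iffpr(
    net: MetabolicNetwork,
    summary: ExpressionSummary,
    partition: ReactionPartition,
    config: FitConfig,
    fva: pd.DataFrame,
    *,
    max_outer: int | None = None,
    stability: float = STABILITY_TOL,
    window: int = STABILITY_WINDOW,
) -> IffprResult:
    """Run the full bound-reduction loop.

    ``fva`` provides the initial mapping ranges for the fitted reactions.
    Deterministic: there is no randomness anywhere in the procedure, so two
    runs with the same inputs are bit-identical.
    """
    fitted = [r for r in partition.fitted if r in summary.gbar.index]
    bounds = fva.loc[fitted, ["min", "max"]].astype(float).copy()
    state = BoundsState(bounds=bounds, initial=bounds.copy())

    targets = map_expression_to_flux(summary, bounds)
    solution, report = solve_fit(net, targets, partition, config)
    if not solution.all_optimal():
        bad = {c: s for c, s in solution.status.items() if s != "optimal"}
        raise RuntimeError(f"initial fit not solvable: {bad}")
    d = report.total
    initial_d = d

    order = rank_reactions(bounds)
    recent: list[float] = [d]
    stopped = False
    for rid in order:
        if stopped:
            break
        while True:
            if max_outer is not None and state.iteration >= max_outer:
                stopped = True
                break
            prev = (float(bounds.loc[rid, "min"]), float(bounds.loc[rid, "max"]))
            new = halve_bounds(*prev)
            if new == prev:
                break  # range fully collapsed onto its fixed bound
            state.iteration += 1
            bounds.loc[rid, ["min", "max"]] = new
            trial_targets = map_expression_to_flux(summary, bounds)
            trial_solution, trial_report = solve_fit(net, trial_targets, partition, config)
            accepted = trial_solution.all_optimal() and trial_report.total < d
            state.history.append(
                {
                    "reaction": rid,
                    "iteration": state.iteration,
                    "Vmin": new[0],
                    "Vmax": new[1],
                    "d": trial_report.total if trial_solution.all_optimal() else float("nan"),
                    "accepted": accepted,
                }
            )
            if accepted:
                targets, solution, report = trial_targets, trial_solution, trial_report
                d = trial_report.total
            else:
                bounds.loc[rid, ["min", "max"]] = prev  # revert the halving
                break
        # stability check over the d values seen after each processed reaction
        recent.append(d)
        if len(recent) > window:
            recent.pop(0)
            span = max(recent) - min(recent)
            scale = max(max(recent), 1e-12)
            if span / scale < stability:
                stopped = True

    return IffprResult(
        state=state,
        solution=solution,
        report=report,
        targets=targets,
        initial_discrepancy=initial_d,
    )
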