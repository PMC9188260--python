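"""Core in-memory containers for stoichiometric networks and flux states."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetabolicNetwork", "FluxSolution", "ValidationError"]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An input violates a structural invariant of the model."""


@dataclass
class MetabolicNetwork:
    """A stoichiometric network with flux bounds.

    Rows of ``S`` are metabolites, columns are reactions; entries are the
    (dimensionless) stoichiometric coefficients.  Fluxes are in
    mmol·gDW⁻¹·h⁻¹ by the usual convention.  Exchange reactions cross the
    system boundary; a negative exchange flux means uptake and a positive
    one secretion.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reversible: np.ndarray
    is_exchange: np.ndarray
    biomass_reaction_id: str | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.is_exchange = np.asarray(self.is_exchange, dtype=bool)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        n_met, n_rxn = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n_met, n_rxn):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({n_met}, {n_rxn})"
            )
        for arr, name in [
            (self.lb, "lb"),
            (self.ub, "ub"),
            (self.reversible, "reversible"),
            (self.is_exchange, "is_exchange"),
        ]:
            if len(arr) != n_rxn:
                raise ValidationError(f"{name} has length {len(arr)}, expected {n_rxn}")
        if len(set(self.reaction_ids)) != n_rxn:
            raise ValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != n_met:
            raise ValidationError("duplicate metabolite ids")
        bad = np.flatnonzero(self.lb > self.ub)
        if bad.size:
            rid = self.reaction_ids[bad[0]]
            raise ValidationError(
                f"reaction {rid!r}: lb {self.lb[bad[0]]} > ub {self.ub[bad[0]]}"
            )
        if self.biomass_reaction_id is not None and (
            self.biomass_reaction_id not in self.reaction_ids
        ):
            raise ValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in network"
            )
        # reversibility flag vs bounds: inconsistency is legal but suspicious
        incons = np.flatnonzero(~self.reversible & (self.lb < 0) & ~self.is_exchange)
        if incons.size:
            warnings.warn(
                "reactions flagged irreversible but with negative lower bound: "
                + ", ".join(self.reaction_ids[i] for i in incons[:5]),
                stacklevel=2,
            )

    # -- convenience --------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    @property
    def exchange_ids(self) -> list[str]:
        return [r for r, ex in zip(self.reaction_ids, self.is_exchange) if ex]

    @property
    def internal_ids(self) -> list[str]:
        return [r for r, ex in zip(self.reaction_ids, self.is_exchange) if not ex]

    def column(self, reaction_id: str) -> np.ndarray:
        return self.S[:, self.index(reaction_id)]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            reversible=self.reversible.copy(),
            is_exchange=self.is_exchange.copy(),
            biomass_reaction_id=self.biomass_reaction_id,
        )

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicNetwork":
        """Return a copy with the given per-reaction (lb, ub) overrides."""
        net = self.copy()
        for rid, (lo, hi) in bounds.items():
            i = net.index(rid)
            net.lb[i], net.ub[i] = lo, hi
        net.validate()
        return net


@dataclass
class FluxSolution:
    """Per-condition steady-state flux vectors.

    ``fluxes`` is a reactions × conditions table in network reaction order.
    ``fit_term`` and ``penalty_term`` carry the two components of the fit
    objective (weighted residual sum and unscaled Σ|v| over penalised
    reactions) where applicable.
    """

    fluxes: pd.DataFrame
    objective: dict[str, float] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    fit_term: dict[str, float] = field(default_factory=dict)
    penalty_term: dict[str, float] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.fluxes.columns)

    def vector(self, condition: str) -> pd.Series:
        return self.fluxes[condition]

    def all_optimal(self) -> bool:
        return all(s == "optimal" for s in self.status.values())


def validate_fluxes(
    net: MetabolicNetwork, fluxes: pd.DataFrame | pd.Series, tol: float = 1e-6
) -> float:
    """Check mass balance and bound satisfaction of a flux table.

    Returns the worst violation found; raises :class:`ValidationError` if it
    exceeds ``tol``.  Applied to every solution the package returns.
    """
    if isinstance(fluxes, pd.Series):
        fluxes = fluxes.to_frame("_")
    v = fluxes.reindex(net.reaction_ids).to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValidationError("flux table missing reactions or containing NaN")
    imbalance = np.abs(net.S @ v).max(initial=0.0)
    below = np.max(net.lb[:, None] - v, initial=0.0)
    above = np.max(v - net.ub[:, None], initial=0.0)
    worst = max(imbalance, below, above)
    if worst > tol:
        raise ValidationError(
            f"flux solution violates constraints by {worst:.3e} (tol {tol:g})"
        )
    return float(worst)
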