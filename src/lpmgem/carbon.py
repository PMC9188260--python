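"""Carbon-source calling from transporter fluxes, plus evaluation metrics.

The primary carbon source of a condition is inferred by standardising each
candidate transporter's uptake across conditions (z-scores) and ranking
within the condition: the highest z is called primary, the second highest
secondary.  Standardising per transporter lets transporters with small
absolute flux differences compete with high-flux ones on equal footing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FluxSolution

__all__ = [
    "CarbonCall",
    "zscore_transporters",
    "call_carbon_sources",
    "normalized_error",
    "correlation_eval",
]

logger = logging.getLogger(__name__)


@dataclass
class CarbonCall:
    """Per-condition ranked transporter calls with their z-scores."""

    ranking: dict[str, list[str]]
    zscores: pd.DataFrame  # transporters × conditions
    ties: dict[str, list[str]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def primary(self, condition: str) -> str:
        return self.ranking[condition][0]

    def secondary(self, condition: str) -> str | None:
        ranked = self.ranking[condition]
        return ranked[1] if len(ranked) > 1 else None

    def to_json(self, path: str | Path) -> Path:
        payload = {
            cond: {
                "primary": self.primary(cond),
                "secondary": self.secondary(cond),
                "zscores": {t: float(self.zscores.loc[t, cond]) for t in self.zscores.index},
                "ties": self.ties.get(cond, []),
            }
            for cond in self.ranking
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def zscore_transporters(
    solution: FluxSolution | pd.DataFrame,
    transporters: list[str],
    use_uptake_magnitude: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardise transporter uptake across conditions.

    By default the uptake magnitude |min(v, 0)| is scored, so that with the
    uptake-is-negative exchange convention a stronger influx scores higher;
    ``use_uptake_magnitude=False`` scores the signed flux instead.  Uses the
    sample (n−1) standard deviation.  Transporters constant across
    conditions have an undefined z and are excluded with a warning.
    """
    fluxes = solution.fluxes if isinstance(solution, FluxSolution) else solution
    if fluxes.shape[1] < 2:
        raise ValueError("z-scores need >= 2 conditions")
    missing = [t for t in transporters if t not in fluxes.index]
    if missing:
        raise KeyError(f"transporters not in flux table: {missing}")
    sub = fluxes.loc[transporters].astype(float)
    values = (-sub).clip(lower=0.0) if use_uptake_magnitude else sub
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    degenerate = sd.index[sd == 0.0].tolist()
    if degenerate:
        logger.warning("transporters with constant uptake excluded: %s", degenerate)
    kept = [t for t in transporters if t not in degenerate]
    z = values.loc[kept].sub(mean[kept], axis=0).div(sd[kept], axis=0)
    return z, degenerate


def call_carbon_sources(zscores: pd.DataFrame, excluded: list[str] | None = None) -> CarbonCall:
    """Rank transporters by z-score within each condition.

    Exact ties are broken lexicographically on the transporter id and
    flagged per condition, so calls are deterministic but the ambiguity is
    visible.
    """
    ranking: dict[str, list[str]] = {}
    ties: dict[str, list[str]] = {}
    for cond in zscores.columns:
        col = zscores[cond]
        order = sorted(col.index, key=lambda t: (-col[t], t))
        ranking[cond] = order
        tied = [
            t
            for t in order[1:]
            if col[t] == col[order[0]]
        ]
        if tied:
            ties[cond] = [order[0], *tied]
    return CarbonCall(ranking=ranking, zscores=zscores, ties=ties, excluded=excluded or [])


def normalized_error(predicted: pd.Series, reference: pd.Series) -> float:
    """Euclidean distance to the reference scaled by the reference magnitude:
    ‖predicted − reference‖₂ / ‖reference‖₂."""
    common = reference.index
    p = predicted.reindex(common).to_numpy(dtype=float)
    r = reference.to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValueError("predicted vector missing reference reactions")
    denom = float(np.linalg.norm(r))
    if denom == 0.0:
        raise ValueError("reference flux vector has zero norm")
    return float(np.linalg.norm(p - r) / denom)


def correlation_eval(
    predicted: pd.DataFrame, reference: pd.DataFrame, by: str = "reaction"
) -> pd.Series:
    """Pearson r between predicted and reference fluxes.

    ``by="reaction"`` correlates each reaction across conditions,
    ``by="condition"`` each condition across reactions.  Pairs with zero
    variance on either side (e.g. reactions predicted zero everywhere) are
    reported as NaN — undefined, not zero.
    """
    if by not in {"reaction", "condition"}:
        raise ValueError("by must be 'reaction' or 'condition'")
    axis_items = reference.index if by == "reaction" else reference.columns
    out = {}
    for item in axis_items:
        if by == "reaction":
            p = predicted.loc[item, reference.columns].to_numpy(dtype=float)
            r = reference.loc[item].to_numpy(dtype=float)
        else:
            p = predicted.loc[reference.index, item].to_numpy(dtype=float)
            r = reference[item].to_numpy(dtype=float)
        if len(r) < 3:
            raise ValueError("Pearson r needs >= 3 paired values")
        if np.std(p) == 0.0 or np.std(r) == 0.0:
            out[item] = np.nan
            continue
        out[item] = float(np.corrcoef(p, r)[0, 1])
    return pd.Series(out, dtype=float)
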