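"""Readers and writers for models, expression matrices, GPR maps and fluxes.

Three model dialects are supported: SBML Level 3 + FBC and BiGG-style JSON
(both delegated to cobrapy) and a plain-TSV toy dialect used throughout the
test fixtures.  The toy dialect is one table with columns

    id  equation  lb  ub  reversible  exchange

where ``equation`` is a reaction string like ``A + 2 B -> C``; an exchange
reaction is written with an empty side (``A ->``), so that negative flux
means uptake and positive flux secretion.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MetabolicNetwork, ValidationError

__all__ = [
    "read_model",
    "write_model_tsv",
    "read_expression",
    "read_gpr",
    "write_fluxes",
    "read_fluxes",
    "FormatError",
]

logger = logging.getLogger(__name__)

_ARROWS = ("<=>", "<->", "-->", "->")


class FormatError(ValueError):
    """A file does not parse under the requested dialect."""


# ---------------------------------------------------------------------------
# toy TSV dialect
# ---------------------------------------------------------------------------

def _parse_side(side: str, rid: str) -> dict[str, float]:
    terms: dict[str, float] = {}
    side = side.strip()
    if not side:
        return terms
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise FormatError(f"reaction {rid!r}: empty term in equation")
        m = re.fullmatch(r"(?:(\d+(?:\.\d+)?)\s+)?(\S+)", term)
        if m is None:
            raise FormatError(f"reaction {rid!r}: cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        terms[met] = terms.get(met, 0.0) + coef
    return terms


def parse_equation(equation: str, rid: str) -> dict[str, float]:
    """Parse ``A + 2 B -> C`` into metabolite -> signed coefficient."""
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise FormatError(f"reaction {rid!r}: no arrow in equation {equation!r}")
    coefs: dict[str, float] = {}
    for met, c in _parse_side(left, rid).items():
        coefs[met] = coefs.get(met, 0.0) - c
    for met, c in _parse_side(right, rid).items():
        coefs[met] = coefs.get(met, 0.0) + c
    return {m: c for m, c in coefs.items() if c != 0.0}


def _read_model_tsv(path: Path, biomass: str | None) -> MetabolicNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"id", "equation", "lb", "ub", "reversible", "exchange"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    reaction_ids: list[str] = []
    columns: list[dict[str, float]] = []
    metabolite_ids: list[str] = []
    seen_mets: set[str] = set()
    lb, ub, rev, exch = [], [], [], []
    for _, row in df.iterrows():
        rid = str(row["id"])
        if rid in reaction_ids:
            raise FormatError(f"{path}: duplicate reaction id {rid!r}")
        coefs = parse_equation(str(row["equation"]), rid)
        if not coefs:
            raise FormatError(f"reaction {rid!r}: equation balances to nothing")
        try:
            lo, hi = float(row["lb"]), float(row["ub"])
        except ValueError as exc:
            raise FormatError(f"reaction {rid!r}: non-numeric bound") from exc
        if lo > hi:
            raise ValidationError(f"reaction {rid!r}: lb {lo} > ub {hi}")
        is_ex = str(row["exchange"]).strip() in {"1", "true", "True"}
        if is_ex and len(coefs) != 1:
            raise FormatError(
                f"exchange reaction {rid!r} must touch exactly one metabolite"
            )
        reaction_ids.append(rid)
        columns.append(coefs)
        lb.append(lo)
        ub.append(hi)
        rev.append(str(row["reversible"]).strip() in {"1", "true", "True"})
        exch.append(is_ex)
        for met in coefs:
            if met not in seen_mets:
                seen_mets.add(met)
                metabolite_ids.append(met)
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    for j, coefs in enumerate(columns):
        for met, c in coefs.items():
            S[met_index[met], j] = c
    return MetabolicNetwork(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        reversible=np.array(rev),
        is_exchange=np.array(exch),
        biomass_reaction_id=biomass,
    )


def write_model_tsv(net: MetabolicNetwork, path: str | Path) -> Path:
    """Serialise a network in the toy TSV dialect (round-trip safe)."""
    path = Path(path)
    rows = []
    for j, rid in enumerate(net.reaction_ids):
        col = net.S[:, j]
        left, right = [], []
        for i in np.flatnonzero(col):
            met = net.metabolite_ids[i]
            c = col[i]
            coef = "" if abs(abs(c) - 1.0) < 1e-12 else f"{abs(c):g} "
            (right if c > 0 else left).append(f"{coef}{met}")
        equation = f"{' + '.join(left)} -> {' + '.join(right)}"
        rows.append(
            {
                "id": rid,
                "equation": equation.strip(),
                "lb": repr(float(net.lb[j])),
                "ub": repr(float(net.ub[j])),
                "reversible": int(net.reversible[j]),
                "exchange": int(net.is_exchange[j]),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# cobrapy-backed dialects
# ---------------------------------------------------------------------------

def _from_cobra(model) -> MetabolicNetwork:
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(model, array_type="dense")
    boundary = {r.id for r in model.boundary}
    biomass = None
    for rxn in model.reactions:
        if rxn.objective_coefficient:
            biomass = rxn.id
            break
    return MetabolicNetwork(
        metabolite_ids=[m.id for m in model.metabolites],
        reaction_ids=[r.id for r in model.reactions],
        S=S,
        lb=np.array([r.lower_bound for r in model.reactions]),
        ub=np.array([r.upper_bound for r in model.reactions]),
        reversible=np.array([r.lower_bound < 0 for r in model.reactions]),
        is_exchange=np.array([r.id in boundary for r in model.reactions]),
        biomass_reaction_id=biomass,
    )


def read_model(
    path: str | Path,
    format: str | None = None,
    biomass: str | None = None,
) -> MetabolicNetwork:
    """Read a metabolic model from SBML, BiGG JSON or the toy TSV dialect.

    ``format`` is one of ``{"sbml", "json", "tsv"}``; when omitted it is
    inferred from the file suffix.  Reaction and metabolite order is the
    file order, so repeated reads are identical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".xml": "sbml", ".sbml": "sbml", ".json": "json", ".tsv": "tsv"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer model format from suffix of {path}")
    if format == "tsv":
        return _read_model_tsv(path, biomass)
    if format == "json":
        from cobra.io import load_json_model

        net = _from_cobra(load_json_model(str(path)))
    elif format == "sbml":
        from cobra.io import read_sbml_model

        net = _from_cobra(read_sbml_model(str(path)))
    else:
        raise FormatError(f"unknown model format {format!r}")
    if biomass is not None:
        net.biomass_reaction_id = biomass
        net.validate()
    return net


# ---------------------------------------------------------------------------
# expression, GPR, fluxes
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    replicate_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Read a genes × conditions log2 expression TSV.

    The first column holds gene symbols.  ``replicate_map`` maps a condition
    label to the replicate column names to average; unmapped columns pass
    through unchanged.  Genes with no finite value in any column are dropped
    with a warning; duplicate gene rows are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row {bad.index[0]!r}: {bad.iloc[0]!r}"
            )
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicate gene rows: {dup}")
    all_missing = df.index[df.isna().all(axis=1)].tolist()
    if all_missing:
        logger.warning("dropping %d genes with no data: %s", len(all_missing), all_missing)
        df = df.drop(index=all_missing)
    if replicate_map:
        collapsed = {}
        used: set[str] = set()
        for cond, cols in replicate_map.items():
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise FormatError(f"replicate columns not in {path}: {missing}")
            collapsed[cond] = df[cols].mean(axis=1)
            used.update(cols)
        for col in df.columns:
            if col not in used:
                collapsed[col] = df[col]
        df = pd.DataFrame(collapsed)
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate condition labels after averaging")
    return df


def read_gpr(
    path: str | Path, net: MetabolicNetwork | None = None
) -> dict[str, list[str]]:
    """Read a reaction → gene-list TSV (genes semicolon-separated).

    Reaction ids missing from ``net`` (when given) are reported in a warning
    but kept, so the caller can decide; empty gene lists are an error.
    """
    path = Path(path)
    gpr: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            rid, genes_str = parts
            genes = [g.strip() for g in genes_str.split(";") if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene list for {rid!r}")
            if rid in gpr:
                raise FormatError(f"{path}:{lineno}: duplicate reaction {rid!r}")
            gpr[rid] = genes
    if net is not None:
        unresolved = [r for r in gpr if r not in net.reaction_ids]
        if unresolved:
            logger.warning("GPR reactions not in network: %s", unresolved)
    return gpr


def write_fluxes(fluxes: pd.DataFrame, path: str | Path) -> Path:
    """Write a reaction × condition flux table at full float precision."""
    if fluxes.empty:
        raise ValueError("refusing to write an empty flux table")
    path = Path(path)
    fluxes.to_csv(path, sep="\t", float_format="%.17g", index_label="reaction")
    return path


def read_fluxes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
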