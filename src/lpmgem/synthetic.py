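"""Toy networks, planted flux states and matching expression matrices.

The generators emulate the statistical structure the fitting method
assumes: expression of a reaction's genes is an affine function of the
planted flux, g = a + b·v + ε with per-reaction coefficients a, b > 0 and
Gaussian noise on the log2 scale.  Planted flux vectors always satisfy
steady state and the network bounds, so every stage of the pipeline can be
exercised against a known ground truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MetabolicNetwork, validate_fluxes

__all__ = [
    "SyntheticScenario",
    "make_path_network",
    "make_loop_network",
    "make_loop_scenario",
    "make_multicarbon_scenario",
    "make_random_network",
    "make_random_fit_case",
    "generate_expression",
]

DEFAULT_NOISE_SD = 0.1
CYCLE_BOUND = 1000.0


@dataclass
class SyntheticScenario:
    """A network plus planted fluxes, generated expression and ground truth."""

    network: MetabolicNetwork
    planted: pd.DataFrame  # reactions × conditions
    expression: pd.DataFrame  # genes × conditions
    gpr: dict[str, list[str]]
    core: list[str]
    transporters: list[str] = field(default_factory=list)
    truth: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    noise_sd: float = DEFAULT_NOISE_SD


def make_path_network(
    n_steps: int = 3,
    uptake_bound: float = 10.0,
    biomass: bool = True,
) -> MetabolicNetwork:
    """Linear chain EX_in → M1 → … → Mn → EX_out, irreversible.

    ``n_steps`` is the number of chain metabolites; with the biomass sink on
    the last metabolite (default) the network has ``n_steps + 2`` reactions.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    mets = [f"M{i}" for i in range(1, n_steps + 1)]
    reaction_ids = ["EX_in"]
    cols: list[dict[str, float]] = [{"M1": -1.0}]
    lb, ub, rev, exch = [-uptake_bound], [0.0], [False], [True]
    for i in range(1, n_steps):
        reaction_ids.append(f"R{i}")
        cols.append({f"M{i}": -1.0, f"M{i + 1}": 1.0})
        lb.append(0.0)
        ub.append(uptake_bound)
        rev.append(False)
        exch.append(False)
    reaction_ids.append("EX_out")
    cols.append({mets[-1]: -1.0})
    lb.append(0.0)
    ub.append(CYCLE_BOUND)
    rev.append(False)
    exch.append(True)
    if biomass:
        reaction_ids.append("BIOMASS")
        cols.append({mets[-1]: -1.0})
        lb.append(0.0)
        ub.append(uptake_bound)
        rev.append(False)
        exch.append(True)
    S = np.zeros((len(mets), len(reaction_ids)))
    idx = {m: i for i, m in enumerate(mets)}
    for j, col in enumerate(cols):
        for met, c in col.items():
            S[idx[met], j] = c
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=reaction_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        reversible=np.array(rev),
        is_exchange=np.array(exch),
        biomass_reaction_id="BIOMASS" if biomass else None,
    )


def make_loop_network(
    cycle_len: int = 3,
    attach_to_path: bool = True,
    cycle_bound: float = CYCLE_BOUND,
    path_steps: int = 3,
    uptake_bound: float = 10.0,
) -> MetabolicNetwork:
    """An internal directed cycle, optionally grafted onto a path network.

    The cycle is a thermodynamically infeasible loop by construction: its
    reactions exchange nothing with the boundary, so any nonzero net flux
    around it violates the loop law.  In the attached variant the cycle
    shares the metabolite M2 with the path and its members are reversible
    with bounds ±``cycle_bound``, which inflates their FVA ranges to the
    full ±bound — the fixture motivating iterative bound reduction.
    """
    if cycle_len < 2:
        raise ValueError("a cycle needs at least 2 reactions")
    if attach_to_path:
        base = make_path_network(path_steps, uptake_bound)
        mets = list(base.metabolite_ids)
        reaction_ids = list(base.reaction_ids)
        cols = [
            {mets[i]: base.S[i, j] for i in np.flatnonzero(base.S[:, j])}
            for j in range(base.n_reactions)
        ]
        lb, ub = list(base.lb), list(base.ub)
        rev, exch = list(base.reversible), list(base.is_exchange)
        anchor = "M2"
        biomass = base.biomass_reaction_id
    else:
        mets, reaction_ids, cols, lb, ub, rev, exch = [], [], [], [], [], [], []
        anchor = "X0"
        mets.append(anchor)
        biomass = None
    cycle_nodes = [anchor] + [f"X{i}" for i in range(1, cycle_len)]
    mets.extend(cycle_nodes[1:])
    for i in range(cycle_len):
        src = cycle_nodes[i]
        dst = cycle_nodes[(i + 1) % cycle_len]
        reaction_ids.append(f"C{i + 1}")
        cols.append({src: -1.0, dst: 1.0})
        lb.append(-cycle_bound if attach_to_path else 0.0)
        ub.append(cycle_bound)
        rev.append(attach_to_path)
        exch.append(False)
    S = np.zeros((len(mets), len(reaction_ids)))
    idx = {m: i for i, m in enumerate(mets)}
    for j, col in enumerate(cols):
        for met, c in col.items():
            S[idx[met], j] = c
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=reaction_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        reversible=np.array(rev),
        is_exchange=np.array(exch),
        biomass_reaction_id=biomass,
    )


def generate_expression(
    planted: pd.DataFrame,
    gpr: dict[str, list[str]],
    rng: np.random.Generator,
    noise_sd: float = DEFAULT_NOISE_SD,
    intercept_range: tuple[float, float] = (5.0, 7.0),
    slope_range: tuple[float, float] = (0.4, 0.8),
) -> pd.DataFrame:
    """Generate log2 expression as an affine image of the planted fluxes.

    Each reaction draws one intercept a and slope b (shared by its genes);
    each gene then gets g = a + b·v + ε with ε ~ Normal(0, noise_sd) drawn
    independently per gene and condition.
    """
    rows = {}
    for rid in planted.index:
        a = rng.uniform(*intercept_range)
        b = rng.uniform(*slope_range)
        for gene in gpr[rid]:
            noise = rng.normal(0.0, noise_sd, size=planted.shape[1]) if noise_sd > 0 else 0.0
            rows[gene] = a + b * planted.loc[rid].to_numpy(dtype=float) + noise
    return pd.DataFrame(rows, index=planted.columns).T


def make_loop_scenario(
    seed: int = 0,
    n_conditions: int = 8,
    noise_sd: float = DEFAULT_NOISE_SD,
    cycle_len: int = 3,
) -> SyntheticScenario:
    """Path-plus-cycle scenario with planted loop-free fluxes.

    The path carries a different flux level per condition while the cycle
    carries none, so the fitted reactions include loop members whose FVA
    ranges are wildly inflated relative to their true (zero) flux — the
    condition under which bound reduction and loop removal earn their keep.
    """
    rng = np.random.default_rng(seed)
    net = make_loop_network(cycle_len=cycle_len, attach_to_path=True)
    conditions = [f"cond{i + 1}" for i in range(n_conditions)]
    levels = np.linspace(2.0, 8.0, n_conditions)
    planted = pd.DataFrame(0.0, index=net.reaction_ids, columns=conditions)
    for cond, level in zip(conditions, levels):
        planted.loc["EX_in", cond] = -level
        planted.loc["R1", cond] = level
        planted.loc["R2", cond] = level
        planted.loc["EX_out", cond] = level
    validate_fluxes(net, planted)
    core = ["R1", "R2"] + [f"C{i + 1}" for i in range(cycle_len)]
    gpr = {rid: [f"g_{rid}_1", f"g_{rid}_2"] for rid in core}
    expression = generate_expression(planted.loc[core], gpr, rng, noise_sd)
    return SyntheticScenario(
        network=net,
        planted=planted,
        expression=expression,
        gpr=gpr,
        core=core,
        seed=seed,
        noise_sd=noise_sd,
    )


def make_random_network(
    seed: int,
    n_extra_edges: tuple[int, int] = (3, 8),
    n_metabolites: tuple[int, int] = (4, 9),
) -> MetabolicNetwork:
    """A random small unimolecular network with a flux-carrying backbone.

    A linear uptake→chain→secretion backbone guarantees nonzero feasible
    flux; random extra internal conversions (half of them reversible) create
    shortcuts and cycles.  All coefficients are unit, which keeps exhaustive
    cycle enumeration an exact loop oracle on these networks.
    """
    rng = np.random.default_rng(seed)
    m = int(rng.integers(*n_metabolites))
    mets = [f"M{i + 1}" for i in range(m)]
    reaction_ids = ["EX_in"]
    cols: list[dict[str, float]] = [{"M1": -1.0}]
    lb, ub, rev, exch = [-10.0], [0.0], [False], [True]
    for i in range(m - 1):
        reaction_ids.append(f"R{i + 1}")
        cols.append({f"M{i + 1}": -1.0, f"M{i + 2}": 1.0})
        lb.append(0.0)
        ub.append(10.0)
        rev.append(False)
        exch.append(False)
    reaction_ids.append("EX_out")
    cols.append({mets[-1]: -1.0})
    lb.append(0.0)
    ub.append(1000.0)
    rev.append(False)
    exch.append(True)
    n_extra = int(rng.integers(*n_extra_edges))
    for e in range(n_extra):
        i, j = rng.choice(m, size=2, replace=False)
        reversible = bool(rng.random() < 0.5)
        reaction_ids.append(f"E{e + 1}")
        cols.append({mets[i]: -1.0, mets[j]: 1.0})
        lb.append(-10.0 if reversible else 0.0)
        ub.append(10.0)
        rev.append(reversible)
        exch.append(False)
    S = np.zeros((m, len(reaction_ids)))
    idx = {met: i for i, met in enumerate(mets)}
    for j, col in enumerate(cols):
        for met, c in col.items():
            S[idx[met], j] = c
    return MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=reaction_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        reversible=np.array(rev),
        is_exchange=np.array(exch),
    )


def make_multicarbon_scenario(
    n_conditions: int = 8,
    n_transporters: int = 8,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    major_uptake: float = 8.0,
    background_uptake: float = 0.5,
    uptake_bound: float = 10.0,
) -> SyntheticScenario:
    """Multi-carbon-source design: one designated substrate per condition.

    ``n_transporters`` carbon sources C_i each enter through an exchange
    EX_C_i and an internal transporter step T_i into a common sink
    metabolite.  In condition j the designated transporter carries
    ``major_uptake`` and all others ``background_uptake``; all uptake
    bounds are opened identically in every condition, so nothing about the
    true source leaks into the constraints.  Expression follows the affine
    rule on the transporter fluxes.
    """
    if n_conditions < 2:
        raise ValueError("z-score based calling needs >= 2 conditions")
    if n_transporters < n_conditions:
        raise ValueError("need at least one designated transporter per condition")
    rng = np.random.default_rng(seed)
    mets = [f"C{i + 1}" for i in range(n_transporters)] + ["P"]
    reaction_ids, cols, lb, ub, rev, exch = [], [], [], [], [], []
    for i in range(n_transporters):
        reaction_ids.append(f"EX_C{i + 1}")
        cols.append({f"C{i + 1}": -1.0})
        lb.append(-uptake_bound)
        ub.append(0.0)
        rev.append(True)
        exch.append(True)
        reaction_ids.append(f"T{i + 1}")
        cols.append({f"C{i + 1}": -1.0, "P": 1.0})
        lb.append(0.0)
        ub.append(uptake_bound)
        rev.append(False)
        exch.append(False)
    reaction_ids.append("EX_P")
    cols.append({"P": -1.0})
    lb.append(0.0)
    ub.append(CYCLE_BOUND)
    rev.append(False)
    exch.append(True)
    S = np.zeros((len(mets), len(reaction_ids)))
    idx = {m: i for i, m in enumerate(mets)}
    for j, col in enumerate(cols):
        for met, c in col.items():
            S[idx[met], j] = c
    net = MetabolicNetwork(
        metabolite_ids=mets,
        reaction_ids=reaction_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        reversible=np.array(rev),
        is_exchange=np.array(exch),
    )
    conditions = [f"cond{i + 1}" for i in range(n_conditions)]
    transporters = [f"EX_C{i + 1}" for i in range(n_transporters)]
    truth = {cond: transporters[i] for i, cond in enumerate(conditions)}
    planted = pd.DataFrame(0.0, index=net.reaction_ids, columns=conditions)
    for j, cond in enumerate(conditions):
        for i in range(n_transporters):
            v = major_uptake if i == j else background_uptake
            planted.loc[f"T{i + 1}", cond] = v
            planted.loc[f"EX_C{i + 1}", cond] = -v
        planted.loc["EX_P", cond] = planted.loc[[f"T{i + 1}" for i in range(n_transporters)], cond].sum()
    validate_fluxes(net, planted)
    core = [f"T{i + 1}" for i in range(n_transporters)]
    gpr = {rid: [f"g_{rid}_1", f"g_{rid}_2"] for rid in core}
    expression = generate_expression(planted.loc[core], gpr, rng, noise_sd)
    return SyntheticScenario(
        network=net,
        planted=planted,
        expression=expression,
        gpr=gpr,
        core=core,
        transporters=transporters,
        truth=truth,
        seed=seed,
        noise_sd=noise_sd,
    )


def make_random_fit_case(
    seed: int,
    n_conditions: int = 2,
    alpha: float = 0.01,
    n_core: int = 4,
):
    """Random network plus random in-range fit targets, ready to solve.

    Core reactions are drawn from the internal reactions and their targets
    sampled uniformly within the FVA range, so targets frequently pull flux
    through the random shortcut edges and provoke loop-carrying optima —
    the regime the loop-removal machinery must handle.  Returns
    (network, targets, partition, config).
    """
    from .core import run_fva
    from .fit import FitConfig, FitTargets, ReactionPartition, compute_weights

    rng = np.random.default_rng(seed)
    net = make_random_network(seed)
    internal = net.internal_ids
    core = sorted(
        rng.choice(internal, size=min(n_core, len(internal)), replace=False).tolist()
    )
    fva = run_fva(net, core)
    partition = ReactionPartition.from_sets(net, core, [], fva)
    conditions = [f"cond{i + 1}" for i in range(n_conditions)]
    lo = fva.loc[partition.fitted, "min"].to_numpy()
    hi = fva.loc[partition.fitted, "max"].to_numpy()
    vfit = pd.DataFrame(
        lo[:, None] + rng.random((len(partition.fitted), n_conditions)) * (hi - lo)[:, None],
        index=partition.fitted,
        columns=conditions,
    )
    targets = FitTargets(
        vfit=vfit, vmin=fva.loc[partition.fitted, "min"], vmax=fva.loc[partition.fitted, "max"]
    )
    config = FitConfig(alpha=alpha, weights=compute_weights(fva, partition))
    return net, targets, partition, config
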