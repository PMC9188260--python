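"""Thin deterministic LP/MILP layer on top of scipy's HiGHS interface.

Every optimisation in the package goes through :class:`LinearProblem`, so a
different backend only needs to reimplement ``solve``.  HiGHS is run
single-threaded with fixed tolerances, which makes repeated solves of the
same problem bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["LinearProblem", "SolveResult", "SolverError"]

#: HiGHS status codes -> package-level status strings
_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded", 4: "error"}

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9


class SolverError(RuntimeError):
    """Raised when the backend fails in a way that is not a status."""


@dataclass
class SolveResult:
    status: str
    objective: float | None
    values: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, name: str) -> float:
        return self.values[name]


class LinearProblem:
    """Incrementally built linear (mixed-integer) program.

    Variables are referenced by name; constraints are ranged rows
    ``lo <= a.x <= hi``.  The objective sense is always minimisation —
    callers maximising flip signs themselves.
    """

    def __init__(self, name: str = "") -> None:
        self.name = name
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        self._rows: list[tuple[dict[int, float], float, float]] = []
        self._objective: dict[int, float] = {}

    # -- construction -------------------------------------------------
    @property
    def variable_names(self) -> list[str]:
        return list(self._index)

    def add_variable(
        self,
        name: str,
        lb: float = -np.inf,
        ub: float = np.inf,
        *,
        integer: bool = False,
    ) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        if lb > ub:
            raise ValueError(f"variable {name!r}: lb {lb} > ub {ub}")
        idx = len(self._lb)
        self._index[name] = idx
        self._lb.append(float(lb))
        self._ub.append(float(ub))
        self._integer.append(bool(integer))
        return idx

    def add_constraint(
        self,
        coefs: Mapping[str, float],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> None:
        row = {self._index[n]: float(c) for n, c in coefs.items() if c != 0.0}
        self._rows.append((row, float(lb), float(ub)))

    def add_objective_term(self, name: str, coef: float) -> None:
        idx = self._index[name]
        self._objective[idx] = self._objective.get(idx, 0.0) + float(coef)

    def set_objective(self, coefs: Mapping[str, float]) -> None:
        self._objective = {self._index[n]: float(c) for n, c in coefs.items()}

    # -- solving ------------------------------------------------------
    def solve(self) -> SolveResult:
        n = len(self._lb)
        if n == 0:
            return SolveResult("optimal", 0.0, {})
        c = np.zeros(n)
        for idx, coef in self._objective.items():
            c[idx] = coef

        constraints = []
        if self._rows:
            data, ri, ci = [], [], []
            lo = np.empty(len(self._rows))
            hi = np.empty(len(self._rows))
            for i, (row, rlo, rhi) in enumerate(self._rows):
                lo[i], hi[i] = rlo, rhi
                for j, coef in row.items():
                    ri.append(i)
                    ci.append(j)
                    data.append(coef)
            A = sp.csr_matrix((data, (ri, ci)), shape=(len(self._rows), n))
            constraints = [LinearConstraint(A, lo, hi)]

        integrality = np.array(self._integer, dtype=np.uint8)
        with warnings.catch_warnings():
            # scipy forwards the HiGHS tolerance options verbatim but warns
            warnings.filterwarnings("ignore", message="Unrecognized options")
            res = milp(
                c,
                constraints=constraints,
                integrality=integrality,
                bounds=Bounds(np.array(self._lb), np.array(self._ub)),
                options={
                    "presolve": True,
                    "mip_rel_gap": 0.0,
                    "primal_feasibility_tolerance": FEASIBILITY_TOL,
                    "dual_feasibility_tolerance": OPTIMALITY_TOL,
                },
            )
        status = _STATUS.get(res.status, "error")
        if status == "optimal" and res.x is None:  # pragma: no cover
            raise SolverError(f"HiGHS reported success without a solution: {res.message}")
        values: dict[str, float] = {}
        if res.x is not None:
            values = {name: float(res.x[idx]) for name, idx in self._index.items()}
        objective = float(res.fun) if res.fun is not None else None
        return SolveResult(status, objective, values)
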