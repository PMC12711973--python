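"""Minimal incremental builder over scipy.optimize.milp (HiGHS backend)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp


@dataclass
class MilpResult:
    status: str  # "optimal" | "feasible" | "infeasible" | "no_solution"
    x: np.ndarray | None
    objective: float | None
    gap: float | None


class Model:
    """A mixed-integer linear program assembled row by row.

    Objective sense is minimization; an additive constant may be carried so
    reported objectives match the modeled quantity.
    """

    def __init__(self) -> None:
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        self._obj: dict[int, float] = {}
        self._rows: list[dict[int, float]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []
        self.obj_constant: float = 0.0

    @property
    def n_vars(self) -> int:
        return len(self._lb)

    @property
    def n_constraints(self) -> int:
        return len(self._rows)

    def add_var(
        self, lb: float = 0.0, ub: float = np.inf, integer: bool = False
    ) -> int:
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(integer)
        return len(self._lb) - 1

    def add_binary(self) -> int:
        return self.add_var(0.0, 1.0, integer=True)

    def set_objective(self, var: int, coeff: float) -> None:
        self._obj[var] = self._obj.get(var, 0.0) + coeff

    def add_constraint(
        self,
        coeffs: dict[int, float],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> None:
        self._rows.append(coeffs)
        self._row_lb.append(lb)
        self._row_ub.append(ub)

    def solve(
        self,
        time_limit: float | None = None,
        mip_gap: float = 1e-9,
    ) -> MilpResult:
        n = self.n_vars
        c = np.zeros(n)
        for j, v in self._obj.items():
            c[j] = v
        data, rows, cols = [], [], []
        for r, row in enumerate(self._rows):
            for j, v in row.items():
                rows.append(r)
                cols.append(j)
                data.append(v)
        constraints = []
        if self._rows:
            A = sp.csr_matrix(
                (data, (rows, cols)), shape=(len(self._rows), n)
            )
            constraints = [
                LinearConstraint(A, np.array(self._row_lb), np.array(self._row_ub))
            ]
        options: dict = {"mip_rel_gap": mip_gap}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c,
            constraints=constraints,
            integrality=np.array(self._integer, dtype=np.int64),
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            options=options,
        )
        if res.status == 0:
            status = "optimal"
        elif res.status == 1 and res.x is not None:
            status = "feasible"
        elif res.status == 2:
            status = "infeasible"
        else:
            status = "no_solution"
        x = np.asarray(res.x) if res.x is not None else None
        obj = (
            float(res.fun) + self.obj_constant if res.fun is not None else None
        )
        gap = float(res.mip_gap) if getattr(res, "mip_gap", None) is not None else None
        return MilpResult(status=status, x=x, objective=obj, gap=gap)
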