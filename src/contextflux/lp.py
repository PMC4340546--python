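"""Thin LP/MILP layer over scipy's HiGHS interface.

All optimisation in this package goes through :class:`LinearModel`: mass
balance, iMAT indicator constraints, L1 deviation fitting, FVA and capacity
maximisation.  Variables are referenced by name; the model is rebuilt into a
sparse ``scipy.optimize.milp`` problem at each solve, which for the problem
sizes this package targets (toy networks, a few hundred variables) is cheap
and keeps the solves stateless and deterministic.
"""

from __future__ import annotations

import contextlib
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp


@contextlib.contextmanager
def _silence_solver_stdout():
    """HiGHS emits stray C-level diagnostics on some MILP solves; results go
    to files/stderr only, so file descriptor 1 is parked during the solve."""
    try:
        fd = os.dup(1)
    except (OSError, ValueError):  # no usable stdout fd; nothing to silence
        yield
        return
    try:
        with open(os.devnull, "w") as devnull:
            os.dup2(devnull.fileno(), 1)
            yield
    finally:
        try:  # flush C-level stdio before the real fd comes back
            import ctypes

            ctypes.CDLL(None).fflush(None)
        except Exception:
            pass
        os.dup2(fd, 1)
        os.close(fd)


class SolverError(RuntimeError):
    """The solver terminated abnormally (not plain infeasibility)."""


class InfeasibleError(SolverError):
    """The constraint system admits no solution."""


#: termination labels used throughout the package
OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


@dataclass
class Solution:
    status: str
    objective: float | None
    values: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


class LinearModel:
    """A mixed-integer linear program built incrementally by name.

    Constraints are two-sided: ``lb <= sum(coef * var) <= ub``.  Binary
    variables are declared with ``binary=True``; everything else is
    continuous.
    """

    def __init__(self) -> None:
        self._names: list[str] = []
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        self._rows: list[dict[int, float]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []

    # -- construction -------------------------------------------------
    def add_var(
        self,
        name: str,
        lb: float = -np.inf,
        ub: float = np.inf,
        binary: bool = False,
    ) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        self._index[name] = len(self._names)
        self._names.append(name)
        if binary:
            lb, ub = max(lb, 0.0), min(ub, 1.0)
        self._lb.append(float(lb))
        self._ub.append(float(ub))
        self._integer.append(binary)
        return name

    def has_var(self, name: str) -> bool:
        return name in self._index

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._index[name]
        self._lb[i] = float(lb)
        self._ub[i] = float(ub)

    def get_bounds(self, name: str) -> tuple[float, float]:
        i = self._index[name]
        return self._lb[i], self._ub[i]

    def add_constr(
        self,
        coefs: dict[str, float],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> int:
        row = {self._index[v]: float(c) for v, c in coefs.items() if c != 0.0}
        self._rows.append(row)
        self._row_lb.append(float(lb))
        self._row_ub.append(float(ub))
        return len(self._rows) - 1

    # -- solving ------------------------------------------------------
    def solve(self, objective: dict[str, float], sense: str = "min") -> Solution:
        """Optimise ``objective`` (a sparse name->coefficient map)."""
        if sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        n = len(self._names)
        c = np.zeros(n)
        for v, coef in objective.items():
            c[self._index[v]] = coef
        if sense == "max":
            c = -c

        constraints = []
        if self._rows:
            data, ri, ci = [], [], []
            for r, row in enumerate(self._rows):
                for j, coef in row.items():
                    ri.append(r)
                    ci.append(j)
                    data.append(coef)
            a = sparse.csr_matrix(
                (data, (ri, ci)), shape=(len(self._rows), n)
            )
            constraints.append(
                LinearConstraint(a, np.array(self._row_lb), np.array(self._row_ub))
            )

        from scipy.optimize import Bounds

        with _silence_solver_stdout():
            res = milp(
                c=c,
                constraints=constraints,
                integrality=np.array(self._integer, dtype=int),
                bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            )
        # scipy/HiGHS status codes: 0 optimal, 1 iteration/time limit,
        # 2 infeasible, 3 unbounded, 4 other
        if res.status == 0:
            obj = float(res.fun) if sense == "min" else -float(res.fun)
            values = {name: float(res.x[i]) for i, name in enumerate(self._names)}
            return Solution(OPTIMAL, obj, values)
        if res.status == 2:
            return Solution(INFEASIBLE, None)
        if res.status == 3:
            return Solution(UNBOUNDED, None)
        raise SolverError(f"solver failure: status={res.status} ({res.message})")

    def solve_or_raise(
        self, objective: dict[str, float], sense: str = "min"
    ) -> Solution:
        sol = self.solve(objective, sense)
        if sol.status == INFEASIBLE:
            raise InfeasibleError("constraint system is infeasible")
        if sol.status == UNBOUNDED:
            raise SolverError("objective is unbounded over the feasible space")
        return sol
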