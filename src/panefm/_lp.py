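"""Thin wrapper around GLPK (via swiglpk) for repeated small LP solves.

A single problem instance is kept alive per network; reaction deletions and
environment changes are applied as column-bound updates so the simplex can
warm-start from the previous basis.  Objective values are basis-independent,
so warm starts are safe for feasibility/growth queries; callers that need a
*flux vector* must request a deterministic solve, which resets the basis
first so the reported optimal vertex does not depend on solve history.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import swiglpk as glp

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {
    glp.GLP_OPT: OPTIMAL,
    glp.GLP_NOFEAS: INFEASIBLE,
    glp.GLP_INFEAS: INFEASIBLE,
    glp.GLP_UNBND: UNBOUNDED,
}


class LinearProgram:
    """``max c'v  s.t.  S v = 0,  lb <= v <= ub`` with mutable column bounds."""

    def __init__(
        self,
        n_rows: int,
        col_ids: Sequence[str],
        entries: Sequence[Tuple[int, int, float]],
        bounds: Sequence[Tuple[float, float]],
    ) -> None:
        self.col_ids = list(col_ids)
        self.col_index: Dict[str, int] = {c: j for j, c in enumerate(self.col_ids)}
        n_cols = len(self.col_ids)
        self._lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(self._lp, glp.GLP_MAX)
        if n_rows:
            glp.glp_add_rows(self._lp, n_rows)
            for i in range(1, n_rows + 1):
                glp.glp_set_row_bnds(self._lp, i, glp.GLP_FX, 0.0, 0.0)
        glp.glp_add_cols(self._lp, n_cols)
        self._bounds: List[Tuple[float, float]] = [(0.0, 0.0)] * n_cols
        for j, (lb, ub) in enumerate(bounds):
            self.set_bounds(j, lb, ub)
        ne = len(entries)
        ia = glp.intArray(ne + 1)
        ja = glp.intArray(ne + 1)
        ar = glp.doubleArray(ne + 1)
        for k, (i, j, v) in enumerate(entries, start=1):
            ia[k] = i + 1
            ja[k] = j + 1
            ar[k] = float(v)
        glp.glp_load_matrix(self._lp, ne, ia, ja, ar)
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF
        self._obj_col = 0

    def __del__(self) -> None:  # pragma: no cover - gc hook
        try:
            glp.glp_delete_prob(self._lp)
        except Exception:
            pass

    def set_bounds(self, j: int, lb: float, ub: float) -> None:
        if lb > ub:
            raise ValueError(f"column {self.col_ids[j]}: lb {lb} > ub {ub}")
        if math.isinf(lb) and math.isinf(ub):
            kind = glp.GLP_FR
        elif math.isinf(ub):
            kind = glp.GLP_LO
        elif math.isinf(lb):
            kind = glp.GLP_UP
        elif lb == ub:
            kind = glp.GLP_FX
        else:
            kind = glp.GLP_DB
        glp.glp_set_col_bnds(
            self._lp,
            j + 1,
            kind,
            0.0 if math.isinf(lb) else lb,
            0.0 if math.isinf(ub) else ub,
        )
        self._bounds[j] = (lb, ub)

    def get_bounds(self, j: int) -> Tuple[float, float]:
        return self._bounds[j]

    def set_objective(self, j: int, maximize: bool = True) -> None:
        glp.glp_set_obj_coef(self._lp, self._obj_col + 1, 0.0)
        glp.glp_set_obj_coef(self._lp, j + 1, 1.0 if maximize else -1.0)
        self._obj_col = j

    def solve(self, fresh_basis: bool = False) -> Tuple[str, float]:
        """Return (status, objective value of the *set* objective column)."""
        if fresh_basis:
            glp.glp_std_basis(self._lp)
        ret = glp.glp_simplex(self._lp, self._parm)
        if ret != 0:
            # numerical trouble with the warm basis: retry from scratch
            glp.glp_std_basis(self._lp)
            ret = glp.glp_simplex(self._lp, self._parm)
            if ret != 0:
                raise RuntimeError(f"GLPK simplex failed with code {ret}")
        status = _STATUS.get(glp.glp_get_status(self._lp), INFEASIBLE)
        value = glp.glp_get_col_prim(self._lp, self._obj_col + 1)
        return status, value

    def column_values(self) -> List[float]:
        return [
            glp.glp_get_col_prim(self._lp, j + 1) for j in range(len(self.col_ids))
        ]
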