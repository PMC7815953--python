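"""Exact rational linear programming by phase-1/phase-2 simplex.

This is the feasibility workhorse behind redundancy tests, reaction
feasibility, steady-state realizability and conformal decomposition.  Bland's
rule guarantees termination; every pivot is carried out in Fraction
arithmetic, so feasibility answers and witnesses are exact.  Problem sizes in
this package are tiny (tens of variables), so a dense tableau is fine.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence

from ._rational import ZERO, Vec, frac

_ONE = Fraction(1)


def _pivot(T: list[list[Fraction]], basis: list[int], row: int, col: int) -> None:
    pv = T[row][col]
    T[row] = [x / pv for x in T[row]]
    for i, r in enumerate(T):
        if i != row and r[col] != 0:
            f = r[col]
            T[i] = [x - f * y for x, y in zip(r, T[row])]
    basis[row] = col


def _simplex_min(T: list[list[Fraction]], basis: list[int], ncols: int) -> None:
    """Minimize the objective in the last tableau row, Bland's rule."""
    while True:
        obj = T[-1]
        col = next((j for j in range(ncols) if obj[j] < 0), None)
        if col is None:
            return
        best_row = None
        best_ratio = None
        for i in range(len(T) - 1):
            if T[i][col] > 0:
                ratio = T[i][-1] / T[i][col]
                if (
                    best_ratio is None
                    or ratio < best_ratio
                    or (ratio == best_ratio and basis[i] < basis[best_row])
                ):
                    best_ratio = ratio
                    best_row = i
        if best_row is None:
            raise ArithmeticError("unbounded LP")
        _pivot(T, basis, best_row, col)


def solve_nonneg(
    A_eq: Sequence[Sequence[Fraction]],
    b_eq: Sequence[Fraction],
    n: int,
    objective: Optional[Sequence[Fraction]] = None,
) -> Optional[list[Fraction]]:
    """Solve min c.x s.t. A_eq x = b_eq, x >= 0, exactly.

    Returns an optimal (or, with objective=None, any feasible) x, or None if
    infeasible.  Raises ArithmeticError if the objective is unbounded below.
    """
    m = len(A_eq)
    # phase 1: artificial variable per row, rows flipped so b >= 0
    T: list[list[Fraction]] = []
    for i in range(m):
        row = [frac(x) for x in A_eq[i]]
        b = frac(b_eq[i])
        if b < 0:
            row = [-x for x in row]
            b = -b
        T.append(row + [ZERO] * m + [b])
    for i in range(m):
        T[i][n + i] = _ONE
    basis = [n + i for i in range(m)]
    # objective: sum of artificials, expressed over nonbasic columns
    obj = [ZERO] * (n + m) + [ZERO]
    for i in range(m):
        obj = [o - t for o, t in zip(obj, T[i])]
    for i in range(m):
        obj[n + i] = ZERO
    T.append(obj)
    _simplex_min(T, basis, n + m)
    if T[-1][-1] != 0:  # min sum of artificials is -T[-1][-1]
        return None
    # drive remaining artificial variables out of the basis where possible
    for i in range(m):
        if basis[i] >= n:
            col = next((j for j in range(n) if T[i][j] != 0), None)
            if col is not None:
                _pivot(T, basis, i, col)
    T.pop()  # drop phase-1 objective
    if objective is not None:
        c = [frac(x) for x in objective] + [ZERO] * m + [ZERO]
        # express objective over current basis
        for i in range(m):
            if basis[i] < n and c[basis[i]] != 0:
                f = c[basis[i]]
                c = [x - f * y for x, y in zip(c, T[i])]
        for i in range(m):
            c[n + i] = ZERO  # artificials stay at zero
        T.append(c)
        _simplex_min(T, basis, n)
        T.pop()
    x = [ZERO] * n
    for i in range(m):
        if basis[i] < n:
            x[basis[i]] = T[i][-1]
    return x


def feasible_nonneg_combination(
    columns: Sequence[Vec], target: Sequence[Fraction]
) -> Optional[list[Fraction]]:
    """Weights lam >= 0 with sum_k lam_k columns[k] == target, or None.

    The zero target is trivially feasible (lam = 0); an empty column set can
    only produce the zero target.
    """
    tgt = [frac(x) for x in target]
    if not columns:
        return [] if all(x == 0 for x in tgt) else None
    dim = len(tgt)
    A = [[columns[k][i] for k in range(len(columns))] for i in range(dim)]
    return solve_nonneg(A, tgt, len(columns))
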