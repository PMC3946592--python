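"""Exact rational linear algebra over ``fractions.Fraction``.

Small dense routines (Gauss-Jordan) used by the elementarity test and by
yield/steady-state checks.  Everything is exact: no floating point enters
any steady-state or rank decision in this package.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

Matrix = list[list[Fraction]]


def _as_fraction_matrix(rows: Sequence[Sequence]) -> Matrix:
    return [[Fraction(x) for x in row] for row in rows]


def rref(rows: Sequence[Sequence]) -> tuple[Matrix, list[int]]:
    """Reduced row-echelon form and pivot column indices."""
    m = _as_fraction_matrix(rows)
    if not m:
        return m, []
    n_rows, n_cols = len(m), len(m[0])
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        if r >= n_rows:
            break
        pivot_row = next((i for i in range(r, n_rows) if m[i][c] != 0), None)
        if pivot_row is None:
            continue
        m[r], m[pivot_row] = m[pivot_row], m[r]
        inv = m[r][c]
        m[r] = [x / inv for x in m[r]]
        for i in range(n_rows):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
    return m, pivots


def rank(rows: Sequence[Sequence]) -> int:
    return len(rref(rows)[1])


def nullspace(rows: Sequence[Sequence], n_cols: int | None = None) -> list[list[Fraction]]:
    """Basis of the (right) nullspace.

    ``n_cols`` must be given for an empty matrix (no rows), in which case
    the basis is the standard one.
    """
    if not rows:
        if n_cols is None:
            raise ValueError("n_cols required for an empty matrix")
        basis = []
        for j in range(n_cols):
            v = [Fraction(0)] * n_cols
            v[j] = Fraction(1)
            basis.append(v)
        return basis
    n_cols = len(rows[0])
    red, pivots = rref(rows)
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n_cols
        v[fc] = Fraction(1)
        for r, pc in enumerate(pivots):
            v[pc] = -red[r][fc]
        basis.append(v)
    return basis


def matvec(rows: Sequence[Sequence], v: Sequence) -> list[Fraction]:
    return [sum((Fraction(a) * Fraction(x) for a, x in zip(row, v)), Fraction(0)) for row in rows]
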