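"""Exact rational vector/matrix helpers.

All enumeration code works over ``fractions.Fraction``; floating point never
enters a stoichiometric coefficient or a generator.  Vectors are plain tuples
of Fractions, matrices are tuples of such tuples (rows).
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

Vec = tuple[Fraction, ...]

ZERO = Fraction(0)


def frac(x) -> Fraction:
    """Parse a value into an exact Fraction.

    Strings are parsed decimally ("0.1" -> 1/10, "-1/3" -> -1/3); floats are
    converted via their shortest decimal repr, so an SBML double written as
    0.1 becomes exactly 1/10 rather than its binary expansion.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        if x != x or x in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite coefficient: {x}")
        return Fraction(repr(x))
    if isinstance(x, str):
        return Fraction(x.strip())
    raise TypeError(f"cannot convert {type(x).__name__} to Fraction")


def vec(values: Iterable) -> Vec:
    return tuple(frac(v) for v in values)


def is_zero(v: Sequence[Fraction]) -> bool:
    return all(x == 0 for x in v)


def dot(a: Sequence[Fraction], b: Sequence[Fraction]) -> Fraction:
    return sum((x * y for x, y in zip(a, b, strict=True)), ZERO)


def add(a: Sequence[Fraction], b: Sequence[Fraction]) -> Vec:
    return tuple(x + y for x, y in zip(a, b, strict=True))


def scale(a: Sequence[Fraction], s: Fraction) -> Vec:
    return tuple(x * s for x in a)


def combine(alpha: Fraction, a: Sequence[Fraction], beta: Fraction, b: Sequence[Fraction]) -> Vec:
    return tuple(alpha * x + beta * y for x, y in zip(a, b, strict=True))


def normalize_ray(v: Sequence[Fraction]) -> Vec:
    """Scale to coprime integer entries, preserving direction.

    The canonical representative of the ray {s*v : s > 0}: entries are
    integers with gcd 1.  The zero vector maps to itself.
    """
    denoms = [x.denominator for x in v]
    nums = [x.numerator for x in v]
    g = 0
    for n in nums:
        g = gcd(g, abs(n))
    if g == 0:
        return tuple(ZERO for _ in v)
    lcm = 1
    for d in denoms:
        lcm = lcm * d // gcd(lcm, d)
    s = Fraction(lcm, g)
    return tuple(x * s for x in v)


def unique_rays(vectors: Iterable[Sequence[Fraction]]) -> list[Vec]:
    """Normalize and drop zero vectors and positive-scalar duplicates,
    preserving first-seen order."""
    seen: set[Vec] = set()
    out: list[Vec] = []
    for v in vectors:
        n = normalize_ray(v)
        if is_zero(n) or n in seen:
            continue
        seen.add(n)
        out.append(n)
    return out


def rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form (in place on a copy); returns (rref, pivot columns)."""
    m = [list(r) for r in rows]
    if not m:
        return [], []
    ncols = len(m[0])
    pivots: list[int] = []
    r = 0
    for c in range(ncols):
        if r >= len(m):
            break
        pr = next((i for i in range(r, len(m)) if m[i][c] != 0), None)
        if pr is None:
            continue
        m[r], m[pr] = m[pr], m[r]
        pv = m[r][c]
        m[r] = [x / pv for x in m[r]]
        for i in range(len(m)):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [x - f * y for x, y in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
    return m[:r], pivots


def nullspace(rows: Sequence[Sequence[Fraction]], ncols: int) -> list[Vec]:
    """Basis of {x : rows @ x = 0} as normalized integer vectors."""
    red, pivots = rref([list(r) for r in rows])
    free = [c for c in range(ncols) if c not in pivots]
    basis: list[Vec] = []
    for fc in free:
        x = [ZERO] * ncols
        x[fc] = Fraction(1)
        for ri, pc in enumerate(pivots):
            x[pc] = -red[ri][fc]
        basis.append(normalize_ray(x))
    return basis


def matrix_rank(rows: Sequence[Sequence[Fraction]]) -> int:
    red, _ = rref([list(r) for r in rows])
    return len(red)
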