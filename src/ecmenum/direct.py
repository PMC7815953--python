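"""Direct enumeration: iterative hyperplane intersection of the generator cone.

Start from the cone generated by the columns of the stoichiometry matrix
(all conversions reachable by conical combinations of reactions, steady
state not yet imposed).  For each internal metabolite i, intersect the
current cone with the hyperplane {c_i = 0}: generators split into a plus-,
zero- and minus-group by the sign of coordinate i; every plus/minus pair
yields a candidate combination with coordinate i balanced; candidates that
are nonnegative combinations of the other new generators are redundant and
dropped.  After all internal coordinates are processed the surviving
generators are the ECMs of the (single-orthant) network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

from ._rational import ZERO, Vec, is_zero, normalize_ray
from ._simplex import feasible_nonneg_combination, solve_nonneg
from .network import Conversion, MetabolicNetwork

_ONE = Fraction(1)


@dataclass
class GeneratorMatrix:
    """Columns generating the current cone, over a fixed metabolite ordering."""

    metabolite_ids: tuple[str, ...]
    columns: list[Vec]
    remaining_internal: list[str]
    lineage: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.lineage:
            self.lineage = [f"g{k}" for k in range(len(self.columns))]

    def index_of(self, mid: str) -> int:
        return self.metabolite_ids.index(mid)

    def conversions(self) -> list[Conversion]:
        return [Conversion(self.metabolite_ids, c) for c in self.columns]


def initial_generators(net: MetabolicNetwork) -> GeneratorMatrix:
    """R(0): the columns of N, zero columns dropped, scale-duplicates merged."""
    mids = tuple(net.metabolite_ids)
    seen: dict[Vec, str] = {}
    cols: list[Vec] = []
    lineage: list[str] = []
    for r, col in zip(net.reactions, net.N):
        n = normalize_ray(col)
        if is_zero(n) or n in seen:
            continue
        seen[n] = r.id
        cols.append(n)
        lineage.append(r.id)
    return GeneratorMatrix(mids, cols, list(net.internal_ids), lineage)


def partition_by_sign(
    R: GeneratorMatrix, i: str
) -> tuple[list[int], list[int], list[int]]:
    """Indices of columns with coordinate i positive / zero / negative."""
    idx = R.index_of(i)
    plus, zero, minus = [], [], []
    for k, col in enumerate(R.columns):
        (plus if col[idx] > 0 else minus if col[idx] < 0 else zero).append(k)
    return plus, zero, minus


def combine_pair(g_plus: Vec, g_minus: Vec, i: int) -> Vec:
    """Minimal-integer positive combination balancing coordinate i."""
    a, b = -g_minus[i], g_plus[i]
    assert a > 0 and b > 0, "combine_pair needs a producer and a consumer"
    return normalize_ray(tuple(a * p + b * m for p, m in zip(g_plus, g_minus)))


def candidate_redundant(candidate: Vec, others: Sequence[Vec]) -> bool:
    """Adjacency test: candidate redundant iff it is a nonnegative
    combination of the other generators (exact LP feasibility)."""
    return feasible_nonneg_combination(list(others), candidate) is not None


@dataclass
class IntersectionStats:
    metabolite: str
    n_plus: int = 0
    n_zero: int = 0
    n_minus: int = 0
    n_candidates: int = 0
    n_redundant: int = 0
    n_out: int = 0


def intersect_with_hyperplane(
    R: GeneratorMatrix,
    i: str,
    stats: Optional[IntersectionStats] = None,
    independent_filter: bool = True,
) -> GeneratorMatrix:
    """Impose the steady-state constraint c_i = 0 on the generator cone.

    ``independent_filter`` runs the redundancy test for each candidate
    against all other prospective columns independently (the tests commute,
    so they can run in any order or in parallel); it is exact for pointed
    cones.  The sequential fallback removes redundant candidates one at a
    time against the surviving set, which is sound for any cone.
    """
    idx = R.index_of(i)
    plus, zero, minus = partition_by_sign(R, i)
    if stats is not None:
        stats.n_plus, stats.n_zero, stats.n_minus = len(plus), len(zero), len(minus)

    zero_cols = [R.columns[k] for k in zero]
    zero_lineage = [R.lineage[k] for k in zero]
    cand_cols: list[Vec] = []
    cand_lineage: list[str] = []
    seen = set(zero_cols)
    n_candidates = 0
    for p in plus:
        for m in minus:
            n_candidates += 1
            c = combine_pair(R.columns[p], R.columns[m], idx)
            if is_zero(c) or c in seen:
                continue
            seen.add(c)
            cand_cols.append(c)
            cand_lineage.append(f"({R.lineage[p]}+{R.lineage[m]})")
    if stats is not None:
        stats.n_candidates = n_candidates

    all_cols = zero_cols + cand_cols
    all_lineage = zero_lineage + cand_lineage
    keep = [True] * len(all_cols)
    n_red = 0
    if independent_filter:
        for k in range(len(zero_cols), len(all_cols)):
            others = [all_cols[j] for j in range(len(all_cols)) if j != k]
            if candidate_redundant(all_cols[k], others):
                keep[k] = False
                n_red += 1
    else:
        for k in range(len(zero_cols), len(all_cols)):
            others = [all_cols[j] for j in range(len(all_cols)) if j != k and keep[j]]
            if candidate_redundant(all_cols[k], others):
                keep[k] = False
                n_red += 1
    if stats is not None:
        stats.n_redundant = n_red

    cols = [c for c, k in zip(all_cols, keep) if k]
    lineage = [l for l, k in zip(all_lineage, keep) if k]
    if stats is not None:
        stats.n_out = len(cols)
    remaining = [m for m in R.remaining_internal if m != i]
    return GeneratorMatrix(R.metabolite_ids, cols, remaining, lineage)


def _cone_is_pointed(R: GeneratorMatrix) -> bool:
    """cone(columns) is pointed iff no nonzero nonnegative combination of the
    columns vanishes (no zero-sum cycle among the generators)."""
    if not R.columns:
        return True
    n = len(R.columns)
    rows = [[R.columns[k][i] for k in range(n)] for i in range(len(R.metabolite_ids))]
    rows.append([_ONE] * n)
    b = [ZERO] * (len(rows) - 1) + [_ONE]
    return solve_nonneg(rows, b, n) is None


def _auto_order(R: GeneratorMatrix) -> str:
    """Next internal metabolite: fewest plus*minus candidate pairs."""
    best, best_cost = None, None
    for mid in R.remaining_internal:
        plus, _, minus = partition_by_sign(R, mid)
        cost = len(plus) * len(minus)
        if best_cost is None or cost < best_cost:
            best, best_cost = mid, cost
    return best


def enumerate_direct(
    net: MetabolicNetwork,
    order: Sequence[str] | str = "auto",
    collect_stats: Optional[list[IntersectionStats]] = None,
) -> GeneratorMatrix:
    """Enumerate the ECMs of a split, single-orthant network directly.

    ``order`` is "auto" (cheapest hyperplane first, recomputed each
    iteration), "file" (metabolite file order) or an explicit sequence of
    internal metabolite ids.
    """
    R = initial_generators(net)
    independent = _cone_is_pointed(R)
    explicit = list(order) if not isinstance(order, str) else None
    if explicit is not None and sorted(explicit) != sorted(R.remaining_internal):
        raise ValueError("explicit order must name every internal metabolite once")
    step = 0
    while R.remaining_internal:
        if explicit is not None:
            mid = explicit[step]
        elif order == "file":
            mid = R.remaining_internal[0]
        else:
            mid = _auto_order(R)
        stats = IntersectionStats(metabolite=mid)
        R = intersect_with_hyperplane(R, mid, stats, independent_filter=independent)
        if collect_stats is not None:
            collect_stats.append(stats)
        step += 1
    # R(0) need not be a minimal generator set (a reaction column may be a
    # conical combination of others), and such columns are never candidates,
    # so they can survive to the end; one global sequential reduction makes
    # the final set minimal.  Extreme rays are never removed by it.
    i = 0
    while i < len(R.columns):
        others = R.columns[:i] + R.columns[i + 1:]
        if candidate_redundant(R.columns[i], others):
            R.columns.pop(i)
            R.lineage.pop(i)
        else:
            i += 1
    return R
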