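"""Indirect enumeration: double description twice via the dual cone.

The generator representation of the initial cone C0 (columns of N) is, by
duality, an inequality representation of the dual cone C0*.  One run of the
double description (DD) method turns it into a generator representation of
C0*, which — again by duality — is an inequality representation of C0
itself.  Steady state is then imposed by deleting the internal-metabolite
columns of that inequality matrix (evaluating the system at c_int = 0), and
a second DD run yields the minimal generators of the steady-state conversion
cone: the ECMs of the single-orthant network.

The DD implementation is exact (Fraction arithmetic) and incremental, with
the standard combinatorial adjacency test; lineality (non-pointed stages,
which occur whenever cone(N) is not full-dimensional) is carried explicitly
as a basis and eliminated one inequality at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from ._rational import (
    ZERO,
    Vec,
    dot,
    is_zero,
    normalize_ray,
    rref,
    unique_rays,
)
from ._simplex import feasible_nonneg_combination
from .direct import GeneratorMatrix
from .network import MetabolicNetwork

_ONE = Fraction(1)


class ResourceError(RuntimeError):
    """An intermediate representation exceeded the configured size cap."""


class ContractError(RuntimeError):
    """The cone violated a representability precondition (e.g. pointedness)."""


@dataclass
class InequalityMatrix:
    """Rows h with cone = {x : h.x >= 0 for every row}."""

    rows: list[Vec]
    dimension: int

    def __post_init__(self):
        self.rows = unique_rays(self.rows)


def _reduce_mod_lineality(v: Vec, lin_rref: list[list[Fraction]], pivots: list[int]) -> Vec:
    """Canonical representative of v modulo the lineality space."""
    x = list(v)
    for row, p in zip(lin_rref, pivots):
        f = x[p]
        if f != 0:
            x = [a - f * b for a, b in zip(x, row)]
    return tuple(x)


@dataclass
class DDCone:
    """Generator representation: conical hull of rays + span of lineality."""

    rays: list[Vec]
    lineality: list[Vec]
    dimension: int


def double_description(
    H: InequalityMatrix, max_intermediate: Optional[int] = None
) -> DDCone:
    """Minimal generators of {x : Hx >= 0} by incremental double description.

    Starts from the whole space (lineality = identity basis) and inserts one
    inequality at a time.  If a lineality vector violates the new
    inequality it is turned into a ray and the rest of the representation is
    projected onto the new face; otherwise rays are partitioned by sign and
    adjacent plus/minus pairs are combined.  Adjacency uses the
    combinatorial zero-set test over the inequalities processed so far.
    """
    n = H.dimension
    lineality: list[Vec] = [
        tuple(_ONE if j == i else ZERO for j in range(n)) for i in range(n)
    ]
    rays: list[Vec] = []
    processed: list[Vec] = []

    for h in H.rows:
        if is_zero(h):
            continue
        pivot_idx = next((k for k, v in enumerate(lineality) if dot(h, v) != 0), None)
        if pivot_idx is not None:
            pivot = lineality.pop(pivot_idx)
            d0 = dot(h, pivot)
            if d0 < 0:
                pivot = tuple(-x for x in pivot)
                d0 = -d0

            def _project(v: Vec) -> Vec:
                f = dot(h, v) / d0
                return tuple(v_i - f * p_i for v_i, p_i in zip(v, pivot))

            lineality = [
                normalize_ray(w2) for w2 in map(_project, lineality) if not is_zero(w2)
            ]
            rays = unique_rays([_project(r) for r in rays] + [pivot])
        else:
            signs = [dot(h, r) for r in rays]
            zero = [r for r, s in zip(rays, signs) if s == 0]
            plus = [(r, s) for r, s in zip(rays, signs) if s > 0]
            minus = [(r, s) for r, s in zip(rays, signs) if s < 0]
            zsets = {
                r: frozenset(k for k, hh in enumerate(processed) if dot(hh, r) == 0)
                for r in rays
            }
            new = zero + [r for r, _ in plus]
            for p, sp in plus:
                for m, sm in minus:
                    common = zsets[p] & zsets[m]
                    adjacent = not any(
                        r not in (p, m) and common <= zsets[r] for r in rays
                    )
                    if adjacent:
                        new.append(
                            tuple(sp * m_i - sm * p_i for p_i, m_i in zip(p, m))
                        )
            rays = unique_rays(new)
        processed.append(h)
        if max_intermediate is not None and len(rays) > max_intermediate:
            raise ResourceError(
                f"double description intermediate exceeded {max_intermediate} rays"
            )

    if lineality:
        lin_rref, pivots = rref([list(v) for v in lineality])
        rays = unique_rays(
            _reduce_mod_lineality(r, lin_rref, pivots) for r in rays
        )
        lineality = [normalize_ray(tuple(v)) for v in lin_rref]
    return DDCone(rays=rays, lineality=lineality, dimension=n)


def dd_minimal_generators(
    H: InequalityMatrix, max_intermediate: Optional[int] = None
) -> list[Vec]:
    """Extreme rays of a pointed cone {x : Hx >= 0}."""
    cone = double_description(H, max_intermediate)
    if cone.lineality:
        raise ContractError(
            "cone is not pointed; double_description() returns its lineality"
        )
    return cone.rays


def dual_representation_swap(gen: DDCone | Sequence[Vec]) -> InequalityMatrix:
    """Reinterpret generators as inequalities of the dual cone (relabeling).

    A lineality vector of the generator representation contributes an
    equality to the dual system, encoded as a +/- inequality pair.
    """
    if isinstance(gen, DDCone):
        rows = list(gen.rays)
        for v in gen.lineality:
            rows.append(v)
            rows.append(tuple(-x for x in v))
        return InequalityMatrix(rows, gen.dimension)
    rows = list(gen)
    if not rows:
        raise ValueError("empty generator set has no dimension")
    return InequalityMatrix(rows, len(rows[0]))


def impose_steady_state_columns(
    H: InequalityMatrix,
    internal_indices: Sequence[int],
    reduce_rows: bool = True,
) -> InequalityMatrix:
    """Drop internal-metabolite columns: evaluate the system at c_int = 0.

    Rows that become zero, scale-duplicates, or conical combinations of the
    other rows are removed.
    """
    drop = set(internal_indices)
    keep = [i for i in range(H.dimension) if i not in drop]
    rows = unique_rays(tuple(r[i] for i in keep) for r in H.rows)
    if reduce_rows:
        i = 0
        while i < len(rows):
            others = rows[:i] + rows[i + 1:]
            if feasible_nonneg_combination(others, rows[i]) is not None:
                rows.pop(i)
            else:
                i += 1
    return InequalityMatrix(rows, len(keep))


def enumerate_indirect(
    net: MetabolicNetwork,
    max_intermediate: Optional[int] = None,
    log: Optional[list[str]] = None,
) -> GeneratorMatrix:
    """ECMs of a split, single-orthant network via the dual-cone DD route."""
    mids = tuple(net.metabolite_ids)
    n = len(mids)
    cols = unique_rays(net.N)

    def note(msg: str) -> None:
        if log is not None:
            log.append(msg)

    # stage 1: generator rep of C0 == inequality rep of C0*
    H_dual = InequalityMatrix(cols, n) if cols else InequalityMatrix([], n)
    note(f"stage 1 (ineq of dual cone): {len(H_dual.rows)} rows, dim {n}")

    # stage 2: DD -> generator rep of C0* == inequality rep of C0
    try:
        dual_gen = double_description(H_dual, max_intermediate)
    except ResourceError as e:
        raise ResourceError(f"first DD application: {e}") from e
    note(
        f"stage 2 (gen of dual cone): {len(dual_gen.rays)} rays, "
        f"{len(dual_gen.lineality)} lineality"
    )
    H0 = dual_representation_swap(dual_gen)

    # stage 3: impose steady state by column removal + row reduction
    internal_idx = [i for i, m in enumerate(net.metabolites) if m.is_internal]
    H_ss = impose_steady_state_columns(H0, internal_idx)
    note(f"stage 3 (ineq of conversion cone): {len(H_ss.rows)} rows, dim {H_ss.dimension}")

    # stage 4: DD -> minimal generators of C == the ECMs
    try:
        ecm_cone = double_description(H_ss, max_intermediate)
    except ResourceError as e:
        raise ResourceError(f"second DD application: {e}") from e
    if ecm_cone.lineality:
        raise ContractError(
            "steady-state conversion cone is not pointed; "
            "split bidirectional externals before enumeration"
        )
    note(f"stage 4 (ECMs): {len(ecm_cone.rays)} rays")

    # embed external-coordinate rays back into the full metabolite space
    external_pos = [i for i in range(n) if i not in set(internal_idx)]
    columns = []
    for r in ecm_cone.rays:
        full = [ZERO] * n
        for pos, val in zip(external_pos, r):
            full[pos] = val
        columns.append(normalize_ray(tuple(full)))
    return GeneratorMatrix(mids, unique_rays(columns), [])
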