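"""Un-splitting, normalization, validation properties and the orthant oracle.

A correct ECM set satisfies three properties: (1) every ECM is a realizable
steady-state conversion (some nonnegative flux vector produces it), (2)
every ECM is elementary (no conformal nonnegative combination of the other
ECMs reproduces it), and (3) every steady-state conversion decomposes as a
conformal nonnegative combination of ECMs.  These checks, plus a brute-force
per-orthant extreme-ray enumerator usable as ground truth on small networks,
live here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

from ._rational import (
    ZERO,
    Vec,
    is_zero,
    normalize_ray,
    nullspace,
    unique_rays,
)
from ._simplex import feasible_nonneg_combination, solve_nonneg
from .direct import GeneratorMatrix
from .network import Conversion, Direction, MetabolicNetwork
from .preprocess import UsageError

_ONE = Fraction(1)

NORMALIZATIONS = ("coprime_integer", "biomass_one", "abs_sum_one")


class DecompositionError(RuntimeError):
    """A steady-state conversion failed to decompose into the ECM set."""


@dataclass
class ECMSet:
    """Normalized elementary conversions over the reported metabolites."""

    metabolite_ids: tuple[str, ...]
    conversions: list[Conversion]
    normalization: str = "coprime_integer"
    hidden: dict[str, str] = field(default_factory=dict)  # id -> direction
    tags: dict[str, str] = field(default_factory=dict)  # tag id -> reaction id
    notes: list[str] = field(default_factory=list)
    biomass_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.conversions)

    def vectors(self) -> list[Vec]:
        return [c.values for c in self.conversions]

    def conversion_strings(self) -> list[str]:
        """Human-readable "a X + b Y -> c Z" strings, with "??" markers on the
        sides where hidden metabolites could contribute."""
        hide_left = any(d in ("input", "both") for d in self.hidden.values())
        hide_right = any(d in ("output", "both") for d in self.hidden.values())
        out = []
        for c in self.conversions:
            lhs = [f"{-v} {m}" if v != -1 else m
                   for m, v in zip(self.metabolite_ids, c.values) if v < 0]
            rhs = [f"{v} {m}" if v != 1 else m
                   for m, v in zip(self.metabolite_ids, c.values) if v > 0]
            if hide_left:
                lhs.append("??")
            if hide_right:
                rhs.append("??")
            out.append(" + ".join(lhs or ["0"]) + " -> " + " + ".join(rhs or ["0"]))
        return out


# ---------------------------------------------------------------------------
# Un-splitting and normalization
# ---------------------------------------------------------------------------

def unsplit_externals(R: GeneratorMatrix, net: MetabolicNetwork) -> ECMSet:
    """Map generators of the split network back to original coordinates.

    For every split metabolite X the reported coordinate is
    c(X) = c(X__out) - c(X__in); virtual coordinates are dropped, zero
    conversions (e.g. the pure X-passthrough) and duplicates are merged.
    """
    split_map: dict[str, tuple[str, str]] = net.metadata.get("split_externals", {})
    hidden: dict[str, str] = net.metadata.get("hidden", {})
    tags: dict[str, str] = net.metadata.get("tags", {})
    virtual_ids = {v for pair in split_map.values() for v in pair}

    reported: list[str] = []
    for m in net.metabolites:
        if m.id in split_map:
            reported.append(m.id)  # split original, currently internal
        elif not m.is_internal and m.id not in virtual_ids:
            reported.append(m.id)
    # a split original may have been compressed away; its virtual coordinates
    # survive (externals are never deleted), so it is still reportable
    for mid in split_map:
        if mid not in reported:
            reported.append(mid)
    rep = tuple(reported)

    notes: list[str] = []
    vecs: list[Vec] = []
    for col, lin in zip(R.columns, R.lineage):
        vals = []
        mids = R.metabolite_ids
        for mid in rep:
            if mid in split_map:
                m_in, m_out = split_map[mid]
                v_in = col[mids.index(m_in)]
                v_out = col[mids.index(m_out)]
                if v_in != 0 and v_out != 0:
                    notes.append(
                        f"generator {lin}: both {m_in} and {m_out} nonzero; net value used"
                    )
                # v_in is the (nonpositive) rate of change of the virtual input
                # metabolite, so the original coordinate is the plain sum
                vals.append(v_out + v_in)
            else:
                vals.append(col[mids.index(mid)])
        vecs.append(tuple(vals))

    convs = [Conversion(rep, v) for v in unique_rays(vecs)]
    return ECMSet(
        metabolite_ids=rep,
        conversions=convs,
        normalization="coprime_integer",
        hidden=dict(hidden),
        tags=dict(tags),
        notes=notes,
    )


def _abs_sum_one(v: Vec) -> Vec:
    s = sum(abs(x) for x in v)
    return v if s == 0 else tuple(x / s for x in v)


def normalize_ecms(
    ecms: ECMSet, rule: str, biomass_id: Optional[str] = None
) -> ECMSet:
    """Rescale every conversion per rule; idempotent for each rule.

    biomass_one fixes the biomass coefficient at 1 and falls back to
    abs_sum_one for conversions that do not produce biomass.
    """
    if rule not in NORMALIZATIONS:
        raise UsageError(f"unknown normalization rule {rule!r}")
    biomass_id = biomass_id or ecms.biomass_id
    if rule == "biomass_one":
        if biomass_id is None or biomass_id not in ecms.metabolite_ids:
            raise UsageError("biomass_one normalization needs a designated biomass metabolite")
        bi = ecms.metabolite_ids.index(biomass_id)

    out = []
    for c in ecms.conversions:
        v = c.values
        if rule == "coprime_integer":
            v = normalize_ray(v)
        elif rule == "abs_sum_one":
            v = _abs_sum_one(v)
        else:
            v = tuple(x / v[bi] for x in v) if v[bi] > 0 else _abs_sum_one(v)
        out.append(Conversion(ecms.metabolite_ids, v))
    return ECMSet(ecms.metabolite_ids, out, rule, dict(ecms.hidden),
                  dict(ecms.tags), list(ecms.notes), biomass_id)


# ---------------------------------------------------------------------------
# Validation properties
# ---------------------------------------------------------------------------

def _full_target(c: Conversion, net: MetabolicNetwork) -> list[Fraction]:
    """Embed a conversion into the network's full metabolite ordering;
    absent coordinates are implied zero."""
    lookup = dict(zip(c.metabolite_ids, c.values))
    return [lookup.get(m.id, ZERO) for m in net.metabolites]


def is_steady_state_conversion(
    c: Conversion, net: MetabolicNetwork
) -> tuple[bool, Optional[dict[str, Fraction]]]:
    """Property 1: exists v >= 0 with N v = c (internal coordinates zero).

    Returns (ok, witness flux vector by reaction id).
    """
    target = _full_target(c, net)
    cols: list[Vec] = []
    labels: list[tuple[str, int]] = []  # (reaction id, sign)
    for r, col in zip(net.reactions, net.N):
        cols.append(col)
        labels.append((r.id, 1))
        if r.reversible:
            cols.append(tuple(-x for x in col))
            labels.append((r.id, -1))
    rows = [[cols[k][i] for k in range(len(cols))] for i in range(len(net.metabolites))]
    v = solve_nonneg(rows, target, len(cols))
    if v is None:
        return False, None
    witness: dict[str, Fraction] = {}
    for (rid, sign), x in zip(labels, v):
        if x != 0:
            witness[rid] = witness.get(rid, ZERO) + sign * x
    return True, {rid: x for rid, x in witness.items() if x != 0}


def _conformal_subset(vectors: Sequence[Vec], c: Vec) -> list[Vec]:
    """Vectors sign-compatible with c on every coordinate: where c is zero
    the contributor must be zero, elsewhere it must not oppose c's sign."""
    out = []
    for v in vectors:
        ok = all(
            (ci == 0 and vi == 0) or (ci > 0 and vi >= 0) or (ci < 0 and vi <= 0)
            for ci, vi in zip(c, v)
        )
        if ok:
            out.append(v)
    return out


def is_elementary_in_set(c: Conversion, ecms: ECMSet) -> bool:
    """Property 2: no conformal nonnegative combination of the OTHER ECMs
    equals c (cancellation-free irreducibility)."""
    vectors = ecms.vectors()
    try:
        skip = vectors.index(c.values)
    except ValueError:
        raise UsageError("conversion is not a member of the ECM set") from None
    others = [v for k, v in enumerate(vectors) if k != skip]
    compatible = _conformal_subset(others, c.values)
    return feasible_nonneg_combination(compatible, c.values) is None


@dataclass
class DecompositionWeights:
    """Nonnegative weights over an ECM set reproducing a conversion."""

    weights: dict[int, Fraction]

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("negative decomposition weight")


def decompose_into_ecms(
    c: Conversion,
    ecms: ECMSet,
    tol: Fraction = ZERO,
    conformal: bool = True,
) -> DecompositionWeights:
    """Property 3 primitive: write c as a nonnegative combination of ECMs.

    With tol = 0 the match is exact; a positive tol allows a per-coordinate
    deviation of at most tol (useful when c comes from floating-point flux
    data).  ``conformal`` restricts contributors to those sign-compatible
    with c.  Raises DecompositionError if infeasible.
    """
    vectors = ecms.vectors()
    if len(c.metabolite_ids) != len(ecms.metabolite_ids):
        raise UsageError("conversion and ECM set use different coordinates")
    pool_idx = list(range(len(vectors)))
    if conformal:
        compat = _conformal_subset(vectors, c.values)
        pool_idx = [k for k, v in enumerate(vectors) if v in compat]
    pool = [vectors[k] for k in pool_idx]
    d = len(c.values)
    K = len(pool)
    tol = Fraction(tol)
    if tol == 0:
        lam = feasible_nonneg_combination(pool, c.values)
        if lam is None:
            raise DecompositionError("conversion does not decompose into the ECM set")
        return DecompositionWeights(
            {pool_idx[k]: w for k, w in enumerate(lam) if w != 0}
        )
    # variables: lam (K), s_plus (d), s_minus (d), u_plus (d), u_minus (d)
    n = K + 4 * d
    rows, b = [], []
    for i in range(d):
        row = [ZERO] * n
        for k in range(K):
            row[k] = pool[k][i]
        row[K + i] = _ONE
        row[K + d + i] = -_ONE
        rows.append(row)
        b.append(c.values[i])
    for i in range(d):  # s_plus_i + u_plus_i = tol ; s_minus_i + u_minus_i = tol
        row = [ZERO] * n
        row[K + i] = _ONE
        row[K + 2 * d + i] = _ONE
        rows.append(row)
        b.append(tol)
        row = [ZERO] * n
        row[K + d + i] = _ONE
        row[K + 3 * d + i] = _ONE
        rows.append(row)
        b.append(tol)
    sol = solve_nonneg(rows, b, n)
    if sol is None:
        raise DecompositionError("conversion does not decompose into the ECM set")
    return DecompositionWeights(
        {pool_idx[k]: sol[k] for k in range(K) if sol[k] != 0}
    )


# ---------------------------------------------------------------------------
# Brute-force per-orthant oracle
# ---------------------------------------------------------------------------

def extreme_rays_bruteforce(
    eq_rows: Sequence[Vec], ineq_rows: Sequence[Vec], n: int
) -> list[Vec]:
    """Extreme rays of {x : eq x = 0, ineq x >= 0} by active-set enumeration.

    An extreme ray activates enough inequality rows that, together with the
    equalities, the solution space is one-dimensional; every such ray is
    found by scanning all (d-1)-subsets of the inequality rows, d being the
    dimension of the equality kernel.
    """
    kernel = nullspace(eq_rows, n) if eq_rows else [
        tuple(_ONE if j == i else ZERO for j in range(n)) for i in range(n)
    ]
    d = len(kernel)
    if d == 0:
        return []

    # work in kernel coordinates: x = K y, inequality rows become h.K
    proj = [tuple(sum(h[i] * k[i] for i in range(n)) for k in kernel)
            for h in ineq_rows]

    def lift_if_feasible(y: Vec, found: list[Vec]) -> None:
        for cand in (y, tuple(-x for x in y)):
            if all(sum(p[j] * cand[j] for j in range(d)) >= 0 for p in proj):
                found.append(
                    tuple(sum(kernel[j][i] * cand[j] for j in range(d))
                          for i in range(n))
                )

    found: list[Vec] = []
    if d == 1:
        lift_if_feasible((_ONE,), found)
        return unique_rays(found)

    search_rows = unique_rays(proj)  # scale-duplicates share active sets
    for subset in itertools.combinations(range(len(search_rows)), d - 1):
        ns = nullspace([search_rows[i] for i in subset], d)
        if len(ns) != 1:
            continue
        lift_if_feasible(ns[0], found)
    return unique_rays(found)


def _minimal_generators(rays: list[Vec]) -> list[Vec]:
    rays = unique_rays(rays)
    i = 0
    while i < len(rays):
        others = rays[:i] + rays[i + 1:]
        if feasible_nonneg_combination(others, rays[i]) is not None:
            rays.pop(i)
        else:
            i += 1
    return rays


def oracle_orthant_enumeration(
    net: MetabolicNetwork,
    max_metabolites: int = 12,
    max_reactions: int = 15,
) -> ECMSet:
    """Ground-truth ECM enumeration by brute force, for small networks.

    For every sign pattern over the bidirectional external metabolites,
    restrict the conversion cone to that orthant (working in flux space,
    where the restriction is linear), enumerate the extreme rays of the
    restricted flux cone exhaustively, map them through N, reduce to minimal
    conversion generators, and take the union over orthants.  Reversible
    reactions are expanded inline as +/- column pairs.
    """
    cols: list[Vec] = []
    for r, col in zip(net.reactions, net.N):
        cols.append(col)
        if r.reversible:
            cols.append(tuple(-x for x in col))
    n = len(cols)
    if len(net.metabolites) > max_metabolites or n > max_reactions:
        raise UsageError(
            f"oracle cap exceeded ({len(net.metabolites)} metabolites, {n} columns)"
        )

    mids = net.metabolite_ids
    n_rows = [tuple(c[i] for c in cols) for i in range(len(mids))]
    eq_rows = [n_rows[i] for i, m in enumerate(net.metabolites) if m.is_internal]
    bidir = [i for i, m in enumerate(net.metabolites)
             if not m.is_internal and m.direction is Direction.BOTH]
    identity = [tuple(_ONE if j == i else ZERO for j in range(n)) for i in range(n)]

    ext_pos = [i for i, m in enumerate(net.metabolites) if not m.is_internal]
    rep = tuple(mids[i] for i in ext_pos)

    all_rays: list[Vec] = []
    for signs in itertools.product((1, -1), repeat=len(bidir)):
        ineq = list(identity)
        for s, i in zip(signs, bidir):
            ineq.append(tuple(s * x for x in n_rows[i]))
        flux_rays = extreme_rays_bruteforce(eq_rows, ineq, n)
        conv = []
        for v in flux_rays:
            image = tuple(
                sum(n_rows[i][k] * v[k] for k in range(n)) for i in ext_pos
            )
            if not is_zero(image):
                conv.append(image)
        all_rays.extend(_minimal_generators(conv))

    final = unique_rays(all_rays)
    return ECMSet(rep, [Conversion(rep, v) for v in final])


def validate_ecm_set(
    ecms: ECMSet,
    net: MetabolicNetwork,
    sample_conversions: Sequence[Conversion] = (),
) -> dict[str, bool]:
    """Run the three correctness properties; sampled steady-state conversions
    (if given) are decomposed conformally with tol = 0."""
    prop1 = all(is_steady_state_conversion(c, net)[0] for c in ecms.conversions)
    prop2 = all(is_elementary_in_set(c, ecms) for c in ecms.conversions)
    prop3 = True
    for c in sample_conversions:
        try:
            decompose_into_ecms(c, ecms, tol=ZERO, conformal=True)
        except DecompositionError:
            prop3 = False
            break
    return {"steady_state": prop1, "elementary": prop2, "decomposable": prop3}
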