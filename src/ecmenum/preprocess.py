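"""Network transforms applied before enumeration.

Order of play in the standard pipeline: split reversible reactions, split
bidirectional external metabolites into an input and an output copy (so the
conversion cone lies in a single orthant), optionally hide external
metabolites or tag reactions of interest, then compress.

Compression exploits that conversion analysis only cares about the overall
conversions between external metabolites, not the internal routes: each rule
provably leaves the ECM set unchanged while shrinking the stoichiometry
matrix.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Optional, Sequence

from ._rational import ZERO, Vec, normalize_ray
from ._simplex import feasible_nonneg_combination, solve_nonneg
from .network import (
    Direction,
    MetabolicNetwork,
    Metabolite,
    Origin,
    Reaction,
)

_ONE = Fraction(1)


class UsageError(ValueError):
    """Caller asked for a transform that does not apply."""


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_reversible(net: MetabolicNetwork) -> MetabolicNetwork:
    """Replace every reversible reaction by a forward/backward pair."""
    reactions: list[Reaction] = []
    mapping: dict[str, tuple[str, str]] = {}
    for r in net.reactions:
        if not r.reversible:
            reactions.append(r)
            continue
        fwd = Reaction(f"{r.id}__fwd", dict(r.stoichiometry), reversible=False,
                       origin=r.origin)
        rev = r.negated(f"{r.id}__rev")
        reactions.extend([fwd, rev])
        mapping[r.id] = (fwd.id, rev.id)
    out = MetabolicNetwork(list(net.metabolites), reactions, dict(net.metadata))
    if mapping:
        out.metadata["reversible_split"] = mapping
    return out


def split_bidirectional_externals(net: MetabolicNetwork) -> MetabolicNetwork:
    """Split every direction-'both' external X into X__in -> X -> X__out.

    X itself becomes internal; afterwards every external metabolite is
    input-only or output-only, so the steady-state conversion cone is
    contained in one orthant and its ECMs are exactly its extreme rays.
    """
    if any(r.reversible for r in net.reactions):
        raise UsageError("split reversible reactions before splitting externals")
    metabolites = list(net.metabolites)
    reactions = list(net.reactions)
    mapping: dict[str, tuple[str, str]] = {}
    for m in net.metabolites:
        if m.is_internal or m.direction is not Direction.BOTH:
            continue
        m_in, m_out = f"{m.id}__in", f"{m.id}__out"
        metabolites.append(Metabolite(m_in, direction=Direction.INPUT,
                                      is_internal=False, origin=Origin.VIRTUAL_SPLIT_IN))
        metabolites.append(Metabolite(m_out, direction=Direction.OUTPUT,
                                      is_internal=False, origin=Origin.VIRTUAL_SPLIT_OUT))
        reactions.append(Reaction(f"{m.id}__uptake", {m_in: -_ONE, m.id: _ONE},
                                  origin=Origin.VIRTUAL))
        reactions.append(Reaction(f"{m.id}__excrete", {m.id: -_ONE, m_out: _ONE},
                                  origin=Origin.VIRTUAL))
        idx = metabolites.index(m)
        metabolites[idx] = Metabolite(m.id, m.name, is_internal=True, origin=m.origin)
        mapping[m.id] = (m_in, m_out)
    out = MetabolicNetwork(metabolites, reactions, dict(net.metadata))
    if mapping:
        out.metadata["split_externals"] = {**out.metadata.get("split_externals", {}),
                                           **mapping}
    return out


# ---------------------------------------------------------------------------
# Hide and tag
# ---------------------------------------------------------------------------

def hide_metabolites(net: MetabolicNetwork, ids: Sequence[str]) -> MetabolicNetwork:
    """Hide external metabolites: free creation/disposal + mark internal.

    An input-only metabolite gets a reaction creating it from nothing, an
    output-only one a reaction disposing of it, a bidirectional one both.
    Enumeration then balances the metabolite internally and no longer reports
    it; provenance records the hidden ids and their original directions so
    reports can place "??" markers on the appropriate side.
    """
    metabolites = list(net.metabolites)
    reactions = list(net.reactions)
    hidden: dict[str, str] = dict(net.metadata.get("hidden", {}))
    for mid in ids:
        m = net.metabolite(mid)
        if m.is_internal:
            raise UsageError(f"cannot hide internal metabolite {mid!r}")
        if m.origin is Origin.VIRTUAL_TAG:
            raise UsageError(f"cannot hide tag metabolite {mid!r}")
        if m.direction in (Direction.INPUT, Direction.BOTH):
            reactions.append(Reaction(f"{mid}__hide_make", {mid: _ONE},
                                      origin=Origin.VIRTUAL_HIDE))
        if m.direction in (Direction.OUTPUT, Direction.BOTH):
            reactions.append(Reaction(f"{mid}__hide_dispose", {mid: -_ONE},
                                      origin=Origin.VIRTUAL_HIDE))
        idx = metabolites.index(m)
        metabolites[idx] = Metabolite(m.id, m.name, is_internal=True,
                                      origin=Origin.VIRTUAL_HIDE)
        hidden[mid] = m.direction.value
    out = MetabolicNetwork(metabolites, reactions, dict(net.metadata))
    if hidden:
        out.metadata["hidden"] = hidden
    return out


def tag_reactions(net: MetabolicNetwork, ids: Sequence[str]) -> MetabolicNetwork:
    """Append a virtual output metabolite T_k (+1) to each named reaction.

    The T_k coefficient of an ECM then equals the rate of the tagged
    reaction in any flux realization of that conversion.
    """
    metabolites = list(net.metabolites)
    reactions = list(net.reactions)
    tags: dict[str, str] = dict(net.metadata.get("tags", {}))
    existing = set(net.metabolite_ids)
    k = len(tags)
    for rid in ids:
        r = net.reaction(rid)  # KeyError on unknown id
        if r.reversible:
            raise UsageError(f"tag after splitting: reaction {rid!r} is reversible")
        k += 1
        tag_id = f"T{k}"
        while tag_id in existing:
            k += 1
            tag_id = f"T{k}"
        existing.add(tag_id)
        metabolites.append(Metabolite(tag_id, is_internal=False,
                                      direction=Direction.OUTPUT,
                                      origin=Origin.VIRTUAL_TAG))
        idx = reactions.index(r)
        stoich = dict(r.stoichiometry)
        stoich[tag_id] = _ONE
        reactions[idx] = Reaction(r.id, stoich, reversible=False, origin=r.origin)
        tags[tag_id] = rid
    out = MetabolicNetwork(metabolites, reactions, dict(net.metadata))
    if tags:
        out.metadata["tags"] = tags
    return out


# ---------------------------------------------------------------------------
# LP primitives
# ---------------------------------------------------------------------------

def reaction_feasible(net: MetabolicNetwork, j: int) -> bool:
    """Can reaction j carry positive flux in some internal steady state?

    Exact LP feasibility of {v >= 0 : N_int v = 0, v_j = 1} (positive flux is
    scale free).
    """
    rows = [list(r) for r in net.internal_rows()]
    n = len(net.reactions)
    pin = [ZERO] * n
    pin[j] = _ONE
    rows.append(pin)
    b = [ZERO] * (len(rows) - 1) + [_ONE]
    return solve_nonneg(rows, b, n) is not None


def conically_redundant(vectors: Sequence[Vec], candidate_index: int) -> bool:
    """Is vectors[candidate_index] a nonnegative combination of the others?"""
    others = [v for k, v in enumerate(vectors) if k != candidate_index]
    return feasible_nonneg_combination(others, vectors[candidate_index]) is not None


# ---------------------------------------------------------------------------
# Compression
# ---------------------------------------------------------------------------

#: cheap structural rules first, LP-based rules last
DEFAULT_COMPRESSION_ORDER: tuple[int, ...] = (4, 1, 5, 3, 6, 2)


def _delete(net: MetabolicNetwork, drop_mets: set[str], drop_rxns: set[str],
            replace_rxns: dict[str, Reaction] | None = None) -> MetabolicNetwork:
    replace_rxns = replace_rxns or {}
    reactions = []
    for r in net.reactions:
        if r.id in drop_rxns:
            continue
        r = replace_rxns.get(r.id, r)
        stoich = {m: c for m, c in r.stoichiometry.items() if m not in drop_mets}
        if not stoich:
            continue
        reactions.append(Reaction(r.id, stoich, r.reversible, r.origin))
    metabolites = [m for m in net.metabolites if m.id not in drop_mets]
    return MetabolicNetwork(metabolites, reactions, dict(net.metadata))


def _rule_dead_end(net: MetabolicNetwork) -> Optional[MetabolicNetwork]:
    """(4) delete internal metabolites that are only produced or only consumed."""
    for m in net.metabolites:
        if not m.is_internal:
            continue
        producers = [r for r in net.reactions if r.stoichiometry.get(m.id, ZERO) > 0]
        consumers = [r for r in net.reactions if r.stoichiometry.get(m.id, ZERO) < 0]
        touching = producers + consumers
        if touching and (not producers or not consumers):
            return _delete(net, {m.id}, {r.id for r in touching})
        if not touching:
            return _delete(net, {m.id}, set())
    return None


def _rule_infeasible(net: MetabolicNetwork) -> Optional[MetabolicNetwork]:
    """(1) remove reactions that can never carry flux at internal steady state."""
    dead = {net.reactions[j].id for j in range(len(net.reactions))
            if not reaction_feasible(net, j)}
    if not dead:
        return None
    return _delete(net, set(), dead)


def _fold(base: Reaction, addend: Reaction, factor: Fraction) -> Reaction:
    stoich = dict(base.stoichiometry)
    for m, c in addend.stoichiometry.items():
        stoich[m] = stoich.get(m, ZERO) + factor * c
    stoich = {m: c for m, c in stoich.items() if c != 0}
    return Reaction(base.id, stoich, base.reversible, base.origin) if stoich else None


def _rule_unique_function(net: MetabolicNetwork) -> Optional[MetabolicNetwork]:
    """(5) fold a sole producer (or consumer) of an internal metabolite into
    the opposite side, then delete reaction and metabolite."""
    for m in net.metabolites:
        if not m.is_internal:
            continue
        producers = [r for r in net.reactions if r.stoichiometry.get(m.id, ZERO) > 0]
        consumers = [r for r in net.reactions if r.stoichiometry.get(m.id, ZERO) < 0]
        if len(producers) == 1 and consumers:
            r1, side = producers[0], consumers
        elif len(consumers) == 1 and producers:
            r1, side = consumers[0], producers
        else:
            continue
        a1 = r1.stoichiometry[m.id]
        repl: dict[str, Reaction] = {}
        drop = {r1.id}
        for s in side:
            folded = _fold(s, r1, -s.stoichiometry[m.id] / a1)
            if folded is None:
                drop.add(s.id)
            else:
                repl[s.id] = folded
        return _delete(net, {m.id}, drop, repl)
    return None


def _antiparallel_pairs(net: MetabolicNetwork) -> list[tuple[int, int]]:
    cols = [normalize_ray(c) for c in net.N]
    out = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if cols[i] == normalize_ray(tuple(-x for x in cols[j])):
                out.append((i, j))
    return out


def _rule_reversible_cancel(net: MetabolicNetwork) -> Optional[MetabolicNetwork]:
    """(3) use a reversible pair (split fwd/rev image) to zero one adjacent
    internal metabolite everywhere, then delete pair and metabolite."""
    for i, j in _antiparallel_pairs(net):
        r1 = net.reactions[i]
        target = next((m for m in net.metabolites
                       if m.is_internal and r1.stoichiometry.get(m.id, ZERO) != 0), None)
        if target is None:
            continue
        a1 = r1.stoichiometry[target.id]
        repl: dict[str, Reaction] = {}
        drop = {r1.id, net.reactions[j].id}
        for s in net.reactions:
            if s.id in drop:
                continue
            a_s = s.stoichiometry.get(target.id, ZERO)
            if a_s == 0:
                continue
            folded = _fold(s, r1, -a_s / a1)  # sign-free: pair acts reversibly
            if folded is None:
                drop.add(s.id)
            else:
                repl[s.id] = folded
        return _delete(net, {target.id}, drop, repl)
    return None


def _find_cycle(net: MetabolicNetwork, j: int) -> Optional[list[Fraction]]:
    """Nonnegative weights lam with N lam = 0 and lam_j = 1 (a zero-sum cycle
    through reaction j), or None."""
    rows = [list(r) for r in net.N_rows()]
    n = len(net.reactions)
    pin = [ZERO] * n
    pin[j] = _ONE
    rows.append(pin)
    b = [ZERO] * (len(rows) - 1) + [_ONE]
    return solve_nonneg(rows, b, n)


def _rule_cycles(net: MetabolicNetwork) -> Optional[MetabolicNetwork]:
    """(6) cancel one reaction and one internal metabolite of a zero-sum cycle.

    Given lam >= 0 with sum_k lam_k R_k = 0 and R1 in the cycle touching an
    internal metabolite A, -lam_1 R1 equals the conical combination of the
    other cycle members, so A can be zeroed in every other reaction using
    only conical folds; R1 is then A's sole partner and both are deleted.
    Applied repeatedly, a k-cycle loses k-1 reactions and metabolites.
    """
    for j, r1 in enumerate(net.reactions):
        target = next((m for m in net.metabolites
                       if m.is_internal and r1.stoichiometry.get(m.id, ZERO) != 0), None)
        if target is None:
            continue
        lam = _find_cycle(net, j)
        if lam is None:
            continue
        a1 = r1.stoichiometry[target.id]
        # reverse of r1 as a conical combination of the other cycle members
        reverse: dict[str, Fraction] = {}
        for k, r in enumerate(net.reactions):
            if k == j or lam[k] == 0:
                continue
            for m, c in r.stoichiometry.items():
                reverse[m] = reverse.get(m, ZERO) + lam[k] * c
        reverse = {m: c for m, c in reverse.items() if c != 0}
        repl: dict[str, Reaction] = {}
        drop = {r1.id}
        for s in net.reactions:
            if s.id == r1.id:
                continue
            a_s = s.stoichiometry.get(target.id, ZERO)
            if a_s == 0:
                continue
            f = -a_s / a1
            if f >= 0:
                folded = _fold(s, r1, f)
            else:
                folded = _fold(s, Reaction("__rev__", reverse), -f)
            if folded is None:
                drop.add(s.id)
            else:
                repl[s.id] = folded
        return _delete(net, {target.id}, drop, repl)
    return None


def _rule_redundant(net: MetabolicNetwork) -> Optional[MetabolicNetwork]:
    """(2) delete reactions that are conical combinations of the others."""
    reactions = list(net.reactions)
    removed = False
    i = 0
    while i < len(reactions):
        cols = [tuple(r.stoichiometry.get(m.id, ZERO) for m in net.metabolites)
                for r in reactions]
        if conically_redundant(cols, i):
            reactions.pop(i)
            removed = True
        else:
            i += 1
    if not removed:
        return None
    return MetabolicNetwork(list(net.metabolites), reactions, dict(net.metadata))


_RULES = {
    1: _rule_infeasible,
    2: _rule_redundant,
    3: _rule_reversible_cancel,
    4: _rule_dead_end,
    5: _rule_unique_function,
    6: _rule_cycles,
}


def compress_network(
    net: MetabolicNetwork,
    steps: Iterable[int] = DEFAULT_COMPRESSION_ORDER,
    max_passes: int = 50,
) -> MetabolicNetwork:
    """Apply the enabled compression rules in order, iterating to fixpoint.

    Every rule preserves the ECM set; rules are numbered as in the module
    docstring: 1 infeasible, 2 redundant, 3 reversible-pair, 4 dead ends,
    5 unique producer/consumer, 6 cycles.
    """
    steps = tuple(steps)
    unknown = set(steps) - set(_RULES)
    if unknown:
        raise UsageError(f"unknown compression rules {sorted(unknown)}")
    current = net.copy()
    for _ in range(max_passes):
        changed = False
        for rule in steps:
            while True:
                nxt = _RULES[rule](current)
                if nxt is None:
                    break
                current = nxt
                changed = True
        if not changed:
            break
    return current
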