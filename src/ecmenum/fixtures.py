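"""Built-in example networks and a seeded random-network generator.

The fixtures are small didactic networks with fully known ECM sets:

* ``box1`` — three external metabolites A, B, BM interconverted via two
  internal ones; B can be both consumed and produced, so one ECM
  (2A -> BM) lies strictly inside the conversion cone and is only found
  through the per-orthant treatment.
* ``box3`` — the 8-metabolite, 7-reaction worked enumeration example
  (inputs A, E, F; output BM); exactly two ECMs: 2A+E -> BM and 2A+F -> BM.
* ``box3_hidden`` — the same network with E and F hidden (made internal and
  creatable from nothing); a single ECM consuming 2A remains.

The random generator is the test surface for cross-method equivalence: it
draws exact small stoichiometries, annotates external directions
*descriptively* (a metabolite is marked input-only iff the network can only
consume it), and rejects networks with an empty ECM set so every instance
exercises the enumeration.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from ._rational import ZERO
from ._simplex import solve_nonneg
from .network import (
    Direction,
    MetabolicNetwork,
    Metabolite,
    Origin,
    Reaction,
)
from .preprocess import UsageError

_ONE = Fraction(1)


def build_fixture(name: str) -> MetabolicNetwork:
    """Return one of the built-in example networks by name."""
    if name == "box1":
        mets = [
            Metabolite("A", is_internal=False, direction=Direction.INPUT),
            Metabolite("B", is_internal=False, direction=Direction.BOTH),
            Metabolite("BM", is_internal=False, direction=Direction.OUTPUT),
            Metabolite("C"),
            Metabolite("D"),
        ]
        rxns = [
            Reaction("v1", {"A": -1, "C": 1}),
            Reaction("v2", {"C": -1, "B": 1}),
            Reaction("v3", {"B": -2, "D": 1}),
            Reaction("v4", {"D": -1, "BM": 1}),
        ]
        return MetabolicNetwork(mets, rxns, {"fixture": "box1"})

    if name in ("box3", "box3_hidden"):
        hidden = name == "box3_hidden"
        mets = [
            Metabolite("A", is_internal=False, direction=Direction.INPUT),
            Metabolite("E", is_internal=hidden, direction=None if hidden else Direction.INPUT,
                       origin=Origin.VIRTUAL_HIDE if hidden else Origin.MODEL),
            Metabolite("F", is_internal=hidden, direction=None if hidden else Direction.INPUT,
                       origin=Origin.VIRTUAL_HIDE if hidden else Origin.MODEL),
            Metabolite("BM", is_internal=False, direction=Direction.OUTPUT),
            Metabolite("B"),
            Metabolite("C"),
            Metabolite("D"),
            Metabolite("G"),
        ]
        rxns = [
            Reaction("v1", {"A": -1, "B": 1}),
            Reaction("v2", {"A": -1, "C": 1}),
            Reaction("v3", {"B": -1, "D": 1}),
            Reaction("v4", {"C": -1, "D": 1}),
            Reaction("v5", {"B": -1, "E": -1, "G": 1}),
            Reaction("v6", {"B": -1, "F": -1, "G": 1}),
            Reaction("v7", {"D": -1, "G": -1, "BM": 1}),
        ]
        meta: dict = {"fixture": name, "biomass": "BM"}
        if hidden:
            rxns.append(Reaction("v8", {"E": 1}, origin=Origin.VIRTUAL_HIDE))
            rxns.append(Reaction("v9", {"F": 1}, origin=Origin.VIRTUAL_HIDE))
            meta["hidden"] = {"E": "input", "F": "input"}
        return MetabolicNetwork(mets, rxns, meta)

    raise UsageError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# Random networks
# ---------------------------------------------------------------------------

def _achievable_signs(net: MetabolicNetwork, mid: str) -> set[int]:
    """Which net signs (+1/-1) the conversion coordinate of ``mid`` can take.

    Exact LP on the reversibility-expanded columns: internal rows zero,
    coordinate ``mid`` pinned to +/-1, other externals free.
    """
    cols = []
    for r, col in zip(net.reactions, net.N):
        cols.append(col)
        if r.reversible:
            cols.append(tuple(-x for x in col))
    n = len(cols)
    idx = net.metabolite_index(mid)
    internal = [i for i, m in enumerate(net.metabolites) if m.is_internal]
    signs = set()
    for s in (1, -1):
        rows = [[cols[k][i] for k in range(n)] for i in internal + [idx]]
        b = [ZERO] * len(internal) + [Fraction(s)]
        if solve_nonneg(rows, b, n) is not None:
            signs.add(s)
    return signs


def _restrict_direction(net: MetabolicNetwork, mid: str, direction: Direction) -> MetabolicNetwork:
    """Structurally enforce a single direction on external ``mid``: the
    original node becomes internal and a fresh boundary metabolite with a
    one-way transport takes over its id."""
    core = f"{mid}_c"
    metabolites = []
    for m in net.metabolites:
        if m.id == mid:
            metabolites.append(Metabolite(core, m.name, is_internal=True))
            metabolites.append(Metabolite(mid, is_internal=False, direction=direction))
        else:
            metabolites.append(m)
    reactions = []
    for r in net.reactions:
        stoich = {core if k == mid else k: v for k, v in r.stoichiometry.items()}
        reactions.append(Reaction(r.id, stoich, r.reversible, r.origin))
    if direction is Direction.INPUT:
        reactions.append(Reaction(f"{mid}_tp", {mid: -_ONE, core: _ONE}))
    else:
        reactions.append(Reaction(f"{mid}_tp", {core: -_ONE, mid: _ONE}))
    return MetabolicNetwork(metabolites, reactions, dict(net.metadata))


def generate_random_network(
    n_int: int,
    n_ext: int,
    n_rxn: int,
    density: float = 0.4,
    p_reversible: float = 0.2,
    p_bidirectional_ext: float = 0.3,
    seed: int = 0,
    oracle_check: bool = True,
    max_attempts: int = 500,
) -> MetabolicNetwork:
    """Draw a small exact-stoichiometry network, reproducibly.

    Coefficients come from {-3..-1, 1..3}; external directions are assigned
    from the achievable conversion signs, with bidirectional status kept
    with probability ``p_bidirectional_ext`` when both signs are achievable
    (otherwise one achievable direction is enforced structurally).  Networks
    whose ECM set is empty under the brute-force oracle are redrawn.
    """
    from .postprocess import oracle_orthant_enumeration

    if min(n_int, n_ext, n_rxn) < 1:
        raise UsageError("counts must be >= 1")
    if oracle_check and (n_int + n_ext > 12 or n_rxn > 15):
        raise UsageError("network too large for the oracle check")
    rng = np.random.default_rng(seed)
    int_ids = [f"X{i + 1}" for i in range(n_int)]
    ext_ids = [f"E{i + 1}" for i in range(n_ext)]
    all_ids = int_ids + ext_ids

    for _ in range(max_attempts):
        reactions = []
        for j in range(n_rxn):
            mask = rng.random(len(all_ids)) < density
            if mask.sum() < 2:
                picks = rng.choice(len(all_ids), size=2, replace=False)
                mask[:] = False
                mask[picks] = True
            chosen = [all_ids[i] for i in np.flatnonzero(mask)]
            coeffs = [int(c) for c in rng.choice([-3, -2, -1, 1, 2, 3], size=len(chosen))]
            if all(c > 0 for c in coeffs):
                coeffs[0] = -coeffs[0]
            if all(c < 0 for c in coeffs):
                coeffs[-1] = -coeffs[-1]
            stoich = {m: Fraction(c) for m, c in zip(chosen, coeffs)}
            reversible = bool(rng.random() < p_reversible)
            reactions.append(Reaction(f"r{j + 1}", stoich, reversible))
        net = MetabolicNetwork(
            [Metabolite(m) for m in int_ids]
            + [Metabolite(m, is_internal=False, direction=Direction.BOTH)
               for m in ext_ids],
            reactions,
            {"seed": int(seed)},
        )

        # descriptive direction annotation, with optional structural restriction
        ok = True
        for mid in ext_ids:
            signs = _achievable_signs(net, mid)
            if not signs:
                net = net.with_metabolite(mid, direction=Direction.INPUT)
            elif signs == {1}:
                net = net.with_metabolite(mid, direction=Direction.OUTPUT)
            elif signs == {-1}:
                net = net.with_metabolite(mid, direction=Direction.INPUT)
            elif rng.random() >= p_bidirectional_ext:
                keep = Direction.INPUT if rng.random() < 0.5 else Direction.OUTPUT
                net = _restrict_direction(net, mid, keep)
        dirs = {net.metabolite(m).direction for m in ext_ids}
        can_in = dirs & {Direction.INPUT, Direction.BOTH}
        can_out = dirs & {Direction.OUTPUT, Direction.BOTH}
        if not (can_in and can_out):
            ok = False
        if ok and oracle_check:
            try:
                ok = len(oracle_orthant_enumeration(net)) > 0
            except UsageError:
                ok = False  # reversible expansion/restriction pushed past the cap
        if ok:
            return net
    raise RuntimeError(f"no usable network found in {max_attempts} attempts (seed {seed})")
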