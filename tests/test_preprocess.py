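"""Splitting, hide/tag, LP primitives and ECM-preserving compression."""

from fractions import Fraction

import pytest

import ecmenum as e
from ecmenum.network import Direction, MetabolicNetwork, Metabolite, Origin, Reaction

from conftest import ecm_key, enumerate_network


# -- splitting ---------------------------------------------------------------

def test_split_reversible_creates_negated_pair():
    net = MetabolicNetwork(
        [Metabolite("A", is_internal=False, direction=Direction.INPUT),
         Metabolite("B", is_internal=False, direction=Direction.OUTPUT)],
        [Reaction("r", {"A": -1, "B": 1}, reversible=True)],
    )
    out = e.split_reversible(net)
    assert [r.id for r in out.reactions] == ["r__fwd", "r__rev"]
    assert out.reaction("r__rev").stoichiometry == {"A": Fraction(1), "B": Fraction(-1)}
    assert not any(r.reversible for r in out.reactions)
    assert out.metadata["reversible_split"] == {"r": ("r__fwd", "r__rev")}


def test_split_reversible_counts(box3):
    rev = MetabolicNetwork(
        list(box3.metabolites),
        [Reaction(r.id, dict(r.stoichiometry), reversible=(i < 3))
         for i, r in enumerate(box3.reactions)],
    )
    assert len(e.split_reversible(rev).reactions) == 10
    # all-irreversible network is unchanged
    assert e.split_reversible(box3).N == box3.N


def test_split_bidirectional_externals(box1):
    net = e.split_bidirectional_externals(box1)
    assert net.metabolite("B").is_internal
    assert net.metabolite("B__in").direction is Direction.INPUT
    assert net.metabolite("B__out").direction is Direction.OUTPUT
    assert net.reaction("B__uptake").stoichiometry == {"B__in": Fraction(-1), "B": Fraction(1)}
    assert all(m.direction is not Direction.BOTH for m in net.metabolites if not m.is_internal)
    # no-op when there is nothing bidirectional
    box3 = e.build_fixture("box3")
    assert e.split_bidirectional_externals(box3).N == box3.N


def test_split_network_generators_are_sign_consistent(box1):
    """After splitting, the cone lies in one orthant: per coordinate all
    generators share a sign."""
    net = e.split_bidirectional_externals(box1)
    R = e.enumerate_direct(net)
    for i in range(len(R.metabolite_ids)):
        signs = {1 if c[i] > 0 else -1 for c in R.columns if c[i] != 0}
        assert len(signs) <= 1


# -- hide and tag ------------------------------------------------------------

def test_hide_output_metabolite_adds_disposal():
    net = MetabolicNetwork(
        [Metabolite("A", is_internal=False, direction=Direction.INPUT),
         Metabolite("F", is_internal=False, direction=Direction.OUTPUT)],
        [Reaction("r", {"A": -1, "F": 1})],
    )
    out = e.hide_metabolites(net, ["F"])
    assert out.metabolite("F").is_internal
    assert out.reaction("F__hide_dispose").stoichiometry == {"F": Fraction(-1)}
    assert out.metadata["hidden"] == {"F": "output"}


def test_hide_equals_hidden_fixture(box3, box3_hidden):
    hidden = e.hide_metabolites(box3, ["E", "F"])
    assert sorted(map(tuple, hidden.N)) == sorted(map(tuple, box3_hidden.N))
    assert hidden.internal_ids == box3_hidden.internal_ids


def test_hide_internal_metabolite_is_an_error(box3):
    with pytest.raises(e.UsageError):
        e.hide_metabolites(box3, ["B"])


def test_hide_nothing_is_identity(box3):
    assert e.hide_metabolites(box3, []).N == box3.N


def test_tag_appends_virtual_product(box3):
    tagged = e.tag_reactions(box3, ["v3"])  # B -> D becomes B -> D + T1
    assert tagged.reaction("v3").stoichiometry["T1"] == Fraction(1)
    assert tagged.metabolite("T1").direction is Direction.OUTPUT
    assert tagged.metabolite("T1").origin is Origin.VIRTUAL_TAG
    assert tagged.metadata["tags"] == {"T1": "v3"}
    assert e.tag_reactions(box3, []).N == box3.N
    with pytest.raises(KeyError):
        e.tag_reactions(box3, ["nope"])


def test_tag_coefficient_equals_reaction_rate(box3):
    """The T1 coefficient of an ECM equals the tagged reaction's rate in a
    flux realization of that ECM."""
    tagged = e.tag_reactions(box3, ["v5"])
    ecms = enumerate_network(tagged)
    uses_e = next(c for c in ecms.conversions if c["E"] != 0)
    ok, witness = e.is_steady_state_conversion(uses_e, tagged)
    assert ok and witness["v5"] == uses_e["T1"] == Fraction(1)
    no_e = next(c for c in ecms.conversions if c["E"] == 0)
    assert no_e["T1"] == 0


# -- LP primitives -----------------------------------------------------------

def test_reaction_feasibility(box3):
    assert e.reaction_feasible(box3, 0)  # v1 carries flux in 2A+E->BM
    dead = MetabolicNetwork(
        [Metabolite("A", is_internal=False, direction=Direction.INPUT),
         Metabolite("X")],
        [Reaction("r", {"A": -1, "X": 1})],  # X produced, never consumed
    )
    assert not e.reaction_feasible(dead, 0)


def test_conical_redundancy():
    ac = (Fraction(-1), Fraction(1), Fraction(0))
    cd = (Fraction(0), Fraction(-1), Fraction(1))
    ad = (Fraction(-1), Fraction(0), Fraction(1))
    assert e.conically_redundant([ac, cd, ad], 2)  # A->D = (A->C) + (C->D)
    assert not e.conically_redundant([ad], 0)  # nothing else available
    assert e.conically_redundant([ac, ac], 1)  # duplicate twin


# -- compression -------------------------------------------------------------

def test_dead_end_rule_removes_metabolite_and_producer():
    net = MetabolicNetwork(
        [Metabolite("A", is_internal=False, direction=Direction.INPUT),
         Metabolite("B", is_internal=False, direction=Direction.OUTPUT),
         Metabolite("X")],
        [Reaction("r1", {"A": -1, "B": 1}), Reaction("r2", {"A": -1, "X": 1})],
    )
    out = e.compress_network(net, steps=(4,))
    assert "X" not in out.metabolite_ids and out.reaction_ids == ["r1"]


def test_two_cycle_cancellation_preserves_ecms():
    net = MetabolicNetwork(
        [Metabolite("S", is_internal=False, direction=Direction.INPUT),
         Metabolite("P", is_internal=False, direction=Direction.OUTPUT),
         Metabolite("A"), Metabolite("B")],
        [Reaction("in", {"S": -1, "A": 1}), Reaction("f", {"A": -1, "B": 1}),
         Reaction("b", {"B": -1, "A": 1}), Reaction("out", {"B": -1, "P": 1})],
    )
    out = e.compress_network(net, steps=(6,))
    assert len(out.reactions) < len(net.reactions)
    assert ecm_key(e.oracle_orthant_enumeration(net)) == ecm_key(
        e.oracle_orthant_enumeration(out)
    )


def test_redundant_reaction_deleted(box3):
    plus = MetabolicNetwork(
        list(box3.metabolites),
        list(box3.reactions) + [Reaction("vx", {"A": -1, "D": 1})],  # = v2+v4
    )
    out = e.compress_network(plus, steps=(2,))
    assert "vx" not in out.reaction_ids
    assert ecm_key(enumerate_network(out)) == ecm_key(enumerate_network(box3))


@pytest.mark.parametrize("rule", [1, 2, 3, 4, 5, 6])
def test_single_rules_preserve_fixture_ecms(rule, box1, box3, box3_hidden):
    for net in (box1, box3, box3_hidden):
        ref = ecm_key(enumerate_network(net))
        got = ecm_key(enumerate_network(net, compress=True, compression_steps=(rule,)))
        assert got == ref


def test_compression_cascade_preserves_random_network_ecms():
    for seed in range(12):
        net = e.generate_random_network(4, 3, 7, p_reversible=0.4, seed=400 + seed)
        ref = ecm_key(enumerate_network(net))
        got = ecm_key(enumerate_network(net, compress=True))
        assert got == ref, f"seed {400 + seed}"


def test_unknown_compression_rule_rejected(box3):
    with pytest.raises(e.UsageError):
        e.compress_network(box3, steps=(9,))
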