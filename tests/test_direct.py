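"""The direct hyperplane-intersection algorithm, against the worked example.

The 8-metabolite network with inputs A, E, F and output BM has exactly two
ECMs (2A+E -> BM and 2A+F -> BM); the first intersection step (metabolite B)
must produce three candidates of which exactly one is redundant.
"""

import random
from fractions import Fraction

import ecmenum as e
from ecmenum.direct import IntersectionStats

from conftest import ecm_key


def col(net, rid):
    return net.column(net.reaction(rid))


def as_dict(R, c):
    return {m: v for m, v in zip(R.metabolite_ids, c) if v != 0}


def test_initial_generators_are_stoichiometry_columns(box3):
    R = e.initial_generators(box3)
    assert len(R.columns) == 7
    assert R.lineage == [r.id for r in box3.reactions]
    assert R.remaining_internal == ["B", "C", "D", "G"]


def test_initial_generators_merge_scale_duplicates():
    from ecmenum.network import Direction, MetabolicNetwork, Metabolite, Reaction

    net = MetabolicNetwork(
        [Metabolite("A", is_internal=False, direction=Direction.INPUT),
         Metabolite("B", is_internal=False, direction=Direction.OUTPUT)],
        [Reaction("r1", {"A": -1, "B": 1}), Reaction("r2", {"A": -2, "B": 2})],
    )
    assert len(e.initial_generators(net).columns) == 1


def test_sign_partition_for_first_constraint(box3):
    R = e.initial_generators(box3)
    plus, zero, minus = e.partition_by_sign(R, "B")
    assert [R.lineage[k] for k in plus] == ["v1"]
    assert [R.lineage[k] for k in zero] == ["v2", "v4", "v7"]
    assert [R.lineage[k] for k in minus] == ["v3", "v5", "v6"]


def test_combine_pair_balances_coordinate(box3):
    R = e.initial_generators(box3)
    i = R.index_of("B")
    v1, v3, v5 = (R.columns[R.lineage.index(r)] for r in ("v1", "v3", "v5"))
    got = e.combine_pair(v1, v5, i)
    assert as_dict(R, got) == {"A": Fraction(-1), "E": Fraction(-1), "G": Fraction(1)}
    assert as_dict(R, e.combine_pair(v1, v3, i)) == {"A": Fraction(-1), "D": Fraction(1)}


def test_combine_pair_uses_minimal_integer_weights():
    gp = (Fraction(2), Fraction(1))
    gm = (Fraction(-3), Fraction(0))
    got = e.combine_pair(gp, gm, 0)  # 3*gp + 2*gm = (0, 3), canonical ray (0, 1)
    assert got == (Fraction(0), Fraction(1))


def test_candidate_redundancy_matches_worked_example(box3):
    ids = box3.metabolite_ids
    def vec(**v):
        return tuple(Fraction(v.get(m, 0)) for m in ids)
    a_d = vec(A=-1, D=1)
    new_set = [
        vec(A=-1, C=1),            # v2
        vec(C=-1, D=1),            # v4
        vec(A=-1, E=-1, G=1),      # v1+v5
        vec(A=-1, F=-1, G=1),      # v1+v6
        vec(D=-1, G=-1, BM=1),     # v7
    ]
    assert e.candidate_redundant(a_d, new_set)  # = v2 + v4
    assert not e.candidate_redundant(new_set[2], new_set[:2] + new_set[3:])
    assert not e.candidate_redundant(a_d, [])


def test_first_intersection_reproduces_worked_example(box3):
    R = e.initial_generators(box3)
    stats = IntersectionStats("B")
    R1 = e.intersect_with_hyperplane(R, "B", stats)
    assert (stats.n_candidates, stats.n_redundant) == (3, 1)
    expected = {
        (("A", Fraction(-1)), ("C", Fraction(1))),
        (("C", Fraction(-1)), ("D", Fraction(1))),
        (("A", Fraction(-1)), ("E", Fraction(-1)), ("G", Fraction(1))),
        (("A", Fraction(-1)), ("F", Fraction(-1)), ("G", Fraction(1))),
        (("BM", Fraction(1)), ("D", Fraction(-1)), ("G", Fraction(-1))),
    }
    got = {tuple(sorted(as_dict(R1, c).items())) for c in R1.columns}
    assert got == expected
    assert "B" not in R1.remaining_internal


def test_intersection_on_balanced_coordinate_is_bookkeeping_only(box3):
    R = e.initial_generators(box3)
    R1 = e.intersect_with_hyperplane(R, "B")
    R2 = e.intersect_with_hyperplane(R1, "B".replace("B", R1.remaining_internal[0]))
    # a coordinate that is already zero everywhere keeps all columns
    zero_everywhere = next(
        (m for m in R2.remaining_internal
         if all(c[R2.index_of(m)] == 0 for c in R2.columns)), None)
    if zero_everywhere is not None:
        R3 = e.intersect_with_hyperplane(R2, zero_everywhere)
        assert R3.columns == R2.columns


def test_hidden_network_collapses_parallel_routes(box3_hidden):
    """Hiding E leaves one producer (the make-from-nothing reaction) and one
    consumer of E; balancing E and F yields the single conversion B -> G —
    the two parallel routes through E and F collapse to one generator."""
    R = e.initial_generators(box3_hidden)
    plus, _, minus = e.partition_by_sign(R, "E")
    assert [R.lineage[k] for k in plus] == ["v8"]
    assert [R.lineage[k] for k in minus] == ["v5"]
    R2 = e.intersect_with_hyperplane(e.intersect_with_hyperplane(R, "E"), "F")
    b_to_g = [c for c in R2.columns
              if as_dict(R2, c) == {"B": Fraction(-1), "G": Fraction(1)}]
    assert len(b_to_g) == 1


def test_enumeration_yields_both_conversions(box3):
    R = e.enumerate_direct(box3, order=["B", "C", "D", "G"])
    got = {tuple(sorted(as_dict(R, c).items())) for c in R.columns}
    assert got == {
        (("A", Fraction(-2)), ("BM", Fraction(1)), ("E", Fraction(-1))),
        (("A", Fraction(-2)), ("BM", Fraction(1)), ("F", Fraction(-1))),
    }


def test_hidden_enumeration_yields_single_conversion(box3_hidden):
    R = e.enumerate_direct(box3_hidden)
    assert len(R.columns) == 1
    assert as_dict(R, R.columns[0]) == {"A": Fraction(-2), "BM": Fraction(1)}


def test_result_is_order_invariant(box3, box1):
    rng = random.Random(11)
    for net in (box3, e.split_bidirectional_externals(box1)):
        ref = ecm_key(e.unsplit_externals(e.enumerate_direct(net), net))
        internals = list(net.internal_ids)
        for _ in range(10):
            perm = internals[:]
            rng.shuffle(perm)
            R = e.enumerate_direct(net, order=perm)
            assert ecm_key(e.unsplit_externals(R, net)) == ref


def test_candidate_tests_are_order_independent(box3):
    """The redundancy test depends only on its inputs: shuffling the other
    generators never changes the verdict (parallel contract)."""
    R = e.initial_generators(box3)
    i = R.index_of("B")
    plus, zero, minus = e.partition_by_sign(R, "B")
    cands = [e.combine_pair(R.columns[p], R.columns[m], i) for p in plus for m in minus]
    pool = [R.columns[k] for k in zero] + cands
    rng = random.Random(3)
    for c in cands:
        others = [x for x in pool if x != c]
        ref = e.candidate_redundant(c, others)
        for _ in range(5):
            shuffled = others[:]
            rng.shuffle(shuffled)
            assert e.candidate_redundant(c, shuffled) == ref


def test_filtering_matches_unfiltered_then_reduced(box3, box1):
    """Candidate filtering never drops a non-redundant generator: the result
    equals combining all candidates and reducing globally afterwards."""
    for net in (box3, e.split_bidirectional_externals(box1)):
        R = e.initial_generators(net)
        mid = R.remaining_internal[0]
        filtered = e.intersect_with_hyperplane(R, mid)
        # unfiltered: all pair combinations plus the zero group
        i = R.index_of(mid)
        plus, zero, minus = e.partition_by_sign(R, mid)
        pool = [R.columns[k] for k in zero] + [
            e.combine_pair(R.columns[p], R.columns[m], i) for p in plus for m in minus
        ]
        pool = list(dict.fromkeys(pool))
        k = 0
        while k < len(pool):
            if e.candidate_redundant(pool[k], pool[:k] + pool[k + 1:]):
                pool.pop(k)
            else:
                k += 1
        assert sorted(filtered.columns) == sorted(pool)


def test_empty_network_enumerates_to_nothing():
    from ecmenum.network import Direction, MetabolicNetwork, Metabolite

    net = MetabolicNetwork(
        [Metabolite("A", is_internal=False, direction=Direction.INPUT)], []
    )
    assert e.enumerate_direct(net).columns == []
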