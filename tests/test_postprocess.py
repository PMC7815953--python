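"""Un-splitting, normalization, the three validation properties, oracle."""

from fractions import Fraction

import pytest

import ecmenum as e

from conftest import conv, ecm_key, enumerate_network

F = Fraction


@pytest.fixture
def fig_set(box1):
    """The three-ECM set over (A, B, BM): A->B, 2B->BM, 2A->BM."""
    return enumerate_network(box1)


def test_unsplit_maps_virtual_coordinates_back(box1):
    net = e.split_bidirectional_externals(box1)
    R = e.enumerate_direct(net)
    ecms = e.unsplit_externals(R, net)
    assert ecms.metabolite_ids == ("A", "B", "BM")
    assert ecm_key(ecms) == {
        (("A", F(-1)), ("B", F(1))),
        (("B", F(-2)), ("BM", F(1))),
        (("A", F(-2)), ("BM", F(1))),
    }


def test_unsplit_drops_pure_passthrough(box1):
    """The uptake+excretion cycle of a split metabolite nets to zero and is
    not reported as a conversion."""
    net = e.split_bidirectional_externals(box1)
    R = e.enumerate_direct(net)
    assert len(R.columns) == 4  # includes B__in -> B__out
    assert len(e.unsplit_externals(R, net)) == 3


def test_normalize_coprime_integer():
    out = e.normalize_ecms(
        e.ECMSet(("A", "E", "F", "BM"),
                 [e.Conversion(("A", "E", "F", "BM"), (F(-4), F(-2), F(0), F(2)))]),
        "coprime_integer",
    )
    assert out.conversions[0].values == (F(-2), F(-1), F(0), F(1))


def test_normalize_biomass_one_with_fallback():
    ids = ("A", "B", "BM")
    ecms = e.ECMSet(ids, [
        e.Conversion(ids, (F(-2), F(0), F(1))),   # already BM = 1
        e.Conversion(ids, (F(-1), F(1), F(0))),   # zero biomass
    ])
    out = e.normalize_ecms(ecms, "biomass_one", biomass_id="BM")
    assert out.conversions[0].values == (F(-2), F(0), F(1))
    assert out.conversions[1].values == (F(-1, 2), F(1, 2), F(0))
    with pytest.raises(e.UsageError):
        e.normalize_ecms(ecms, "biomass_one", biomass_id=None)


@pytest.mark.parametrize("rule", ["coprime_integer", "biomass_one", "abs_sum_one"])
def test_normalization_is_idempotent(fig_set, rule):
    once = e.normalize_ecms(fig_set, rule, biomass_id="BM")
    twice = e.normalize_ecms(once, rule, biomass_id="BM")
    assert [c.values for c in once.conversions] == [c.values for c in twice.conversions]


def test_steady_state_check_returns_verifiable_witness(box3):
    c = conv(box3.metabolite_ids, A=-2, E=-1, BM=1)
    ok, witness = e.is_steady_state_conversion(c, box3)
    assert ok
    # push the witness through N and compare coordinate by coordinate
    total = {m.id: F(0) for m in box3.metabolites}
    for rid, rate in witness.items():
        for mid, coeff in box3.reaction(rid).stoichiometry.items():
            total[mid] += rate * coeff
    assert total == c.as_dict() | {m: F(0) for m in total if m not in c.as_dict()}


def test_unproducible_direction_is_not_steady_state(box3):
    assert not e.is_steady_state_conversion(conv(box3.metabolite_ids, A=1), box3)[0]


def test_zero_conversion_is_steady_state(box3):
    ok, witness = e.is_steady_state_conversion(conv(box3.metabolite_ids), box3)
    assert ok and witness == {}


def test_interior_ecm_is_elementary(fig_set):
    red = next(c for c in fig_set.conversions if c["B"] == 0)
    assert e.is_elementary_in_set(red, fig_set)
    # ... although it IS a plain (non-conformal) combination of the others
    w = e.decompose_into_ecms(red, fig_set, conformal=False)
    assert len(w.weights) >= 2


def test_duplicate_is_not_elementary(fig_set):
    dup = fig_set.conversions[0]
    bigger = e.ECMSet(fig_set.metabolite_ids, fig_set.conversions + [dup])
    assert not e.is_elementary_in_set(dup, bigger)


def test_conformal_decomposition_selects_interior_ecm(fig_set):
    red = next(c for c in fig_set.conversions if c["B"] == 0)
    w = e.decompose_into_ecms(red, fig_set, conformal=True)
    assert w.weights == {fig_set.conversions.index(red): F(1)}


def test_scaled_member_decomposes_with_scaled_weight(fig_set):
    c0 = fig_set.conversions[0]
    tripled = e.Conversion(c0.metabolite_ids, tuple(3 * x for x in c0.values))
    w = e.decompose_into_ecms(tripled, fig_set)
    assert w.weights == {0: F(3)}


def test_infeasible_decomposition_raises(fig_set):
    bad = conv(fig_set.metabolite_ids, A=1)
    with pytest.raises(e.DecompositionError):
        e.decompose_into_ecms(bad, fig_set)


def test_tolerant_decomposition_absorbs_small_error(fig_set):
    c0 = fig_set.conversions[0]
    vals = list(c0.values)
    vals[0] += F(1, 10**8)
    off = e.Conversion(c0.metabolite_ids, tuple(vals))
    with pytest.raises(e.DecompositionError):
        e.decompose_into_ecms(off, fig_set, tol=F(0))
    w = e.decompose_into_ecms(off, fig_set, tol=F(1, 10**7))
    assert all(x >= 0 for x in w.weights.values())


def test_flux_mode_conversions_decompose_into_ecms():
    """Every elementary flux mode's overall conversion is a conformal
    nonnegative combination of the ECMs, exactly (tol = 0)."""
    from ecmenum.postprocess import extreme_rays_bruteforce
    from ecmenum._rational import ZERO

    for seed in (901, 902, 903, 904):
        net = e.generate_random_network(4, 3, 7, p_reversible=0.0, seed=seed)
        ecms = enumerate_network(net)
        n = len(net.reactions)
        eq = net.internal_rows()
        nonneg = [tuple(F(int(i == j)) for j in range(n)) for i in range(n)]
        efms = extreme_rays_bruteforce(eq, nonneg, n)
        rows = net.N_rows()
        ext = [i for i, m in enumerate(net.metabolites) if not m.is_internal]
        for v in efms:
            image = tuple(sum(rows[i][k] * v[k] for k in range(n)) for i in ext)
            c = e.Conversion(ecms.metabolite_ids, image)
            if all(x == 0 for x in image):
                continue
            e.decompose_into_ecms(c, ecms, tol=ZERO, conformal=True)


def test_oracle_counts_on_fixtures(box1, box3):
    assert len(e.oracle_orthant_enumeration(box1)) == 3
    assert len(e.oracle_orthant_enumeration(box3)) == 2


def test_oracle_single_reversible_exchange():
    from ecmenum.network import Direction, MetabolicNetwork, Metabolite, Reaction

    net = MetabolicNetwork(
        [Metabolite("A", is_internal=False, direction=Direction.BOTH),
         Metabolite("B", is_internal=False, direction=Direction.BOTH)],
        [Reaction("r", {"A": -1, "B": 1}, reversible=True)],
    )
    assert ecm_key(e.oracle_orthant_enumeration(net)) == {
        (("A", F(-1)), ("B", F(1))), (("A", F(1)), ("B", F(-1))),
    }


def test_oracle_size_cap(box3):
    with pytest.raises(e.UsageError):
        e.oracle_orthant_enumeration(box3, max_reactions=3)


def test_validation_suite_on_fixture_pipeline(box1):
    ecms = enumerate_network(box1)
    val_net = e.split_reversible(box1)
    # sampled steady-state conversions: nonnegative combinations of ECMs
    samples = []
    for w in ([1, 2, 0], [3, 1, 1]):
        vals = tuple(
            sum(F(wk) * c.values[i] for wk, c in zip(w, ecms.conversions))
            for i in range(len(ecms.metabolite_ids))
        )
        samples.append(e.Conversion(ecms.metabolite_ids, vals))
    result = e.validate_ecm_set(ecms, val_net, samples)
    assert result == {"steady_state": True, "elementary": True, "decomposable": True}
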