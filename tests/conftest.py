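from fractions import Fraction

import pytest

import ecmenum as e


@pytest.fixture
def box1():
    return e.build_fixture("box1")


@pytest.fixture
def box3():
    return e.build_fixture("box3")


@pytest.fixture
def box3_hidden():
    return e.build_fixture("box3_hidden")


def ecm_key(ecms):
    """Order- and coordinate-name-robust fingerprint of an ECM set."""
    return frozenset(tuple(sorted(c.as_dict().items())) for c in ecms.conversions)


def enumerate_network(net, method="direct", compress=False, **kw):
    ecms, _ = e.run_pipeline(
        e.PipelineConfig(network=net, method=method, compress=compress, **kw)
    )
    return ecms


def conv(ids, **vals):
    return e.Conversion(tuple(ids), tuple(Fraction(vals.get(m, 0)) for m in ids))
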