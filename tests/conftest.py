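import numpy as np
import pytest

import cngrectify as cg


@pytest.fixture(scope="session")
def cs_model():
    return cg.load_preset("cs_like")


@pytest.fixture(scope="session")
def rb_model():
    return cg.load_preset("rb_like")


@pytest.fixture(scope="session")
def na_model():
    return cg.load_preset("na_like")


@pytest.fixture(scope="session")
def wt_dma_model():
    return cg.load_preset("wt_dma")


@pytest.fixture(scope="session")
def tail_protocol():
    """The standard tail family: prepulses −200…+200 mV, tail at −200 mV."""
    return cg.build_tail_protocol(0, -200, 200, 20, 100.0, -200, 5.0)


@pytest.fixture(scope="session")
def flat_po_model(na_model):
    """A channel whose open probability is effectively voltage independent."""
    law = cg.TwoBoltzmann(
        1.0, cg.BoltzmannComponent(-2000.0, 50.0), cg.BoltzmannComponent(-2000.0, 50.0)
    )
    return cg.ChannelModel(
        po_law=law, rate_law=na_model.rate_law, perm=na_model.perm,
        N=10000, name="flat_po",
    )


@pytest.fixture(scope="session")
def slow_two_level_perm(na_model):
    return na_model.perm


def make_counting_model(n_channels, perm, seed_po=0.5):
    """Slow two-state channel at P_o≈0.5 with well-separated unitary levels."""
    law = cg.TwoBoltzmann(
        1.0, cg.BoltzmannComponent(100.0, 25.0), cg.BoltzmannComponent(100.0, 25.0)
    )
    return cg.ChannelModel(
        po_law=law,
        rate_law=cg.RateLaw(0.05, 0.1, 0.05, 0.1),
        perm=perm,
        N=n_channels,
        name=f"counting_{n_channels}",
    )


@pytest.fixture(scope="session")
def vt_mV():
    return cg.CONSTANTS.thermal_mV
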