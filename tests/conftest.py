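import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import irute as ir
from irute.nufft import GriddingNufft

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom64():
    return ir.build_default_phantom(64, n_lesions=4, seed=1)


@pytest.fixture(scope="session")
def seq64():
    return ir.SequenceParams(matrix_size=64)


@pytest.fixture(scope="session")
def sched64_seq():
    return ir.make_schedule(ir.nyquist_spokes(64), 21, "sequential")


@pytest.fixture(scope="session")
def sched64_bit():
    return ir.make_schedule(ir.nyquist_spokes(64), 21, "bit_reversed")


@pytest.fixture(scope="session")
def nufft64():
    return GriddingNufft(64)


@pytest.fixture(scope="session")
def ks64_bit(phantom64, seq64, sched64_bit):
    """Noiseless motion-free dual-echo k-space, bit-reversed ordering."""
    return ir.encode(phantom64, seq64, sched64_bit)


@pytest.fixture(scope="session")
def ks64_seq(phantom64, seq64, sched64_seq):
    return ir.encode(phantom64, seq64, sched64_seq)


@pytest.fixture(scope="session")
def masks64(phantom64):
    return ir.roi_masks(phantom64)


@pytest.fixture(scope="session")
def recon64_full(ks64_bit, nufft64):
    return ir.recon_dual_echo(ks64_bit, nufft=nufft64)
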