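import numpy as np
import pytest

from vipquant.synthetic_data import (
    ColocSimParams,
    IshSimParams,
    SweepSimParams,
    generate_coloc_stack,
    generate_ish_image,
    generate_sweeps,
)


@pytest.fixture(scope="session")
def coloc_default():
    """One default synthetic stack plus its truth (session-cached: the
    3D generator is the slowest fixture)."""
    return generate_coloc_stack(ColocSimParams(seed=1))


@pytest.fixture(scope="session")
def coloc_reference():
    """Independent stack whose puncta channel serves as the histogram-
    matching reference."""
    stack, _ = generate_coloc_stack(ColocSimParams(seed=99))
    return stack.channel("puncta")


@pytest.fixture(scope="session")
def coloc_noise_free():
    params = ColocSimParams(seed=2, snr=np.inf)
    return generate_coloc_stack(params)


@pytest.fixture()
def ish_default():
    return generate_ish_image(IshSimParams(seed=3))


@pytest.fixture()
def sweeps_clean():
    params = SweepSimParams(amp1=-100.0, amp2=-151.0, noise_sigma=0.0, seed=0)
    return generate_sweeps(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
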