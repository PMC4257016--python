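import numpy as np
import pytest

import strokeperf.phantom as ph
from strokeperf.preprocess import ConversionParams, DynamicSeries


@pytest.fixture(scope="session")
def noiseless_spec() -> ph.PhantomSpec:
    return ph.PhantomSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_pwi(noiseless_spec):
    """Rendered noiseless PWI signal plus ground-truth maps."""
    signal, truth = ph.render_pwi(noiseless_spec)
    return signal, truth


@pytest.fixture(scope="session")
def noiseless_series(noiseless_spec, noiseless_pwi) -> DynamicSeries:
    signal, _ = noiseless_pwi
    return DynamicSeries(signal, dt=noiseless_spec.tr, kind="signal",
                         te=noiseless_spec.te)


@pytest.fixture(scope="session")
def noiseless_dwi(noiseless_spec):
    return ph.render_dwi(noiseless_spec)


@pytest.fixture()
def params() -> ConversionParams:
    return ConversionParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140254)
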