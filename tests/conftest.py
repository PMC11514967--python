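import numpy as np
import pytest

from tfdiff.synth import default_core_ppm, generate_dataset, recovery_config, toy_library


@pytest.fixture(scope="session")
def toy_lib():
    return toy_library(10)


@pytest.fixture(scope="session")
def core_ppm():
    return default_core_ppm()


@pytest.fixture(scope="session")
def small_recovery(toy_lib):
    """A small three-signal dataset plus its fitted model, shared read-only."""
    from tfdiff.model import DifferentialBindingModel

    cfg = recovery_config(n_per_class=150, seed=11, library=toy_lib)
    ds = generate_dataset(cfg)
    model = DifferentialBindingModel(ds.windows_a, ds.windows_b,
                                     [cfg.core_ppm], toy_lib)
    res = model.fit(seed=12)
    return ds, model, res


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
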