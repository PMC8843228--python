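import numpy as np
import pytest

from necromap.param_maps import derive_parametric_maps
from necromap.phantom import PhantomConfig, generate_phantom


def small_config(**overrides):
    """A small, fast phantom used by the unit tests (not the default
    study-scale suite, which the acceptance tests build themselves)."""
    kw = dict(shape=(48, 48, 8), spacing=(3.0, 3.0, 5.0),
              tumor_center=(24.0, 24.0, 4.0), tumor_axes=(12.0, 10.0, 3.0),
              necrosis_blob_scale=5.0)
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_case():
    """One derived small phantom (60% necrosis) plus its ground truth."""
    case, truth = generate_phantom(small_config(necrosis_fraction=60.0,
                                                seed=7))
    derive_parametric_maps(case)
    return case, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
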