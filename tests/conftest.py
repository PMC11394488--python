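import numpy as np
import pytest

from damil.keyset import CrlConfig, build_keyset
from damil.model import DamilConfig, init_params
from damil.synthetic import SyntheticCohortSpec, ToySlideSpec, gen_cohort, gen_toy_slide


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticCohortSpec(
        n_rc=8, n_nrc=8, dim=16, n_instances=(5, 10), witness_rate=0.25, seed=1
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return gen_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_keyset(tiny_cohort):
    bags, _ = tiny_cohort
    return build_keyset(bags, CrlConfig(keys_per_slide=2))


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    config = DamilConfig(dim=tiny_spec.dim, hidden_dim=6, gate_dim=4, seed=3)
    return config, init_params(config)


@pytest.fixture(scope="session")
def toy_slide():
    spec = ToySlideSpec(
        width=192,
        height=160,
        tumor_blobs=[((60, 60), 30, (130, 60, 170)), ((140, 100), 24, (130, 60, 170))],
        normal_texture_color=(225, 160, 185),
        seed=4,
    )
    image, tumor, tissue = gen_toy_slide(spec)
    return spec, image, tumor, tissue


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
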