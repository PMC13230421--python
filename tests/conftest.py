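import numpy as np
import pytest

from ct2adc.phantom import PhantomSpec, generate_patient, generate_split


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(image_size=32, n_patients=4, slices_per_patient=3,
                       lesion_probability=0.5, seed=42)


@pytest.fixture(scope="session")
def tiny_slices(tiny_spec):
    out = []
    for p in range(tiny_spec.n_patients):
        out.extend(generate_patient(tiny_spec, p))
    return out


@pytest.fixture(scope="session")
def tiny_split(tiny_spec):
    return generate_split(tiny_spec, 2, 1, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
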