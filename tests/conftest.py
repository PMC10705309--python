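import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_patient():
    """One clean phantom patient (no scanner affine), 64x64x32."""
    from rfseg.phantom import PhantomConfig, clean_config, generate_patient

    cfg = clean_config(PhantomConfig(n_patients=1, seed=42))
    return generate_patient(cfg, 0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six 16^3 phantoms — the smallest cohort that splits 4/1/1."""
    from rfseg.phantom import PhantomConfig, generate_cohort

    cfg = PhantomConfig(shape=(16, 16, 16), n_patients=6,
                        tumor_volume_fraction_range=(0.08, 0.15), seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
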