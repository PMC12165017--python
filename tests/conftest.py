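import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_panel():
    from maldiag import synthgen as sg

    return sg.generate_panel(n_strong=40, n_weak=10, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    from maldiag import synthgen as sg

    cfg = sg.CohortConfig.small(n_per_group=12, n_batches=3, qc_per_batch=2)
    return sg.generate_cohort(cfg, seed=12)
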