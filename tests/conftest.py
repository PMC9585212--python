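import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stratgwas as sg

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20221007)


@pytest.fixture
def small_cohort():
    """600 individuals x 80 null variants with covariate effects on."""
    cfg = sg.SimulationConfig(n_individuals=600, n_variants=80, seed=11)
    return sg.simulate_cohort(cfg)


@pytest.fixture
def tiny_matrix():
    """3 individuals x 2 variants, one missing call."""
    variants = [
        sg.VariantInfo("rs1", "1", 100, "A", "G"),
        sg.VariantInfo("rs2", "2", 500, "C", "T"),
    ]
    dos = np.array([[0, 2], [1, -1], [2, 0]], dtype=np.int8)
    return sg.GenotypeMatrix(variants, dos, ["s1", "s2", "s3"])
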