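import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240922)


@pytest.fixture
def toy_matrix():
    """8 subjects x 10 variants, complete, mixed codes."""
    from fanovatest import GenotypeMatrix, recode_to_minor

    gen = np.random.default_rng(7)
    codes = gen.choice([0.0, 1.0, 2.0], size=(8, 10), p=[0.5, 0.3, 0.2])
    G = GenotypeMatrix(
        codes=codes,
        positions=np.arange(100, 1100, 100),
        groups=np.array(["case"] * 4 + ["control"] * 4),
    )
    return recode_to_minor(G)


@pytest.fixture
def scaled_region(rng):
    """A QC'd, imputed, scaled region big enough for all three smoothers."""
    from fanovatest import SimConfig, simulate_dataset, apply_qc, impute_missing
    from fanovatest import recode_to_minor, scale_positions

    G = simulate_dataset(SimConfig(n_cases=20, n_controls=20, n_variants=60, seed=404))
    G = apply_qc(G)
    G = impute_missing(G, seed=1)
    G = recode_to_minor(G)
    G = apply_qc(G)
    return scale_positions(G)
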