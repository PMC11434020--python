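import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def glai():
    from stempcr.mdre import load_enzyme

    return load_enzyme("GlaI")


@pytest.fixture
def small_matrix():
    """Two-class beta matrix with 3 planted sites among 17 nulls."""
    from stempcr.simulate import EffectProfile, gen_methylation_cohort

    profile = EffectProfile(
        site_ids=[f"cg{i:05d}" for i in range(20)],
        n_differential=3,
        case_mean=0.5,
        control_mean=0.2,
        dispersion=50,
    )
    return gen_methylation_cohort(profile, 40, 40, seed=11)


@pytest.fixture
def stool_cohort():
    from stempcr.simulate import StoolSimSpec, gen_stool_cohort

    return gen_stool_cohort(StoolSimSpec(seed=5))


def rng(seed=0):
    return np.random.default_rng(seed)
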