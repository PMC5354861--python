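import pytest
from hypothesis import HealthCheck, settings

from cernarank import SynthConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Desk-scale generator conditions shared by the quick unit tests."""
    return SynthConfig(
        n_mirnas=60,
        n_lncrnas=40,
        n_mrnas=48,
        n_planted_pairs=20,
        n_network_modules=4,
        module_size=12,
        n_networks=2,
        n_diseases=3,
        seeds_per_disease=3,
        genes_per_profile=4,
        rng_seed=11,
    )
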