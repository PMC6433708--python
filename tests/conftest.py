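import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_run():
    """One synthetic run at seed 1: (config, disease corpus, scale corpus, truth)."""
    from triad_miner.synthetic_corpus import default_config, generate_corpus

    cfg = default_config(seed=1)
    disease, scale, truth = generate_corpus(cfg)
    return cfg, disease, scale, truth


@pytest.fixture(scope="session")
def paper_tables():
    from triad_miner.synthetic_corpus import load_paper_tables

    return load_paper_tables()
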