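import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def name_lexicon():
    """Synthetic gendered-name fixture: 10,000 names, seed 1."""
    from oswb import synthgen
    return synthgen.generate_name_lexicon(10000, seed=1)


@pytest.fixture(scope="session")
def small_corpus():
    """A small but non-trivial synthetic world shared across tests."""
    from oswb import synthgen
    cfg = synthgen.GeneratorConfig(n_months=8, n_users=600, seed=11)
    latent = synthgen.generate_latent_series(cfg)
    return cfg, latent, synthgen.generate_corpus(cfg, latent)
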