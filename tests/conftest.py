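import pytest

from aderelex import synthetic


@pytest.fixture(scope="session")
def synth_cache():
    """Session-wide cache so expensive corpora are generated once."""
    cache = {}

    def get(preset_name="ici-like", seed=1, **overrides):
        key = (preset_name, seed, tuple(sorted(overrides.items())))
        if key not in cache:
            cfg = synthetic.preset(preset_name, seed=seed, **overrides)
            cache[key] = synthetic.generate_corpus(cfg)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def ici_corpus(synth_cache):
    """Default ici-like corpus (seed 1) and its manifest."""
    return synth_cache("ici-like", seed=1)


@pytest.fixture(scope="session")
def perfect_signal_corpus(synth_cache):
    """ici-like corpus with signal_strength 1.0 (perfectly separable)."""
    return synth_cache("ici-like", seed=1, signal_strength=1.0)
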