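import numpy as np
import pytest

from setasim.scenarios import run_scenario


@pytest.fixture(scope="session")
def scenario_runs():
    """Session-wide cache of full scenario runs keyed by (name, seed, overrides).

    The acceptance checks compare many scenarios over shared seeds; caching
    lets every comparison reuse the same runs instead of recomputing them.
    """
    cache = {}

    def get(name: str, seed: int, **overrides):
        key = (name, seed, tuple(sorted(overrides.items())))
        if key not in cache:
            cache[key] = run_scenario(name, seed, overrides=overrides or None)
        return cache[key]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(42)
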