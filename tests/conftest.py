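import pytest

from nhaneskit.catalog import fetch_codebook, fetch_table
from nhaneskit.config import Config
from nhaneskit.fixtures import PopulationSpec, install_fixtures
from nhaneskit.translate import translate_table


@pytest.fixture(scope="session")
def spec():
    return PopulationSpec()


@pytest.fixture(scope="session")
def fixture_cache(tmp_path_factory, spec):
    """One synthetic fixture set (XPT + codebooks + manifest + truth) per session."""
    cache = tmp_path_factory.mktemp("cache")
    truth = install_fixtures(cache, spec)
    return cache, truth


@pytest.fixture(scope="session")
def config(fixture_cache):
    return Config(cache_dir=fixture_cache[0], offline=True)


@pytest.fixture(scope="session")
def truth(fixture_cache):
    return fixture_cache[1]


@pytest.fixture(scope="session")
def demo_translated(config):
    return translate_table(fetch_table("DEMO_J", config), fetch_codebook("DEMO_J", config))


@pytest.fixture(scope="session")
def bpx_translated(config):
    return translate_table(fetch_table("BPX_J", config), fetch_codebook("BPX_J", config))


@pytest.fixture(scope="session")
def bpq_codebook(config):
    return fetch_codebook("BPQ_J", config)


@pytest.fixture()
def bpq_translated(config, bpq_codebook):
    # function-scoped: skip-fill tests mutate the table
    return translate_table(fetch_table("BPQ_J", config), bpq_codebook)
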