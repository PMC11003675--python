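import numpy as np
import pytest

from serann.config import tiny_config
from serann.netspec import Vocabulary
from serann.specgen import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary.default()


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_config(seed=0)


@pytest.fixture(scope="session")
def default_gen_cfg():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def tiny_gen_cfg(tiny_cfg):
    return tiny_cfg.generator_config()


@pytest.fixture(scope="session")
def small_corpus(default_gen_cfg):
    """50 generated specs under the shipped default configuration."""
    return generate_corpus(50, default_gen_cfg, rng=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
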