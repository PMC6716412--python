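import dataclasses

import pytest

import countysae as cs


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic two-survey world shared by cheap tests."""
    cfg = cs.GeneratorConfig(m_counties=60, seed=42)
    counties = cs.generate_counties(cfg)
    nhis = cs.sample_nhis(counties, cfg)
    brfss = cs.sample_brfss(counties, cfg)
    return cfg, counties, nhis, brfss


@pytest.fixture()
def tiny_config():
    return cs.GeneratorConfig(m_counties=12, seed=7)


def make_config(**kwargs) -> cs.GeneratorConfig:
    return cs.GeneratorConfig(**kwargs)
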