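from __future__ import annotations

import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from sherdmix import PipelineConfig, SherdRecord, default_sources

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig().validate()


@pytest.fixture(scope="session")
def sources4():
    """maize, marine, C3_plant, ruminant default references."""
    return default_sources()


@pytest.fixture(scope="session")
def sources3(sources4):
    """maize, marine, ruminant — the 3-source fixture used by the oracles."""
    by_name = {s.source_name: s for s in sources4}
    return [by_name["maize"], by_name["marine"], by_name["ruminant"]]


@pytest.fixture
def fast_mcmc_cfg(cfg) -> PipelineConfig:
    return dataclasses.replace(cfg, n_chains=4, n_iter=1500, n_burn=800, seed=11)


def make_record(sample_id="S1", **kwargs) -> SherdRecord:
    defaults = dict(
        site="siteA",
        tradition="Guarani",
        decoration="plain",
        lipid_yield=20.0,
        abundances={},
        d13c={},
    )
    defaults.update(kwargs)
    return SherdRecord(sample_id=sample_id, **defaults)


@pytest.fixture
def record_factory():
    return make_record
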