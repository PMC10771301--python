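"""Shared fixtures: one moderately sized synthetic bundle per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from faers_signals.ingest import load_clean_bundle, read_soc_map
from faers_signals.synthetic import GeneratorConfig, PlantedSignal, generate_bundle

SYNONYMS = ("MEPOLIZUMAB", "NUCALA")

#: planted drug-event excesses used by most integration tests
PLANTED = (
    PlantedSignal("Asthmatic crisis", 10.0),
    PlantedSignal("Pneumonia", 5.0),
    PlantedSignal("Headache", 3.0, female_rate_multiplier=4.0),
)


@pytest.fixture(scope="session")
def bundle_cfg() -> GeneratorConfig:
    return GeneratorConfig(n_reports=12_000, seed=11, planted_signals=PLANTED,
                           duplicate_rate=0.08)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, bundle_cfg):
    """(directory, ground truth) of the session's main synthetic bundle."""
    d = tmp_path_factory.mktemp("bundle")
    truth = generate_bundle(bundle_cfg, d)
    return d, truth


@pytest.fixture(scope="session")
def dataset(bundle):
    d, _ = bundle
    return load_clean_bundle(d, SYNONYMS)


@pytest.fixture(scope="session")
def soc_map(bundle):
    d, _ = bundle
    return read_soc_map(d / "pt_soc_map.txt")
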