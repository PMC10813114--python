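"""Shared fixtures: full-scale replicates are expensive, so each experiment
configuration is simulated once per session and reused across tests."""

from __future__ import annotations

import pytest

from floodsim import default_config, replicate, summarize


def make_config(profile="esc", policy="encouraging", scenario="independent",
                free_rider_fraction=0.0, **overrides):
    cfg = default_config()
    cfg.policy = policy
    cfg.scenario = scenario
    if free_rider_fraction > 0:
        cfg.profile_mix = {profile: 1.0 - free_rider_fraction,
                           "free_rider": free_rider_fraction}
    else:
        cfg.profile_mix = {profile: 1.0}
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def _replicated(profile, policy, scenario="independent", free_rider_fraction=0.0,
                n_runs=100, seed=11):
    cfg = make_config(profile, policy, scenario, free_rider_fraction)
    result = replicate(cfg, n_runs=n_runs, seed=seed)
    return result, summarize(result)


@pytest.fixture(scope="session")
def random_enc():
    return _replicated("random", "encouraging")


@pytest.fixture(scope="session")
def random_pun():
    return _replicated("random", "punitive")


@pytest.fixture(scope="session")
def ap_enc():
    return _replicated("ap", "encouraging")


@pytest.fixture(scope="session")
def apc_enc():
    return _replicated("apc", "encouraging")


@pytest.fixture(scope="session")
def es_enc():
    return _replicated("es", "encouraging")


@pytest.fixture(scope="session")
def esc_enc():
    return _replicated("esc", "encouraging")


@pytest.fixture(scope="session")
def esc_pun():
    return _replicated("esc", "punitive")


@pytest.fixture(scope="session")
def s2_esc_enc():
    return _replicated("esc", "encouraging", scenario="interdependent")


@pytest.fixture(scope="session")
def s2_freerider_enc():
    return _replicated("esc", "encouraging", scenario="interdependent",
                       free_rider_fraction=0.2)
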