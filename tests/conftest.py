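"""Shared fixtures: generator configurations used across the suite."""

import dataclasses

import pytest

from mvtforage import SimulationConfig


@pytest.fixture
def subset_config():
    """Study-condition records generated directly inside the MVT subset.

    All filter attributes are forced true and no key field is blanked, so
    every generated record survives preprocessing; noise and rounding stay
    at their defaults.
    """

    def make(n: int = 61, seed: int = 0, **overrides) -> SimulationConfig:
        return SimulationConfig(
            n=n,
            seed=seed,
            p_main_patch=1.0,
            p_home_roundtrip=1.0,
            p_foot=1.0,
            p_missing_key=0.0,
            **overrides,
        )

    return make


@pytest.fixture
def noise_free_config(subset_config):
    """Records lying exactly on the generating gain curve."""

    def make(n: int = 40, seed: int = 0, **overrides) -> SimulationConfig:
        cfg = subset_config(n=n, seed=seed, **overrides)
        return dataclasses.replace(
            cfg, sigma_T=0.0, sigma_t=0.0, sigma_g=0.0,
            round_T=0.0, round_t=0.0, round_g=0.0,
        )

    return make
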