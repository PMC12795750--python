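import numpy as np
import pandas as pd
import pytest

from noisequity.synthetic_data import (
    GeneratorConfig,
    OCC_GROUPS,
    generate_geography,
    generate_jem,
    generate_structural,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_metro_areas=2,
        tracts_per_metro=40,
        nonmetro_tracts=20,
        blocks_per_tract=(2, 4),
        mean_tract_population=2000,
        beta_transport=4.0,
        beta_occupation=1.0,
        redline_fraction=0.5,
        discrimination_fraction=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_geography(small_config):
    tracts, blocks, truth = generate_geography(small_config)
    return tracts, blocks, truth


@pytest.fixture(scope="session")
def small_jem(small_config):
    return generate_jem(OCC_GROUPS, small_config)


@pytest.fixture(scope="session")
def small_structural(small_config, small_geography):
    tracts, _, _ = small_geography
    return generate_structural(tracts, small_config)


def make_blocks(levels, populations, tract_id="T1"):
    """Hand-built single-tract block table."""
    return pd.DataFrame({
        "block_id": [f"{tract_id}-B{i}" for i in range(len(levels))],
        "tract_id": tract_id,
        "population": populations,
        "laeq_24h": levels,
    })


def brute_force_err(omega, p, t):
    """Independent scalar-loop evaluation of the displayed ERR formula."""
    num_top = num_bot = den_top = den_bot = 0.0
    for w_i, p_i, t_i in zip(omega, p, t):
        num_top += w_i * p_i
        num_bot += p_i
        den_top += w_i * t_i
        den_bot += t_i
    return (num_top / num_bot) / (den_top / den_bot)
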