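import pytest

from fishmerc.hgdb import load_group_attributes, pool_table, records_from_frame
from fishmerc.synth import (
    default_config,
    simulate_catches,
    simulate_hg_records,
    simulate_supply,
)


@pytest.fixture(scope="session")
def sim_config():
    return default_config(seed=1)


@pytest.fixture(scope="session")
def group_attrs():
    return load_group_attributes()


@pytest.fixture(scope="session")
def catches_df(sim_config):
    return simulate_catches(sim_config)


@pytest.fixture(scope="session")
def hg_records(sim_config):
    return records_from_frame(simulate_hg_records(sim_config))


@pytest.fixture(scope="session")
def conc_table(hg_records, group_attrs):
    return pool_table(hg_records, group_attrs)


@pytest.fixture(scope="session")
def supply_and_profiles(sim_config):
    return simulate_supply(sim_config)
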