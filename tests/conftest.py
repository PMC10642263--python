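"""Shared fixtures: the default configuration and its base-case results."""

import pytest

from npc_cea import build_model, compare, load_config, run_totals


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def base_model(config):
    """(intervention ArmSpec, comparator ArmSpec, ModelSettings)."""
    return build_model(config)


@pytest.fixture(scope="session")
def base_totals(base_model):
    tc, chemo, settings = base_model
    return run_totals(tc, settings), run_totals(chemo, settings)


@pytest.fixture(scope="session")
def base_comparison(base_model, base_totals):
    tc, chemo, settings = base_model
    tot_tc, tot_chemo = base_totals
    return compare(tot_tc, tot_chemo, settings.wtp, tc.name, chemo.name)
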