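import numpy as np
import pytest

import transposim as tp


@pytest.fixture(scope="session")
def in_vitro_table():
    return tp.derive_parameter_table(tp.preset_inputs("in_vitro"))


@pytest.fixture(scope="session")
def in_vivo_table(in_vitro_table):
    return tp.derive_parameter_table(
        tp.preset_inputs("in_vivo"), k_act=in_vitro_table.k_act
    )


@pytest.fixture(scope="session")
def allosteric_invivo_traj():
    """The crowded-nucleus allosteric invasion, shared across tests."""
    return tp.run_invasion(tp.get_scenario("snec_invivo_allosteric"))


@pytest.fixture(scope="session")
def spd_baseline_traj():
    return tp.run_invasion(tp.get_scenario("spd_invitro"))


def rel_err(value, expected):
    return abs(value - expected) / abs(expected)


@pytest.fixture(scope="session")
def two_sf():
    """Relative tolerance matching values printed to two significant figures."""
    return 0.05
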