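import numpy as np
import pytest

import dyncubeprod as dcp


@pytest.fixture(scope="session")
def toy():
    return dcp.build_toy_network()


@pytest.fixture(scope="session")
def toy_maxima(toy):
    return dcp.compute_theoretical_maxima(toy, min_growth=1.0)


@pytest.fixture(scope="session")
def toy_params():
    return dcp.SearchParams(min_growth=1.0, min_target=1.0)


@pytest.fixture(scope="session")
def random_net7():
    """Small irreversible random network used with the rational oracle."""
    return dcp.generate_random_network(4, 8, seed=7)


def random_params(model):
    """Study-condition thresholds for a generated network: half / quarter of
    the fixed influx."""
    u = float(model.LB[model.reaction_index("R_uptake")])
    return dcp.SearchParams(min_growth=u / 2.0, min_target=u / 4.0)
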