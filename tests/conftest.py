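"""Shared fixtures.  Expensive PBK simulations are session-scoped so the
forward-prediction, metric and mass-balance tests reuse the same runs."""

import numpy as np
import pytest

from qivive.parameters import DoseRegimen, build_default_model
from qivive.pbk import simulate


@pytest.fixture(scope="session")
def default_params():
    return build_default_model()


@pytest.fixture(scope="session")
def result_70mg_74kg(default_params):
    """60-day repeated dosing, the first clinical evaluation scenario."""
    params = default_params.updated({"BW": 74.0})
    return simulate(params, DoseRegimen(70.0, n_days=60))


@pytest.fixture(scope="session")
def result_200mg_70kg(default_params):
    """High-dose scenario used for the EDDP exposure screen."""
    return simulate(default_params, DoseRegimen(200.0),
                    until_steady_state=True)


@pytest.fixture(scope="session")
def noise_free_crc():
    from qivive.mea import concentration_response
    from qivive.synthetic import MeaCrcConfig, gen_mea_crc

    wells, truth = gen_mea_crc(MeaCrcConfig(
        seed=1, response_noise_cv=0.0, well_variability_sd=0.0))
    return concentration_response(wells), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
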