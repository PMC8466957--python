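"""Shared fixtures: one synthetic angiogram with ground truth, one cohort.

The image fixtures are session-scoped because growing the capillary
network is the slowest part of the suite; tests must not mutate them.
"""

import numpy as np
import pytest

from lmh_octa import binarize as B
from lmh_octa import synthdata as S


@pytest.fixture(scope="session")
def sim_config():
    return S.SimulationConfig(seed=7, noise_sd=0.02)


@pytest.fixture(scope="session")
def ground_truth(sim_config):
    faz = S.generate_faz_polygon(
        sim_config.faz_area_mm2, sim_config.faz_circularity, seed=7
    )
    return S.generate_vessel_network(sim_config, faz, seed=7)


@pytest.fixture(scope="session")
def angiogram(ground_truth, sim_config):
    return S.render_angiogram(ground_truth, sim_config, seed=8)


@pytest.fixture(scope="session")
def segmented(angiogram):
    return B.binarize_angiogram(angiogram)


@pytest.fixture(scope="session")
def cohort():
    return S.simulate_cohort(S.SimulationConfig(seed=11), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
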