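"""Shared fixtures: reference parameters and moderately sized ensembles.

Ensemble fixtures are session-scoped and shared across feature, pattern and
acceptance tests; 200 replicates is the scaled-down stand-in for the
1000-replicate study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

import nfkbse as nk

ENSEMBLE_N = 200
CHI = 0.3
SEED = 11


@pytest.fixture(scope="session")
def params_nominal() -> nk.ParameterSet:
    return nk.load_parameter_table(column="nominal")


@pytest.fixture(scope="session")
def params_fitted() -> nk.ParameterSet:
    return nk.load_parameter_table(column="fitted")


@pytest.fixture(scope="session")
def protocol_10h() -> nk.StimulusProtocol:
    return nk.StimulusProtocol(TR=1.0, t_stimulate_h=10.0)


@pytest.fixture(scope="session")
def wt_trajectory(params_nominal, protocol_10h) -> nk.Trajectory:
    """Single wild-type reference trajectory at TR = 1."""
    return nk.simulate_response(params_nominal, protocol_10h)


@pytest.fixture(scope="session")
def wt_ensemble(params_nominal, protocol_10h) -> nk.Ensemble:
    return nk.simulate_ensemble(
        params_nominal, protocol=protocol_10h, n=ENSEMBLE_N, chi=CHI, seed=SEED
    )


@pytest.fixture(scope="session")
def bkeko_ensemble(params_nominal, protocol_10h) -> nk.Ensemble:
    return nk.simulate_ensemble(
        params_nominal, genotype=nk.Genotype.parse(["IkBb", "IkBe"]),
        protocol=protocol_10h, n=ENSEMBLE_N, chi=CHI, seed=SEED,
    )


@pytest.fixture(scope="session")
def small_dose_ensemble(params_nominal) -> nk.Ensemble:
    proto = nk.StimulusProtocol(TR=0.01, t_stimulate_h=10.0)
    return nk.simulate_ensemble(
        params_nominal, protocol=proto, n=ENSEMBLE_N, chi=CHI, seed=SEED
    )


@pytest.fixture(scope="session")
def wt_features(wt_ensemble):
    return nk.ensemble_features(wt_ensemble)


@pytest.fixture(scope="session")
def bkeko_features(bkeko_ensemble):
    return nk.ensemble_features(bkeko_ensemble)
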