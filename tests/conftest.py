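"""Shared fixtures: small synthetic sessions and trace builders.

Session fixtures are session-scoped because featurizing an LFP recording
is the expensive step; tests treat them as read-only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from stnmes import behavior as bhv
from stnmes import mes as mes_mod
from stnmes.behavior import Trace
from stnmes.spectral import epoch_spectral_features, preprocess_lfp
from stnmes.synth import GeneratorConfig, simulate_session


def make_trace(x, y, fs=1000.0, role="cursor") -> Trace:
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) / fs
    return Trace(t=t, x=x, y=np.asarray(y, dtype=float), fs=fs, role=role)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(duration=300.0)


@pytest.fixture(scope="session")
def pd_session(default_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_session(default_config, group="PD", seed=11, subject_id="PD00")


@pytest.fixture(scope="session")
def control_session(default_config):
    return simulate_session(
        default_config, group="control", seed=12, subject_id="CTRL", with_lfp=False
    )


@pytest.fixture(scope="session")
def metric_matrices(pd_session, control_session):
    pd_mm = bhv.metrics_from_traces(pd_session.cursor, pd_session.target, 7.0, group="PD")
    ct_mm = bhv.metrics_from_traces(
        control_session.cursor, control_session.target, 7.0, group="control"
    )
    return pd_mm, ct_mm


@pytest.fixture(scope="session")
def mes_model(metric_matrices):
    pd_mm, ct_mm = metric_matrices
    return mes_mod.fit_mes_model(pd_mm, ct_mm, seed=5)


@pytest.fixture(scope="session")
def pd_mes(mes_model, metric_matrices):
    return mes_mod.score_mes(mes_model, metric_matrices[0])


@pytest.fixture(scope="session")
def pd_features(pd_session):
    clean = preprocess_lfp(pd_session.lfp)
    return epoch_spectral_features(clean, 7.0)
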