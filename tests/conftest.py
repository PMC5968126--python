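"""Shared fixtures: all data is generated programmatically at session scope."""

from __future__ import annotations

import numpy as np
import pytest

from fibrofocal import atlas as at
from fibrofocal import experiments as ex
from fibrofocal import ionic
from fibrofocal import mlpipe as ml
from fibrofocal.config import ExperimentConfig


@pytest.fixture(scope="session")
def la_params():
    return ionic.MyocyteParams.from_region("LA")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale configuration used by the geometry/pipeline tests."""
    return ExperimentConfig(atlas_subdivisions=3, torso_nodes=3000,
                            fast_svm=True, seed=3)


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return at.build_atlas(subdivisions=small_config.atlas_subdivisions,
                          torso_nodes=small_config.torso_nodes,
                          rng_seed=small_config.seed)


@pytest.fixture(scope="session")
def ap_template(small_config):
    return ex.ap_template(small_config)


@pytest.fixture(scope="session")
def all_datasets(small_config):
    """Atlas + fibrosis library + datasets M0..M5 at desk scale."""
    return ex.build_all_datasets(small_config)


@pytest.fixture(scope="session")
def m0_dataset(all_datasets):
    return all_datasets[2]["M0"]


@pytest.fixture(scope="session")
def electrode_layout(small_atlas):
    return ml.reduce_electrodes(small_atlas.torso, 256, rng_seed=0)


@pytest.fixture(scope="session")
def all_features(all_datasets, electrode_layout, ap_template, small_config):
    """BSPiM feature tables (runs x 256) for every dataset model."""
    _, _, datasets = all_datasets
    out = {}
    for m, ds in datasets.items():
        out[m] = ex.bspim_features(ds, electrode_layout, ap_template,
                                   small_config)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
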