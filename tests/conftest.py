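"""Shared fixtures: synthetic scenes and cohorts generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hyperflux.io_core import Group
from hyperflux.pipeline import analyse_cohort
from hyperflux.preprocess import preprocess_stack
from hyperflux.synth import (
    DEFAULT_EFFECT_TABLE,
    CohortSpec,
    GroupEffect,
    SceneParams,
    make_cohort,
    make_endmembers,
    make_scene,
)
from hyperflux.unmix import fit_blind_unmixing

SCENE_SEED = 7
COHORT_SEED = 11
NULL_SEED = 5


@pytest.fixture(scope="session")
def endmembers69():
    return make_endmembers(69, seed=SCENE_SEED)


@pytest.fixture(scope="session")
def default_scene(endmembers69):
    """128x128, 69-channel scene at 30 dB SNR with full corruption."""
    return make_scene(
        SceneParams(), endmembers69, DEFAULT_EFFECT_TABLE[Group.RA_MID], seed=SCENE_SEED
    )


@pytest.fixture(scope="session")
def preprocessed_scene(default_scene):
    stack, bf, _truth = default_scene
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean, qc = preprocess_stack(stack, bf)
    return clean, qc


@pytest.fixture(scope="session")
def blind_fit(preprocessed_scene):
    clean, _ = preprocessed_scene
    return fit_blind_unmixing(clean, n_components=3, seed=SCENE_SEED, n_restarts=10)


@pytest.fixture(scope="session")
def default_cohort():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_cohort(CohortSpec(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_table(default_cohort):
    """Feature table from the full preprocess/segment/unmix chain."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, spectra, qc = analyse_cohort(default_cohort, seed=COHORT_SEED)
    return table


@pytest.fixture(scope="session")
def null_cohort_table():
    """Cohort with identical effect means in every group (no signal)."""
    effects = {g: GroupEffect((0.30, 0.30, 0.30)) for g in DEFAULT_EFFECT_TABLE}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # patient_cv=0 makes ROIs exchangeable across patients: the null
        # hypothesis of zero separation between the pooled sides
        entries = make_cohort(
            CohortSpec(seed=NULL_SEED, effect_table=effects, patient_cv=0.0)
        )
        table, _, _ = analyse_cohort(entries, seed=NULL_SEED)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
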