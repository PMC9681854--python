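"""Shared fixtures: a small synthetic world, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from plankshift.classify import classify_lifestyles
from plankshift.identity import classify_table
from plankshift.occurrence import fit_all, station_presence
from plankshift.simulate import WorldSpec, gen_motu_world

SMALL_MOTUS = {
    "Spinose": 12,
    "Non-Spinose": 12,
    "Microperforates": 12,
    "Basal": 12,
    "Monothalamea": 10,
    "Tubothalamea": 10,
    "Globothalamea": 30,
}


@pytest.fixture(scope="session")
def small_spec() -> WorldSpec:
    return WorldSpec(
        n_stations=60,
        n_motus_per_category=dict(SMALL_MOTUS),
        n_refs_per_category=3,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_world(small_spec):
    return gen_motu_world(small_spec)


@pytest.fixture(scope="session")
def small_assignments(small_world):
    return classify_table(
        small_world.motu_sequences, small_world.reference_db,
        table=small_world.occurrence,
    )


@pytest.fixture(scope="session")
def small_presence(small_world):
    return station_presence(small_world.occurrence, small_world.metadata)


@pytest.fixture(scope="session")
def small_fits(small_presence):
    return fit_all(small_presence)


@pytest.fixture(scope="session")
def small_classification(small_assignments, small_presence, small_fits):
    return classify_lifestyles(
        small_assignments, small_presence, small_fits, n_trees=200, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
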