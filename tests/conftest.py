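"""Shared fixtures: the bundled catalog with synthetic stand-in sequences and
a prebuilt, calibrated search profile for the most-used clade."""

import pytest
from hypothesis import settings

from phytascan.catalog import load_catalog
from phytascan.profiles import build_profile, calibrate_evalues
from phytascan.synthetic import attach_synthetic_sequences

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def reps(catalog):
    """clade_id -> representative enzyme with synthetic stand-in sequence."""
    return {e.clade_id: e for e in attach_synthetic_sequences(catalog)}


@pytest.fixture(scope="session")
def abl(reps):
    return reps["BPP_ABL"]


@pytest.fixture(scope="session")
def abl_profile(abl):
    return build_profile([abl.sequence], 1.0, clade_label="BPP_ABL", family="BPP")


@pytest.fixture(scope="session")
def abl_calibration(abl_profile):
    return calibrate_evalues(abl_profile, n_random=300, seed=123)
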