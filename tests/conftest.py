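import numpy as np
import pytest

import aptrial as ap
from aptrial.config import default_compounds_path, default_ranges_path
from aptrial.population import CalibrationRanges, calibrate, sample_scalings


@pytest.fixture(scope="session")
def toy_model():
    return ap.get_model("toy-fast")


@pytest.fixture(scope="session")
def ord_model():
    return ap.get_model("ORd-endo")


@pytest.fixture(scope="session")
def human_ranges():
    return CalibrationRanges.from_yaml(default_ranges_path())


@pytest.fixture(scope="session")
def compound_records():
    return ap.read_compound_table(default_compounds_path())


@pytest.fixture(scope="session")
def toy_population(toy_model, human_ranges):
    """Small calibrated toy population shared across trial-level tests."""
    candidates = sample_scalings(40, seed=7)
    population, report = calibrate(candidates, toy_model, ranges=human_ranges)
    assert population.n_mod > 0
    return population


@pytest.fixture(scope="session")
def toy_control(toy_population, toy_model):
    return ap.run_control(toy_population, toy_model)
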