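import numpy as np
import pytest

from csiatrace.config import load_config
from csiatrace.core_io import Element, default_registry
from csiatrace.synthetic import CohortSpec, InstrumentModel, ParameterTable


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def config():
    return load_config("paper_defaults")


@pytest.fixture
def quiet_instrument():
    """Noise-free, drift-free, identity-response instrument (delta_d still
    distinct from tissue values, so the carbon mixing is non-trivial)."""
    return InstrumentModel(
        derivatization_delta={"default": -30.0},
        nitrogen_response=(0.0, 1.0),
        drift_slope={Element.C13: 0.0, Element.N15: 0.0},
        noise_sd={Element.C13: 0.0, Element.N15: 0.0},
    )


@pytest.fixture
def tiny_table():
    """Two-treatment, one-compartment table plus prey, nitrogen only."""
    rows = [
        {"treatment": "autotrophy", "compartment": "symbiont", "aa": "Glu", "element": "N15", "mean": 3.71, "sd": 1.23},
        {"treatment": "autotrophy", "compartment": "symbiont", "aa": "Phe", "element": "N15", "mean": 3.72, "sd": 1.21},
        {"treatment": "heterotrophy", "compartment": "symbiont", "aa": "Glu", "element": "N15", "mean": 12.65, "sd": 2.19},
        {"treatment": "heterotrophy", "compartment": "symbiont", "aa": "Phe", "element": "N15", "mean": 8.10, "sd": 1.82},
        {"treatment": "prey", "compartment": "prey", "aa": "Glu", "element": "N15", "mean": 14.17, "sd": 0.22},
        {"treatment": "prey", "compartment": "prey", "aa": "Phe", "element": "N15", "mean": 8.03, "sd": 0.04},
    ]
    return ParameterTable.from_records(rows)


@pytest.fixture
def tiny_spec(tiny_table):
    return CohortSpec(
        parameter_table=tiny_table,
        n_colonies=3,
        treatments=("autotrophy", "heterotrophy"),
        compartments=("symbiont",),
        n_prey=2,
    )
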