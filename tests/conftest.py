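import dataclasses

import numpy as np
import pandas as pd
import pytest

import seronet as sn


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic cohort shared across read-only tests."""
    return sn.simulate_bead_array(sn.SimulationConfig(rng_seed=11))


@pytest.fixture(scope="session")
def pipeline(dataset):
    return sn.preprocess_pipeline(dataset.plate, dataset.clinical)


@pytest.fixture(scope="session")
def clinical_t(dataset):
    return sn.transform_clinical(dataset.clinical)


def make_plate(mfi, well_role, analyte_role):
    return sn.RawPlate(
        mfi=mfi,
        well_role=pd.Series(well_role, index=mfi.index),
        analyte_role=pd.Series(analyte_role, index=mfi.columns),
    )


@pytest.fixture()
def tiny_plate():
    """2 samples + 2 empty wells, 3 antigens + 1 control."""
    mfi = pd.DataFrame(
        [
            [500.0, 300.0, 150.0, 900.0],
            [400.0, 250.0, 100.0, 850.0],
            [10.0, 10.0, 10.0, 12.0],
            [10.0, 10.0, 10.0, 8.0],
        ],
        index=["S1", "S2", "E1", "E2"],
        columns=["A1", "A2", "A3", "CTRL"],
    )
    return make_plate(
        mfi,
        ["sample", "sample", "empty", "empty"],
        ["antigen", "antigen", "antigen", "control_positive"],
    )
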