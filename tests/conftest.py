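import numpy as np
import pandas as pd
import pytest

import occscreen as oc
from occscreen.synth import SynthConfig


@pytest.fixture
def example_raw() -> pd.DataFrame:
    """Six bat records with renamed columns, exercising the field mapping."""
    raw = oc.example_records()
    return raw.rename(columns={"species": "Species", "identifier": "Identifier"})


@pytest.fixture
def example_mapping() -> dict:
    return {"species": "Species", "x": "x", "y": "y", "year": "year",
            "spatialUncertainty": "spatialUncertainty", "identifier": "Identifier"}


@pytest.fixture
def example_tab(example_raw, example_mapping) -> oc.OccurrenceTable:
    return oc.validate_occurrences(example_raw, example_mapping)


@pytest.fixture(scope="session")
def decades() -> oc.PeriodSet:
    return oc.decadal_periods()


@pytest.fixture(scope="session")
def unbiased_tab(decades) -> oc.OccurrenceTable:
    """Seeded clean reference dataset, period-assigned, shared across tests."""
    tab = oc.gen_unbiased(SynthConfig(seed=20240901))
    return oc.assign_periods(tab, decades)


@pytest.fixture(scope="session")
def unit_mask() -> oc.StudyMask:
    return oc.StudyMask.rectangle(0.0, 1.0, 0.0, 1.0, cell_size=0.1)


@pytest.fixture(scope="session")
def square_mask_100() -> oc.StudyMask:
    return oc.StudyMask.rectangle(0.0, 100.0, 0.0, 100.0, cell_size=10.0)
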