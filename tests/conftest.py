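import dataclasses

import pytest

from plasmokan.cohort import CohortDesign, SensorConfig, generate_dataset, sample_cohort


@pytest.fixture(scope="session")
def tiny_design() -> CohortDesign:
    """40-subject cohort with the default class mix, fixed seed."""
    return dataclasses.replace(CohortDesign().scaled(40), seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design):
    """400-record dataset (40 subjects x 2 markers x 5 replicates)."""
    return generate_dataset(sample_cohort(tiny_design), SensorConfig(), tiny_design)


@pytest.fixture(scope="session")
def noiseless_sensor() -> SensorConfig:
    return dataclasses.replace(SensorConfig(), sigma_reflectance=0.0, baseline_tilt=0.0)
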