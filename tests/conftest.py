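import numpy as np
import pytest

from guildflow.design import StudyDesign


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """One group of six participants — enough for consensus support rules."""
    return StudyDesign(groups=("overweight",), participants_per_group=6)


@pytest.fixture(scope="session")
def ten_design() -> StudyDesign:
    return StudyDesign(groups=("overweight",), participants_per_group=10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
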