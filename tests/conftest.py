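import pytest

from tcmbmd import CalibrationTable, ForwardModel, default_calibration


@pytest.fixture(scope="session")
def table() -> CalibrationTable:
    return default_calibration()


@pytest.fixture(scope="session")
def calib120(table):
    return table[120]


@pytest.fixture(scope="session")
def model120(calib120) -> ForwardModel:
    return ForwardModel.from_calibration(calib120)
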