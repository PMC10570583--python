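import numpy as np
import pytest

from smcrisk import us2019_fixture

# Printed case-study values used across the suite (US road crashes, 2019).
PRINTED_SUMS = {
    "environment": {"R1": 8.4, "R2": 22.6, "R3": 40.8, "R4": 25.3},
    "driver_state": {"R5": 18.2, "R6": 2.0},
    "driver_behavior": {"R7": 17.9, "R8": 8.8, "R9": 12.0},
}

PRINTED_SUB_PCMS = {
    "environment": (
        ["R1", "R2", "R3", "R4"],
        np.array(
            [
                [1, 1 / 3, 1 / 5, 1 / 3],
                [3, 1, 1 / 2, 1],
                [5, 2, 1, 2],
                [3, 1, 1 / 2, 1],
            ]
        ),
    ),
    "driver_state": (["R5", "R6"], np.array([[1, 9], [1 / 9, 1]])),
    "driver_behavior": (
        ["R7", "R8", "R9"],
        np.array([[1, 2, 2], [1 / 2, 1, 1 / 2], [1 / 2, 2, 1]]),
    ),
}

PRINTED_LOCAL_WEIGHTS = {
    "criteria": {"C1": 0.101, "C2": 0.433, "C3": 0.466},
    "C1": {"R1": 0.082, "R2": 0.235, "R3": 0.448, "R4": 0.235},
    "C2": {"R5": 0.900, "R6": 0.100},
    "C3": {"R7": 0.493, "R8": 0.196, "R9": 0.311},
}

PRINTED_GLOBALS = {
    "R1": 0.008, "R2": 0.024, "R3": 0.045, "R4": 0.024, "R5": 0.390,
    "R6": 0.043, "R7": 0.230, "R8": 0.091, "R9": 0.145,
}

PRINTED_RANKS = {
    "R5": 1, "R7": 2, "R9": 3, "R8": 4, "R3": 5, "R6": 6, "R2": 7,
    "R4": 7, "R1": 9,
}


@pytest.fixture(scope="session")
def us2019():
    return us2019_fixture()


@pytest.fixture(scope="session")
def us2019_severity(us2019):
    return us2019[0]


@pytest.fixture(scope="session")
def us2019_evidence(us2019):
    return us2019[1]


@pytest.fixture(scope="session")
def us2019_config(us2019):
    return us2019[2]
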