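import math

import numpy as np
import pytest
from hypothesis import settings

from platescreen import (
    AnalysisConfig,
    ScreenDataset,
    WellAddress,
    WellRecord,
    WellRole,
    WellStatus,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def config():
    return AnalysisConfig()


def make_plate(
    test_readings,
    positive_readings=(),
    negative_readings=(),
    plate_id="P1",
    replicate=1,
    min_reference=None,
):
    """Build one plate-replicate's WellRecords from raw reading lists."""
    wells = []
    i = 0
    for value in test_readings:
        addr = WellAddress(chr(ord("A") + i % 8), 4 + i // 8)
        status = WellStatus.OK if value is not None else WellStatus.DEAD
        wells.append(
            WellRecord(
                plate_id, addr, WellRole.TEST, f"C{i:03d}", 10.0,
                status=status, fluorescence=value, replicate=replicate,
            )
        )
        i += 1
    for j, value in enumerate(positive_readings):
        addr = WellAddress(chr(ord("A") + j % 8), 1 + j // 8)
        wells.append(
            WellRecord(
                plate_id, addr, WellRole.POSITIVE_CONTROL, "riluzole", 10.0,
                status=WellStatus.OK, fluorescence=value, replicate=replicate,
            )
        )
    for j, value in enumerate(negative_readings):
        addr = WellAddress(chr(ord("A") + j % 8), 12 - j // 8)
        wells.append(
            WellRecord(
                plate_id, addr, WellRole.NEGATIVE_CONTROL, "DMSO", 0.0,
                status=WellStatus.OK, fluorescence=value, replicate=replicate,
            )
        )
    return wells


@pytest.fixture
def small_config():
    return AnalysisConfig(min_reference_size=4)
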