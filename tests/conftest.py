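import numpy as np
import pytest

from respirotools import (
    ChamberSpec,
    CycleSchedule,
    FishPhysiology,
    FishRecord,
    Protocol,
    SensorModel,
)


@pytest.fixture
def fish():
    return FishRecord(
        fish_id="f1", species="Caesio teres", swim_mode="BCF",
        mass_kg=0.015, standard_length_m=0.082,
    )


@pytest.fixture
def phys():
    return FishPhysiology(smr_true=170.0, mmr_true=1300.0, ucrit_true_bl_s=10.3)


@pytest.fixture
def quiet_phys():
    """Deterministic physiology: no spontaneous activity noise."""
    return FishPhysiology(smr_true=170.0, mmr_true=1300.0, ucrit_true_bl_s=10.3,
                          activity_sigma=0.0)


@pytest.fixture
def noise_free():
    return SensorModel(noise_sd=0.0)


@pytest.fixture
def rest_chamber():
    return ChamberSpec.default(Protocol.REST)


@pytest.fixture
def swim_chamber():
    return ChamberSpec.default(Protocol.SWIM)


@pytest.fixture
def circle_chamber():
    return ChamberSpec.default(Protocol.CIRCLE)


@pytest.fixture
def schedule():
    return CycleSchedule()
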