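import numpy as np
import pytest

from spikewell import (
    PlateSpec,
    RecordingSession,
    SpikeTrain,
    TrainGenSpec,
    TreatmentEffect,
    WellCondition,
    generate_plate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_train(times, duration=1800.0, electrode_id="e0"):
    return SpikeTrain(electrode_id, np.asarray(times, dtype=float), duration)


def make_session(trains_times, duration=1800.0, well_id="w0", timepoint="baseline", treatment=None):
    trains = tuple(
        make_train(t, duration, f"e{i}") for i, t in enumerate(trains_times)
    )
    return RecordingSession(
        well_id=well_id,
        timepoint=timepoint,
        trains=trains,
        treatment=treatment or {},
        recording_duration=duration,
    )


@pytest.fixture(scope="session")
def small_plate():
    """A compact two-condition plate reused by I/O and pipeline tests."""
    gen = TrainGenSpec(duration=300.0)
    cond = {
        f"w{i:02d}": WellCondition(
            gen=gen,
            effect=TreatmentEffect(onset_timepoint="30min")
            if i < 2
            else TreatmentEffect(burst_duration_scale=0.5, onset_timepoint="30min"),
            treatment={} if i < 2 else {"TNFa_pg_ml": 1e5},
            label="control" if i < 2 else "tnf",
        )
        for i in range(4)
    }
    return PlateSpec(
        condition_map=cond,
        electrodes_per_well=4,
        timepoints=("baseline", "30min", "1D"),
        master_seed=7,
    )


@pytest.fixture(scope="session")
def small_sessions(small_plate):
    return generate_plate(small_plate)
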