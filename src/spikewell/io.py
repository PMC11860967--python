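"""Spike-timestamp containers and on-disk formats.

Everything downstream (burst detection, features, synchrony) consumes the
:class:`SpikeTrain` / :class:`RecordingSession` containers defined here, so the
readers are the single place where ordering and bounds invariants are
enforced: no later stage ever sees unsorted or out-of-window timestamps.

Two spike dialects are supported:

* an HDF5 layout ``/wells/<well_id>/<timepoint>/electrodes/<electrode_id>``
  with a 1-D float64 dataset ``timestamps_s`` per electrode and session
  attributes ``duration_s`` and ``treatment_json``;
* a long-format CSV with columns ``well, timepoint, electrode, time_s`` plus
  optional ``duration_s`` and ``treatment_json`` columns.

Times are always seconds (float64), zero-based from recording start.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "RecordingSession",
    "WellFeatureRow",
    "FEATURE_NAMES",
    "read_spike_h5",
    "write_spike_h5",
    "read_spike_csv",
    "write_spike_csv",
    "write_feature_table",
    "read_feature_table",
]

#: The six per-well activity features, in canonical column order.
FEATURE_NAMES = (
    "n_spikes",
    "firing_rate",
    "mean_isi",
    "burst_duration",
    "bursts_per_min",
    "spikes_in_bursts",
)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike timestamps for one electrode over a recording window.

    Parameters
    ----------
    electrode_id:
        Label of the recording electrode.
    times:
        Spike times in seconds, strictly increasing, all in ``[0, duration)``.
    duration:
        Length of the recording window in seconds (> 0).
    """

    electrode_id: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError(f"electrode {self.electrode_id!r}: times must be 1-D")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError(
                f"electrode {self.electrode_id!r}: duration must be positive, "
                f"got {self.duration!r}"
            )
        if times.size:
            if not np.all(np.isfinite(times)):
                raise ValueError(f"electrode {self.electrode_id!r}: non-finite times")
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"electrode {self.electrode_id!r}: times not strictly increasing"
                )
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError(
                    f"electrode {self.electrode_id!r}: times outside [0, duration)"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        """Interspike intervals (seconds) between consecutive spikes."""
        return np.diff(self.times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.electrode_id == other.electrode_id
            and self.duration == other.duration
            and self.times.shape == other.times.shape
            and bool(np.all(self.times == other.times))
        )


def clean_times(
    times: np.ndarray, *, electrode_id: str = "", warn: bool = True
) -> np.ndarray:
    """Sort and deduplicate raw timestamps, warning when repair was needed."""
    times = np.asarray(times, dtype=np.float64)
    out = np.unique(times)  # sorted + strictly increasing
    if warn and out.size != times.size:
        warnings.warn(
            f"electrode {electrode_id!r}: collapsed {times.size - out.size} "
            "duplicate timestamp(s)",
            stacklevel=2,
        )
    if warn and out.size == times.size and times.size and np.any(np.diff(times) < 0):
        warnings.warn(
            f"electrode {electrode_id!r}: timestamps were not sorted; reordered",
            stacklevel=2,
        )
    return out


@dataclass(frozen=True)
class RecordingSession:
    """All electrode trains of one well at one timepoint.

    ``treatment`` maps cytokine names to concentrations in pg/mL
    (an empty mapping denotes an untreated / vehicle well).
    """

    well_id: str
    timepoint: str
    trains: tuple[SpikeTrain, ...]
    treatment: dict[str, float] = field(default_factory=dict)
    recording_duration: float = 1800.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", tuple(self.trains))
        ids = [t.electrode_id for t in self.trains]
        if len(set(ids)) != len(ids):
            raise ValueError(
                f"well {self.well_id!r}/{self.timepoint!r}: duplicate electrode ids"
            )
        for t in self.trains:
            if t.duration != self.recording_duration:
                raise ValueError(
                    f"well {self.well_id!r}/{self.timepoint!r}: electrode "
                    f"{t.electrode_id!r} duration {t.duration} != session "
                    f"duration {self.recording_duration}"
                )

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def train(self, electrode_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.electrode_id == electrode_id:
                return t
        raise KeyError(electrode_id)


@dataclass
class WellFeatureRow:
    """Per-well mean features at one timepoint, plus the synchrony summary.

    Undefined features (e.g. mean ISI of a silent well) are NaN in memory and
    empty fields on disk.
    """

    well_id: str
    timepoint: str
    treatment: dict[str, float]
    n_active_electrodes: int
    n_spikes: float = np.nan
    firing_rate: float = np.nan
    mean_isi: float = np.nan
    burst_duration: float = np.nan
    bursts_per_min: float = np.nan
    spikes_in_bursts: float = np.nan
    mean_synchrony: float = np.nan

    def as_dict(self) -> dict:
        d = {
            "well": self.well_id,
            "timepoint": self.timepoint,
            "treatment_json": json.dumps(self.treatment, sort_keys=True),
            "n_active_electrodes": self.n_active_electrodes,
        }
        for name in FEATURE_NAMES:
            d[name] = getattr(self, name)
        d["mean_synchrony"] = self.mean_synchrony
        return d


# ---------------------------------------------------------------------------
# HDF5 dialect
# ---------------------------------------------------------------------------


def write_spike_h5(sessions, path) -> None:
    """Write sessions in the package HDF5 dialect.

    Datasets are created with ``track_times=False`` so that identical inputs
    produce byte-identical files.
    """
    with h5py.File(path, "w") as f:
        wells = f.create_group("wells")
        for s in sorted(sessions, key=lambda s: (s.well_id, s.timepoint)):
            g = wells.require_group(s.well_id).create_group(s.timepoint)
            g.attrs["duration_s"] = float(s.recording_duration)
            g.attrs["treatment_json"] = json.dumps(s.treatment, sort_keys=True)
            el = g.create_group("electrodes")
            for t in sorted(s.trains, key=lambda t: t.electrode_id):
                el.create_dataset(
                    f"{t.electrode_id}/timestamps_s",
                    data=t.times,
                    dtype=np.float64,
                    track_times=False,
                )


def read_spike_h5(path) -> list[RecordingSession]:
    """Read all sessions from a spike HDF5 file, validating invariants.

    Raises ``ValueError`` naming the offending HDF5 path for malformed groups
    (unsorted times, missing ``duration_s``, …).
    """
    sessions: list[RecordingSession] = []
    with h5py.File(path, "r") as f:
        if "wells" not in f:
            raise ValueError(f"{path}: no /wells group")
        for well_id, wg in f["wells"].items():
            for timepoint, g in wg.items():
                where = f"/wells/{well_id}/{timepoint}"
                if "duration_s" not in g.attrs:
                    raise ValueError(f"{path}:{where}: missing duration_s attribute")
                duration = float(g.attrs["duration_s"])
                treatment = json.loads(g.attrs.get("treatment_json", "{}"))
                trains = []
                for eid, eg in g.get("electrodes", {}).items():
                    if "timestamps_s" not in eg:
                        raise ValueError(
                            f"{path}:{where}/electrodes/{eid}: missing timestamps_s"
                        )
                    times = np.asarray(eg["timestamps_s"], dtype=np.float64)
                    try:
                        trains.append(SpikeTrain(eid, times, duration))
                    except ValueError as e:
                        raise ValueError(f"{path}:{where}/electrodes/{eid}: {e}") from e
                sessions.append(
                    RecordingSession(
                        well_id=well_id,
                        timepoint=timepoint,
                        trains=tuple(trains),
                        treatment=treatment,
                        recording_duration=duration,
                    )
                )
    return sessions


# ---------------------------------------------------------------------------
# Long-format CSV dialect
# ---------------------------------------------------------------------------

_CSV_REQUIRED = ("well", "timepoint", "electrode", "time_s")


def write_spike_csv(sessions, path) -> None:
    """Write sessions as long-format CSV (one row per spike)."""
    records = []
    for s in sorted(sessions, key=lambda s: (s.well_id, s.timepoint)):
        tj = json.dumps(s.treatment, sort_keys=True)
        for t in sorted(s.trains, key=lambda t: t.electrode_id):
            for x in t.times:
                records.append(
                    (s.well_id, s.timepoint, t.electrode_id, x, s.recording_duration, tj)
                )
    df = pd.DataFrame.from_records(
        records,
        columns=[*_CSV_REQUIRED, "duration_s", "treatment_json"],
    )
    # %.17g keeps float64 exact so CSV<->HDF5 round-trips are lossless
    df.to_csv(path, index=False, float_format="%.17g")


def read_spike_csv(path, *, default_duration: float = 1800.0) -> list[RecordingSession]:
    """Read long-format CSV into sessions.

    Times are sorted on load (with a warning when reordering or deduplication
    was needed); electrodes present in the file but with no rows cannot be
    represented, so silent electrodes should be carried in HDF5 or added
    downstream.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    sessions = []
    if df.empty:
        return sessions
    for (well_id, timepoint), sg in df.groupby(["well", "timepoint"], sort=True):
        if "duration_s" in sg.columns and sg["duration_s"].notna().any():
            duration = float(sg["duration_s"].dropna().iloc[0])
        else:
            duration = default_duration
        if "treatment_json" in sg.columns and sg["treatment_json"].notna().any():
            treatment = json.loads(sg["treatment_json"].dropna().iloc[0])
        else:
            treatment = {}
        trains = []
        for eid, eg in sg.groupby("electrode", sort=True):
            times = clean_times(
                eg["time_s"].to_numpy(dtype=np.float64), electrode_id=str(eid)
            )
            trains.append(SpikeTrain(str(eid), times, duration))
        sessions.append(
            RecordingSession(
                well_id=str(well_id),
                timepoint=str(timepoint),
                trains=tuple(trains),
                treatment=treatment,
                recording_duration=duration,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def feature_frame(rows) -> pd.DataFrame:
    """Stack :class:`WellFeatureRow` objects into a tidy DataFrame."""
    return pd.DataFrame.from_records([r.as_dict() for r in rows])


def write_feature_table(rows, path) -> None:
    """Write per-well feature rows as tidy CSV.

    One row per well × timepoint, stable column order; undefined values are
    written as empty fields (never the string ``"NaN"``).
    """
    df = rows if isinstance(rows, pd.DataFrame) else feature_frame(rows)
    df.to_csv(path, index=False, na_rep="")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def convert_spikes(src, dst) -> None:
    """Convert between the HDF5 and CSV spike dialects based on suffixes."""
    src, dst = Path(src), Path(dst)
    readers = {".h5": read_spike_h5, ".hdf5": read_spike_h5, ".csv": read_spike_csv}
    writers = {".h5": write_spike_h5, ".hdf5": write_spike_h5, ".csv": write_spike_csv}
    try:
        sessions = readers[src.suffix](src)
        writers[dst.suffix](sessions, dst)
    except KeyError as e:
        raise ValueError(f"unsupported spike file suffix: {e}") from e
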