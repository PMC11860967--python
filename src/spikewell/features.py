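"""Per-electrode activity features, electrode filtering, per-well means.

Six features are computed per electrode: spike count, firing rate, mean ISI,
mean burst duration, bursts per minute and total spikes in bursts.  Electrodes
are then partitioned into *included*, *inactive* (fewer than 10 spikes in the
recording) and *noisy* (mean burst duration above 5 s), and the included
electrodes are averaged to one row per well — the unit on which all group
statistics are run.

Interval-type features (mean ISI, burst duration) are undefined on silent or
burst-free electrodes; they are carried as NaN and averaged only over
electrodes where defined.  Count-type features are zero there and always enter
the well mean.  An optional convention switch additionally zero-counts the
*inactive* electrodes into the well mean (the "value of 0" reading of the
inclusion rule); the default averages included electrodes only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bursts import Burst
from .io import RecordingSession, SpikeTrain, WellFeatureRow

logger = logging.getLogger(__name__)

__all__ = [
    "ElectrodeFeatures",
    "FilterParams",
    "ElectrodePartition",
    "electrode_features",
    "apply_electrode_filters",
    "well_features",
]

COUNT_FEATURES = ("n_spikes", "firing_rate", "bursts_per_min", "spikes_in_bursts")
INTERVAL_FEATURES = ("mean_isi", "burst_duration")


@dataclass(frozen=True)
class ElectrodeFeatures:
    """The six activity features of one electrode.

    ``mean_isi`` and ``burst_duration`` are NaN when undefined (fewer than two
    spikes / no bursts); counts and rates are plain zeros in that case.
    """

    electrode_id: str
    n_spikes: int
    firing_rate: float
    mean_isi: float
    burst_duration: float
    bursts_per_min: float
    spikes_in_bursts: int

    def value(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class FilterParams:
    """Electrode inclusion/exclusion rules.

    ``min_active_spikes``: an electrode must record at least this many spikes
    in the recording window to be analysed (default 10 per 30 min).
    ``noisy_mean_burst_duration``: electrodes whose mean burst duration is
    strictly greater than this (default 5 s) are excluded as noisy.
    """

    min_active_spikes: int = 10
    noisy_mean_burst_duration: float = 5.0

    def __post_init__(self) -> None:
        if self.min_active_spikes <= 0 or self.noisy_mean_burst_duration <= 0:
            raise ValueError("filter parameters must be positive")


@dataclass(frozen=True)
class ElectrodePartition:
    """Total, disjoint partition of a well's electrodes."""

    included: tuple[ElectrodeFeatures, ...]
    inactive: tuple[ElectrodeFeatures, ...]
    noisy: tuple[ElectrodeFeatures, ...]

    @property
    def all(self) -> tuple[ElectrodeFeatures, ...]:
        return self.included + self.inactive + self.noisy


def electrode_features(
    train: SpikeTrain, bursts: list[Burst], recording_duration: float | None = None
) -> ElectrodeFeatures:
    """Compute the six features of one electrode from its train and bursts."""
    duration = train.duration if recording_duration is None else recording_duration
    n = train.n_spikes
    isis = train.isis()
    durations = np.array([b.duration for b in bursts])
    return ElectrodeFeatures(
        electrode_id=train.electrode_id,
        n_spikes=n,
        firing_rate=n / duration,
        mean_isi=float(isis.mean()) if isis.size else np.nan,
        burst_duration=float(durations.mean()) if durations.size else np.nan,
        bursts_per_min=len(bursts) / (duration / 60.0),
        spikes_in_bursts=int(sum(b.n_spikes for b in bursts)),
    )


def apply_electrode_filters(
    feats: list[ElectrodeFeatures], params: FilterParams = FilterParams()
) -> ElectrodePartition:
    """Partition electrodes into included / inactive / noisy.

    Inactive: fewer than ``min_active_spikes`` spikes.  Noisy: mean burst
    duration strictly greater than ``noisy_mean_burst_duration`` (an exact
    5.0 s mean is retained).  Inactivity takes precedence; every electrode
    lands in exactly one class.
    """
    included, inactive, noisy = [], [], []
    for f in feats:
        if f.n_spikes < params.min_active_spikes:
            inactive.append(f)
        elif np.isfinite(f.burst_duration) and f.burst_duration > params.noisy_mean_burst_duration + 1e-9:
            noisy.append(f)
        else:
            included.append(f)
    return ElectrodePartition(tuple(included), tuple(inactive), tuple(noisy))


def well_features(
    session: RecordingSession,
    partition: ElectrodePartition,
    *,
    mean_synchrony: float = np.nan,
    zero_inactive: bool = False,
) -> WellFeatureRow:
    """Aggregate one well's electrode features into a single row.

    Count-type features are averaged over the included electrodes (silent but
    included electrodes contribute genuine zeros); interval-type features are
    averaged only over included electrodes where they are defined.  With
    ``zero_inactive=True``, inactive electrodes additionally contribute zeros
    to the count-type means.  A well with no included electrode yields an
    all-undefined row with a warning.
    """
    pool = list(partition.included)
    if zero_inactive:
        pool += list(partition.inactive)
    row = WellFeatureRow(
        well_id=session.well_id,
        timepoint=session.timepoint,
        treatment=dict(session.treatment),
        n_active_electrodes=len(partition.included),
        mean_synchrony=mean_synchrony,
    )
    if not partition.included:
        logger.warning(
            "well %s/%s: no included electrodes; feature row undefined",
            session.well_id,
            session.timepoint,
        )
        return row
    for name in COUNT_FEATURES:
        setattr(row, name, float(np.mean([f.value(name) for f in pool])))
    for name in INTERVAL_FEATURES:
        vals = [f.value(name) for f in partition.included if np.isfinite(f.value(name))]
        if vals:
            setattr(row, name, float(np.mean(vals)))
        else:
            logger.info(
                "well %s/%s: %s undefined on all included electrodes",
                session.well_id,
                session.timepoint,
                name,
            )
    return row
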