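"""Synthetic MEA plate generator with known ground truth.

Generates per-electrode spike trains (background Poisson firing plus bursting
episodes), whole multi-well plates across a timepoint series with programmable
treatment effects, correlated electrode pairs for synchrony testing, and raw
voltage traces for the spike-detection stage.  Every quantity the analysis
pipeline later estimates — firing rate, burst duration, spikes per burst,
pairwise synchrony structure — is controlled here, so the full pipeline can be
validated by parameter recovery without any recorded data.

The default plate emulates the study design this package targets: 6-well MEA
devices, ~16–40 electrodes per well, 30-minute recordings, a pre-exposure
baseline followed by 30 min / 60 min / 1 d / 2 d / 7 d post-exposure
recordings, and well-level treatment conditions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .io import RecordingSession, SpikeTrain

__all__ = [
    "TrainGenSpec",
    "TreatmentEffect",
    "WellCondition",
    "PlateSpec",
    "TrueBurst",
    "generate_poisson_train",
    "generate_bursting_train",
    "apply_effect",
    "generate_plate",
    "generate_correlated_pair",
    "generate_raw_trace",
    "spike_template",
    "DEFAULT_TIMEPOINTS",
]

#: Recording schedule of a cytokine-exposure experiment: pre-dose baseline,
#: two recordings in the first hour post-dose, then daily/weekly follow-ups.
DEFAULT_TIMEPOINTS = ("baseline", "30min", "60min", "1D", "2D", "7D")


@dataclass(frozen=True)
class TrainGenSpec:
    """Ground-truth activity parameters for one electrode.

    Parameters
    ----------
    background_rate:
        Rate of the background (non-burst) Poisson process, events/s.
    burst_rate:
        Rate of burst onsets, bursts per **minute**.
    spikes_per_burst_mean:
        Mean spike count per burst; counts are drawn as ``1 + Poisson(mean-1)``
        so every burst has at least one spike.
    intra_burst_isi:
        Spacing of spikes within a burst, seconds.  A burst of *n* spikes has
        true duration ``(n - 1) * intra_burst_isi``.
    duration:
        Recording length, seconds.
    seed:
        Seed of the electrode's private random stream.
    """

    background_rate: float = 1.0
    burst_rate: float = 6.0
    spikes_per_burst_mean: float = 18.0
    intra_burst_isi: float = 0.015
    duration: float = 1800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.background_rate) or self.background_rate < 0:
            raise ValueError("background_rate must be finite and >= 0")
        if not np.isfinite(self.burst_rate) or self.burst_rate < 0:
            raise ValueError("burst_rate must be finite and >= 0")
        if not self.spikes_per_burst_mean >= 1:
            raise ValueError("spikes_per_burst_mean must be >= 1")
        if not self.intra_burst_isi > 0:
            raise ValueError("intra_burst_isi must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative effect of a treatment on generator parameters.

    A scale of 1.0 means no effect.  ``burst_duration_scale`` acts on
    ``intra_burst_isi`` (holding spike count), ``spikes_per_burst_scale`` on
    the mean burst spike count, and ``firing_rate_scale`` on the overall
    event rate (background rate and burst-onset rate together), so the three
    effects land on three distinct observables.  The effect is active from
    ``onset_timepoint`` onwards.
    """

    burst_duration_scale: float = 1.0
    firing_rate_scale: float = 1.0
    spikes_per_burst_scale: float = 1.0
    onset_timepoint: str = "30min"

    def __post_init__(self) -> None:
        for name in ("burst_duration_scale", "firing_rate_scale", "spikes_per_burst_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0")

    @property
    def is_null(self) -> bool:
        return (
            self.burst_duration_scale == 1.0
            and self.firing_rate_scale == 1.0
            and self.spikes_per_burst_scale == 1.0
        )


@dataclass(frozen=True)
class WellCondition:
    """Generator spec, treatment effect and treatment label for one well."""

    gen: TrainGenSpec = field(default_factory=TrainGenSpec)
    effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    treatment: dict[str, float] = field(default_factory=dict)
    label: str = "control"


@dataclass(frozen=True)
class PlateSpec:
    """A whole multi-well plate across a series of recording timepoints."""

    condition_map: dict[str, WellCondition]
    electrodes_per_well: int = 16
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    master_seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints)
        object.__setattr__(self, "timepoints", tps)
        if not tps or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be non-empty and unique")
        if not self.condition_map:
            raise ValueError("condition_map must name at least one well")
        if self.electrodes_per_well < 1:
            raise ValueError("electrodes_per_well must be >= 1")

    @property
    def n_wells(self) -> int:
        return len(self.condition_map)


@dataclass(frozen=True)
class TrueBurst:
    """Ground-truth burst annotation: interval, spike count, truncation flag."""

    onset: float
    offset: float
    n_spikes: int
    truncated: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Homogeneous Poisson event times on [0, duration)."""
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def generate_poisson_train(
    rate: float, duration: float, seed, electrode_id: str = "e"
) -> SpikeTrain:
    """Homogeneous Poisson spike train at ``rate`` events/s on [0, duration).

    ``seed`` may be an int or an existing :class:`numpy.random.Generator`.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.unique(_poisson_times(rng, rate, duration))
    return SpikeTrain(electrode_id, times, duration)


def generate_bursting_train(
    spec: TrainGenSpec, electrode_id: str = "e"
) -> tuple[SpikeTrain, list[TrueBurst]]:
    """Background Poisson firing plus bursting episodes, with annotations.

    Burst onsets are Poisson at ``spec.burst_rate`` per minute; each burst
    carries ``1 + Poisson(mean - 1)`` spikes at ``intra_burst_isi`` spacing.
    Bursts running past the recording end are truncated and flagged;
    overlapping burst episodes are merged into a single annotation interval
    (which is all an ISI-based detector can resolve).

    Returns the train and the list of ground-truth :class:`TrueBurst`
    annotations (burst spikes only; background spikes falling inside a burst
    interval are not counted in the annotation).
    """
    rng = np.random.default_rng(spec.seed)
    background = _poisson_times(rng, spec.background_rate, spec.duration)

    annotations: list[TrueBurst] = []
    burst_spikes: list[np.ndarray] = []
    if spec.burst_rate > 0:
        onsets = _poisson_times(rng, spec.burst_rate / 60.0, spec.duration)
        counts = 1 + rng.poisson(spec.spikes_per_burst_mean - 1.0, size=onsets.size)
        raw: list[tuple[float, float, int, bool]] = []
        for onset, n in zip(onsets, counts):
            times = onset + np.arange(n) * spec.intra_burst_isi
            inside = times < spec.duration
            truncated = not bool(inside.all())
            times = times[inside]
            if times.size == 0:
                continue
            burst_spikes.append(times)
            raw.append((times[0], times[-1], times.size, truncated))
        # merge overlapping/adjacent episodes into single annotation intervals
        for onset, offset, n, trunc in raw:
            if annotations and onset <= annotations[-1].offset + spec.intra_burst_isi:
                prev = annotations[-1]
                annotations[-1] = TrueBurst(
                    prev.onset,
                    max(prev.offset, offset),
                    prev.n_spikes + n,
                    prev.truncated or trunc,
                )
            else:
                annotations.append(TrueBurst(onset, offset, n, trunc))

    all_times = np.unique(np.concatenate([background, *burst_spikes]))
    return SpikeTrain(electrode_id, all_times, spec.duration), annotations


def apply_effect(spec: TrainGenSpec, effect: TreatmentEffect) -> TrainGenSpec:
    """Return ``spec`` with the treatment effect applied (pure function).

    ``firing_rate_scale`` multiplies the background and burst-onset rates so
    the overall event rate scales by the same factor;
    ``burst_duration_scale`` multiplies ``intra_burst_isi`` (burst duration is
    ``(n-1)*isi``, so duration scales while spike count is held);
    ``spikes_per_burst_scale`` multiplies the mean burst spike count
    (floored at 1 spike).
    """
    return replace(
        spec,
        background_rate=spec.background_rate * effect.firing_rate_scale,
        burst_rate=spec.burst_rate * effect.firing_rate_scale,
        intra_burst_isi=spec.intra_burst_isi * effect.burst_duration_scale,
        spikes_per_burst_mean=max(1.0, spec.spikes_per_burst_mean * effect.spikes_per_burst_scale),
    )


def electrode_seed(master_seed: int, well_id: str, timepoint: str, electrode: int) -> np.random.SeedSequence:
    """Deterministic per-electrode seed derived from the master seed."""
    return np.random.SeedSequence(
        [
            int(master_seed),
            zlib.crc32(well_id.encode()),
            zlib.crc32(timepoint.encode()),
            int(electrode),
        ]
    )


def generate_plate(
    plate: PlateSpec, *, with_annotations: bool = False
) -> list[RecordingSession] | tuple[list[RecordingSession], dict]:
    """Generate one :class:`RecordingSession` per (well, timepoint).

    Treatment effects are applied only at and after ``effect.onset_timepoint``
    (wells whose onset label is not in the timepoint series are never
    treated).  Per-electrode random streams are derived deterministically
    from ``master_seed``, the well id, the timepoint and the electrode index,
    so regenerating the same plate is bit-identical.

    With ``with_annotations=True`` additionally returns a dict mapping
    ``(well_id, timepoint, electrode_id)`` to the list of ground-truth
    :class:`TrueBurst` annotations.
    """
    sessions: list[RecordingSession] = []
    annotations: dict[tuple[str, str, str], list[TrueBurst]] = {}
    width = len(str(plate.electrodes_per_well - 1))
    for well_id, cond in plate.condition_map.items():
        try:
            onset_idx = plate.timepoints.index(cond.effect.onset_timepoint)
        except ValueError:
            onset_idx = len(plate.timepoints)  # never reached
        for ti, timepoint in enumerate(plate.timepoints):
            gen = cond.gen
            if ti >= onset_idx:
                gen = apply_effect(gen, cond.effect)
            trains = []
            for e in range(plate.electrodes_per_well):
                eid = f"e{e:0{width}d}"
                ss = electrode_seed(plate.master_seed, well_id, timepoint, e)
                espec = replace(gen, seed=ss)
                train, ann = generate_bursting_train(espec, electrode_id=eid)
                trains.append(train)
                annotations[(well_id, timepoint, eid)] = ann
            sessions.append(
                RecordingSession(
                    well_id=well_id,
                    timepoint=timepoint,
                    trains=tuple(trains),
                    treatment=dict(cond.treatment),
                    recording_duration=cond.gen.duration,
                )
            )
    if with_annotations:
        return sessions, annotations
    return sessions


def generate_correlated_pair(
    base: SpikeTrain, jitter_sd: float, deletion_prob: float, seed
) -> tuple[SpikeTrain, SpikeTrain]:
    """Return ``base`` plus a jittered/thinned copy for synchrony testing.

    The second train is the base train with i.i.d. Gaussian time jitter of SD
    ``jitter_sd`` seconds and independent thinning at ``deletion_prob``,
    re-sorted, deduplicated and clipped to the recording window.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not 0 <= deletion_prob < 1:
        raise ValueError("deletion_prob must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = base.times[rng.uniform(size=base.n_spikes) >= deletion_prob]
    if jitter_sd > 0:
        times = times + rng.normal(0.0, jitter_sd, size=times.size)
    eps = np.spacing(base.duration)
    times = np.unique(np.clip(times, 0.0, base.duration - eps))
    twin = SpikeTrain(base.electrode_id + "_corr", times, base.duration)
    return base, twin


def spike_template(fs: float, width: float = 0.001) -> np.ndarray:
    """Stereotyped 1-ms biphasic extracellular waveform, negative peak = -1.

    A dominant negative phase followed by a smaller positive rebound, the
    typical shape of an extracellular action potential.
    """
    n = max(int(round(fs * width)), 4)
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    wave = np.where(
        t < 0.6,
        -np.sin(np.pi * t / 0.6),
        0.35 * np.sin(np.pi * (t - 0.6) / 0.4),
    )
    return wave / -wave.min()  # exact -1.0 at the negative peak


def generate_raw_trace(
    train: SpikeTrain,
    spike_amplitude: float = 8.0,
    noise_sd: float = 1e-5,
    fs: float = 10000.0,
    seed=0,
    *,
    amplitude_volts: float | None = None,
) -> np.ndarray:
    """Sampled voltage trace: Gaussian noise plus a waveform at each spike.

    ``spike_amplitude`` is the (positive) peak amplitude in multiples of
    ``noise_sd``; pass ``amplitude_volts`` to set it in volts directly (useful
    on noiseless traces, where multiples of zero are meaningless).  The
    waveform's negative peak lands on the sample nearest each timestamp.
    Waveforms of spikes closer than one template width are summed.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if spike_amplitude < 0 or noise_sd < 0:
        raise ValueError("spike_amplitude and noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(train.duration * fs))
    trace = (
        rng.normal(0.0, noise_sd, size=n_samples)
        if noise_sd > 0
        else np.zeros(n_samples)
    )
    amp = amplitude_volts if amplitude_volts is not None else spike_amplitude * noise_sd
    if amp != 0 and train.n_spikes:
        template = spike_template(fs) * amp
        peak_offset = int(np.argmin(template))
        starts = np.round(train.times * fs).astype(np.int64) - peak_offset
        for s in starts:
            lo, hi = max(s, 0), min(s + template.size, n_samples)
            if hi > lo:
                trace[lo:hi] += template[lo - s : hi - s]
    return trace
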