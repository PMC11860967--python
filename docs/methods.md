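# Methods

This note documents the models, parameter choices and numerical conventions
behind `spikewell`, and what the synthetic-data validation does and does not
establish about recorded data.

## Analysis model

The unit of inference is the **well**: electrode-level quantities are never
compared across wells directly.  For each well × timepoint session the
pipeline computes per-electrode features, filters electrodes, averages over
the included electrodes, normalizes the per-well series to its own
pre-exposure baseline, and expresses it as a fold change against the mean of
age-matched vehicle-control wells at the same timepoint.  This two-stage
normalization removes both stable well-to-well differences in activity and
plate-wide, time-locked disturbances (e.g. the mechanical effect of
pipetting treatment into the wells), leaving a quantity whose control-group
mean is exactly 1 at every timepoint by construction.

### Spike detection

Raw traces are bandpass filtered 4–4000 Hz with a 2nd-order Butterworth
applied forward-backward (zero-phase, so spike times carry no filter
latency).  Baseline noise SD is estimated as `1.4826 × MAD` over a
calibration window (default: the whole trace); the MAD is used because the
trace is a mixture of Gaussian noise and sparse large spikes, and the median
of absolute deviations is essentially blind to the spike tail.  A spike is a
maximal run of samples at or below −6.5 σ̂, timestamped at the run's
extremum; events closer than the 1 ms refractory window are merged to the
first.  Only negative-going crossings are detected by default (the
extracellular action potential's dominant phase); absolute-value detection
is available behind `DetectorParams.polarity`.  Detection requires σ̂ > 0
and raises on constant traces.  Noise SD is estimated once per recording per
electrode, not tracked over time.

### Max-interval burst detection

Five parameters (defaults): max begin ISI 0.1 s, max end ISI 0.2 s, min
inter-burst interval 0.5 s, min duration 0.05 s, min spikes 6.  Semantics:

* **scan** — a candidate begins at the first spike of a pair with
  ISI ≤ begin and extends while ISIs ≤ end; candidates are maximal and
  disjoint;
* **merge** — consecutive candidates with gap (next onset − previous
  offset) strictly < min IBI are merged, absorbing interior spikes, to a
  fixed point; merging runs **before** size filtering so two sub-threshold
  fragments separated by less than the IBI survive as one burst;
* **filter** — keep bursts with duration ≥ min duration and ≥ min spikes.

"Max"/"min" comparisons are inclusive; the merge gap is strict.  Burst
duration is last-spike time minus first-spike time, unpadded.  All interval
comparisons carry a 1 ns tolerance (`bursts.EPS`): a value within
floating-point rounding of a threshold is treated as exactly at it.  This is
far below both the 0.1 ms sampling resolution and any biological
variability; it exists because synthetic boundary probes built on regular
time grids accumulate ulp-level errors in `diff`, and boundary behaviour is
part of this package's tested contract.

### Electrode filters and well means

Electrodes with fewer than 10 spikes per recording are *inactive*;
electrodes with mean burst duration strictly greater than 5.0 s are *noisy*
(an exact 5.0 s mean is retained); inactivity takes precedence and the three
classes partition the array.  Noisy electrodes are excluded from both the
feature and the synchrony analyses.

Count-type features (spike count, firing rate, bursts/min, spikes in bursts)
are zero on silent electrodes and always enter the well mean; interval-type
features (mean ISI, mean burst duration) are undefined there, carried as
NaN, and averaged only over electrodes where defined.  Whether array-wide
means should also zero-count the *inactive* electrodes is genuinely
ambiguous (a "count inactive electrodes as 0" rule and a "≥ 10 spikes to be
included" rule pull in opposite directions), so both conventions are
implemented; the default follows the inclusion rule, and
`well_features(..., zero_inactive=True)` selects the other.  The "ISI"
feature is the per-electrode mean ISI (not median).

### SPIKE-distance synchrony

The SPIKE-distance profile S(t) (definitions in the README) is piecewise
linear between "corner" times — the pooled spikes of both trains plus
auxiliary edge spikes at the window boundaries — because every discrete
quantity (tP, tF, x_ISI, ΔtP, ΔtF) is constant on each open interval while
xP and xF vary linearly.  The time average is therefore computed *exactly*
as a sum of trapezoids evaluated at one-sided interval limits; there is no
integration grid and no tolerance parameter.  The independent check in the
test suite integrates the same profile on a dense 0.1 ms grid instead.
Auxiliary edge spikes make the distance well defined for arbitrarily sparse
(including empty) trains; identical trains give D = 0 identically.  The
implementation is symmetric, invariant to time shifts (≲1e-12) and to joint
time rescaling (≲1e-9).

**Surrogate normalization.** The similarity 1 − D of rate-matched but
independent Poisson pairs sits near 0.7, not 0, and drifts with firing rate
when spike counts are low.  Each pair's similarity is therefore divided by
the mean similarity of `n_surrogates = 20` Poisson surrogate pairs matched
to the two trains' empirical rates, and capped at 1: identical trains score
exactly 1, and pairs at or below chance score near or below their chance
ratio.  The exact normalization form is an open design point; the division
form with a cap was chosen because it pins the perfect-synchrony anchor at 1
without a second parameter.  The uncapped ratio and the raw similarity are
emitted alongside every score for audit.  Pairs in which either train is
empty have no defined rate-matched surrogate; their score is NaN and they
are excluded from well summaries.  Surrogate streams are seeded from the
`SurrogateSpec` seed plus the electrode-id pair, so scores are reproducible
and independent of scoring order.

The density bias this normalization corrects is a sparsity effect: by time
rescaling invariance, the distance of equal-rate independent pairs depends
on rate only through the number of spikes in the window, so the bias is
measurable on short sparse windows (tens of spikes) and negligible on
30-minute recordings at ≥ 0.5 Hz.  The bias-correction validation
accordingly probes 15-s windows, where the raw similarity's mean drifts by
≈ 0.03 across 0.5–8 Hz and the normalized score's drift is reliably
smaller.

### Statistics

`group_stats` is a thin convenience stage over standard engines:
`pingouin.mixed_anova` (between = condition, within = timepoint,
subject = well) per feature, and `scipy.stats.dunnett` for many-to-one
comparisons against the control condition within each feature × timepoint
family, α = 0.05.  Degenerate designs (single condition, single timepoint,
< 2 wells in any cell) raise instead of silently falling back.  Numerical
equivalence with any particular commercial statistics package is not a goal.

## Synthetic plate generator

Each electrode's train is background homogeneous Poisson firing superposed
with burst episodes: burst onsets are Poisson (rate in bursts/min), each
burst has `1 + Poisson(mean − 1)` spikes (guaranteeing ≥ 1) at a fixed
intra-burst ISI.  Bursts overrunning the recording are truncated and
flagged; overlapping episodes are merged into one annotation interval —
which is all an ISI-based detector could ever resolve.  Ground-truth
annotations (interval, spike count) are available for every train so that
features can be computed with the detector bypassed.

Treatment effects are multiplicative and mapped to distinct observables to
keep parameter recovery identifiable:

| scale | acts on | observable |
|---|---|---|
| `burst_duration_scale` | intra-burst ISI (count held) | mean burst duration |
| `spikes_per_burst_scale` | mean burst spike count (floor 1) | spikes in bursts |
| `firing_rate_scale` | background **and** burst-onset rate | firing rate |

`firing_rate_scale` deliberately scales the whole event rate rather than the
background alone: the firing-rate feature counts intra-burst spikes, so a
background-only scale of 0.5 would surface as a ≈ 0.8 fold change and the
injected effect would not be recoverable on the observable it names.
Effects apply from `onset_timepoint` onward; baseline recordings always use
the untreated parameters.

Default parameters — background 1.0 Hz, 6 bursts/min, 18 spikes/burst at
15 ms ISI (≈ 0.26 s bursts, total rate ≈ 2.8 Hz/electrode), 30-min
recordings, 16 electrodes/well, 6 wells/arm, timepoints
baseline/30min/60min/1D/2D/7D — were chosen once as plausible for mature
iPSC-derived neuron/astrocyte co-cultures on MEAs; no quantitative baseline
activity levels were available to match, so these are plausibility choices,
not calibrations.

Per-electrode random streams derive from
`SeedSequence([master_seed, crc32(well), crc32(timepoint), electrode])`, so
plates regenerate bit-identically and HDF5 outputs are byte-identical
(datasets are written with `track_times=False`).

**What the generator does not emulate** — and hence what passing validation
does not establish about recordings: network-level correlation structure
(electrodes are independent unless explicitly paired), non-stationarity
(development, adaptation, drift within a recording), electrode-specific
noise and amplitude variation, biophysical burst shape (ISIs within a burst
are constant, real bursts accelerate/decelerate), and any
cytokine-mechanism realism beyond multiplicative effects on three
parameters.  Validation on this generator establishes that the pipeline's
*estimators and decision rules* behave as specified, not that any specific
biological effect size would be recovered from real cultures.

## Validation sizing

The simulation-based checks use: effect recovery — 6 wells/arm, 16
electrodes, 30-min recordings, baseline + 2 post timepoints, 5 master
seeds, ± 0.15 tolerance on the fold-change scale; type-I error — 50
replicate null plates (two identical arms, 8 electrodes, baseline + 3
timepoints), requiring ≤ 10% significant control-referenced comparisons;
power — 20 replicate plates with a 50% burst-duration reduction (16
electrodes), requiring detection at every post-onset timepoint in ≥ 90% of
replicates.  Electrode counts for the null check are reduced relative to
the study design because well-level type-I behaviour is insensitive to the
within-well electrode count.

## Known limitations

* Recovered burst-duration fold changes overshoot slightly toward 1 (e.g.
  ≈ 0.6 for a true 0.5) because background spikes within the end-ISI window
  of a burst edge are absorbed into the detected burst at both baseline and
  post timepoints; this is a property of max-interval detection itself, not
  of the generator.
* The capped normalized synchrony saturates at 1 for any pair at or above
  chance similarity; graded comparisons between strongly synchronous wells
  should use the uncapped ratio column.
* The CSV spike dialect cannot represent silent electrodes (no rows); use
  the HDF5 dialect when inactive-electrode bookkeeping matters.
* `mixed_anova` assumes complete well × timepoint tables; wells dropped for
  undefined baselines propagate as missing cells and may raise.
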