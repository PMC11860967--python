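# Example pipeline configuration for `spikewell run examples/plate_config.yaml`.
#
# `simulate` describes a synthetic plate (omit it and set `input: path.h5`
# plus a `conditions: {well_id: label}` map to analyze recorded spikes
# instead).  All generator and analysis parameters shown with their defaults.
simulate:
  electrodes_per_well: 16
  timepoints: [baseline, 30min, 60min, 1D, 2D, 7D]
  master_seed: 1
  conditions:
    - label: control
      wells: 6
      treatment: {TNFa_pg_ml: 0}
      gen:
        background_rate: 1.0        # Hz, non-burst Poisson firing
        burst_rate: 6.0             # bursts per minute
        spikes_per_burst_mean: 18
        intra_burst_isi: 0.015      # s
        duration: 1800.0            # s (30-min recordings)
    - label: tnf_high
      wells: 6
      treatment: {TNFa_pg_ml: 100000}
      effect:
        burst_duration_scale: 0.5   # halve burst duration ...
        firing_rate_scale: 1.0
        spikes_per_burst_scale: 1.0
        onset_timepoint: 30min      # ... from this timepoint onward

analysis:
  baseline_timepoint: baseline
  control_condition: control
  synchrony: true
  surrogates: {n_surrogates: 20, seed: 0}
  burst_params: {}                  # max_begin_isi 0.1, max_end_isi 0.2, min_ibi 0.5,
                                    # min_duration 0.05, min_spikes 6
  filter_params: {}                 # min_active_spikes 10, noisy_mean_burst_duration 5.0
  zero_inactive: false
  stats: true

output_dir: spikewell_out
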