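"""End-to-end analysis: simulate a treated plate and recover the effect.

Simulates a plate with control wells and wells carrying a 50% burst-duration
reduction, runs the full analysis (burst detection -> electrode filters ->
per-well features -> baseline normalization -> fold change vs. age-matched
controls -> repeated-measures statistics) and prints the recovered fold
changes with their Dunnett-adjusted p-values.
"""

from spikewell import run_pipeline

config = {
    "simulate": {
        "electrodes_per_well": 16,
        "timepoints": ["baseline", "30min", "1D"],
        "master_seed": 1,
        "conditions": [
            {"label": "control", "wells": 6, "treatment": {"TNFa_pg_ml": 0}},
            {
                "label": "tnf_high",
                "wells": 6,
                "treatment": {"TNFa_pg_ml": 1e5},
                "effect": {"burst_duration_scale": 0.5, "onset_timepoint": "30min"},
            },
        ],
    },
    "analysis": {"synchrony": False},
    "output_dir": "spikewell_demo_out",
}

results = run_pipeline(config)
cmp = results["stats"].comparisons
bd = cmp[cmp.feature == "burst_duration"]
print(bd[["timepoint", "condition", "mean_fold_change", "p_adj", "significant"]].to_string(index=False))
# The treated wells' burst-duration fold change lands near the injected 0.5
# (slightly above: background spikes absorbed at burst edges dilute the
# effect) and is flagged significant at every post-onset timepoint; all
# other artifacts (CSVs, manifest, log) are in spikewell_demo_out/.
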