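"""End-to-end study analysis: features, synchrony, normalization, statistics.

The analysis follows the per-well design of a cytokine-exposure MEA
experiment: every well is recorded at a pre-exposure baseline and a series of
post-exposure timepoints; each feature is first normalized to the well's own
baseline (to cancel well-to-well activity differences and the mechanical
disturbance of dosing), then expressed as a fold change relative to the mean
of the age-matched vehicle-control wells at the same timepoint; group effects
are assessed with a mixed repeated-measures ANOVA (condition x timepoint,
well as subject) and Dunnett-style comparisons against the control condition.

:func:`run_pipeline` orchestrates the whole chain from a config mapping
(simulate or load spikes -> burst detection -> electrode/well features ->
synchrony -> fold-change table -> statistics), writing tidy CSVs and a
manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bursts import BurstParams, detect_bursts
from .features import FilterParams, apply_electrode_filters, electrode_features, well_features
from .io import (
    FEATURE_NAMES,
    RecordingSession,
    feature_frame,
    read_spike_csv,
    read_spike_h5,
    write_feature_table,
    write_spike_h5,
)
from .simulate import PlateSpec, TrainGenSpec, TreatmentEffect, WellCondition, generate_plate
from .synchrony import SurrogateSpec, well_synchrony

logger = logging.getLogger(__name__)

__all__ = [
    "baseline_normalize",
    "control_fold_change",
    "group_stats",
    "StatsResult",
    "analyze_sessions",
    "run_pipeline",
    "plate_from_config",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Feature extraction over sessions
# ---------------------------------------------------------------------------


def analyze_sessions(
    sessions: list[RecordingSession],
    burst_params: BurstParams = BurstParams(),
    filter_params: FilterParams = FilterParams(),
    surrogate_spec: SurrogateSpec | None = None,
    *,
    zero_inactive: bool = False,
    bin_width: float = 0.05,
):
    """Per-well feature rows (and optional synchrony) for a set of sessions.

    Returns ``(well_df, electrode_df, pair_df)``: the per-well feature table,
    a per-electrode audit table with inclusion flags, and the pairwise
    synchrony table (empty when ``surrogate_spec`` is None, which skips the
    synchrony stage).
    """
    rows, el_records, pair_frames = [], [], []
    for s in sessions:
        feats = []
        for train in s.trains:
            bursts = detect_bursts(train, burst_params)
            feats.append(electrode_features(train, bursts, s.recording_duration))
        partition = apply_electrode_filters(feats, filter_params)
        status = {f.electrode_id: "included" for f in partition.included}
        status.update({f.electrode_id: "inactive" for f in partition.inactive})
        status.update({f.electrode_id: "noisy" for f in partition.noisy})
        for f in feats:
            rec = {
                "well": s.well_id,
                "timepoint": s.timepoint,
                "electrode": f.electrode_id,
                "status": status[f.electrode_id],
            }
            rec.update({name: f.value(name) for name in FEATURE_NAMES})
            el_records.append(rec)
        mean_sync = np.nan
        if surrogate_spec is not None:
            res = well_synchrony(s, partition, surrogate_spec, bin_width)
            mean_sync = res.mean_score
            pf = res.pairs.copy()
            pf.insert(0, "well", s.well_id)
            pf.insert(1, "timepoint", s.timepoint)
            pair_frames.append(pf)
        rows.append(
            well_features(s, partition, mean_synchrony=mean_sync, zero_inactive=zero_inactive)
        )
    well_df = feature_frame(rows)
    electrode_df = pd.DataFrame.from_records(el_records)
    pair_df = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(columns=["well", "timepoint", "e1", "e2", "raw", "surrogate_mean", "ratio", "score"])
    )
    return well_df, electrode_df, pair_df


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def baseline_normalize(
    well_df: pd.DataFrame,
    baseline_timepoint: str = "baseline",
    features: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Divide each well's post-exposure features by its own baseline value.

    Returns a long table with columns ``well, timepoint, feature,
    baseline_value, post_value, baseline_normalized`` (one row per well x
    post timepoint x feature).  Wells with a zero or undefined baseline for a
    feature are flagged (``baseline_normalized`` NaN) and logged; a well with
    no baseline recording at all raises ``ValueError``.
    """
    wells = well_df["well"].unique()
    base = well_df[well_df["timepoint"] == baseline_timepoint].set_index("well")
    missing = [w for w in wells if w not in base.index]
    if missing:
        raise ValueError(f"no baseline ({baseline_timepoint!r}) recording for wells {missing}")
    post = well_df[well_df["timepoint"] != baseline_timepoint]
    records = []
    for _, row in post.iterrows():
        for feat in features:
            b = base.at[row["well"], feat]
            v = row[feat]
            if not np.isfinite(b) or b == 0:
                norm = np.nan
                logger.warning(
                    "well %s feature %s: baseline zero/undefined; excluded", row["well"], feat
                )
            else:
                norm = v / b
            rec = {
                "well": row["well"],
                "timepoint": row["timepoint"],
                "feature": feat,
                "baseline_value": b,
                "post_value": v,
                "baseline_normalized": norm,
            }
            if "treatment_json" in row:
                rec["treatment_json"] = row["treatment_json"]
            if "condition" in row:
                rec["condition"] = row["condition"]
            records.append(rec)
    return pd.DataFrame.from_records(records)


def control_fold_change(
    normalized: pd.DataFrame,
    control_condition: str = "control",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Express baseline-normalized values as fold change vs. age-matched
    controls.

    Each well's baseline-normalized value is divided by the mean of the
    control wells' baseline-normalized values at the *same* timepoint (the
    age-matched vehicle mean).  By construction the control wells' fold
    changes average to 1 at every timepoint.  Raises ``ValueError`` when a
    timepoint has no control well; wells whose control-mean denominator is
    undefined are dropped with a logged reason.
    """
    if condition_col not in normalized.columns:
        raise ValueError(f"column {condition_col!r} required for fold-change normalization")
    out = normalized.copy()
    is_ctrl = out[condition_col] == control_condition
    if not is_ctrl.any():
        raise ValueError(f"no wells with condition {control_condition!r}")
    ctrl_mean = (
        out[is_ctrl]
        .groupby(["timepoint", "feature"])["baseline_normalized"]
        .mean()
        .rename("control_mean_normalized")
    )
    for tp in out["timepoint"].unique():
        if tp not in ctrl_mean.index.get_level_values(0):
            raise ValueError(f"no control wells at timepoint {tp!r}")
    out = out.join(ctrl_mean, on=["timepoint", "feature"])
    denom = out["control_mean_normalized"]
    bad = ~np.isfinite(denom) | (denom == 0)
    if bad.any():
        for _, r in out[bad].iterrows():
            logger.warning(
                "dropping fold change for well %s %s/%s: control mean undefined",
                r["well"],
                r["timepoint"],
                r["feature"],
            )
        out = out[~bad]
    out["fold_change"] = out["baseline_normalized"] / out["control_mean_normalized"]
    return out


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


@dataclass
class StatsResult:
    """Repeated-measures ANOVA tables and control-referenced comparisons.

    ``anova`` maps feature name to a mixed-ANOVA table (condition,
    timepoint, interaction effects); ``comparisons`` holds one row per
    (feature, timepoint, condition) with the Dunnett-adjusted p-value of the
    comparison against the control condition.
    """

    anova: dict[str, pd.DataFrame] = field(default_factory=dict)
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    alpha: float = ALPHA


def group_stats(
    fold: pd.DataFrame,
    control_condition: str = "control",
    condition_col: str = "condition",
    alpha: float = ALPHA,
) -> StatsResult:
    """Mixed repeated-measures ANOVA plus Dunnett comparisons vs. control.

    Per feature: a condition (between-well) x timepoint (within-well,
    repeated) ANOVA with well as the subject, then, at each timepoint, a
    Dunnett many-to-one comparison of every condition against the control
    wells' fold changes (familywise-adjusted within each feature x timepoint
    family).  Requires at least two conditions, two timepoints and two wells
    per condition; degenerate designs raise ``ValueError``.
    """
    import pingouin as pg
    from scipy import stats as sps

    conditions = sorted(fold[condition_col].unique())
    timepoints = list(fold["timepoint"].unique())
    if len(conditions) < 2 or len(timepoints) < 2:
        raise ValueError("design needs >= 2 conditions and >= 2 repeated timepoints")
    n_wells = fold.groupby(condition_col)["well"].nunique()
    if (n_wells < 2).any():
        raise ValueError(f"every condition needs >= 2 wells; got {n_wells.to_dict()}")
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent")

    result = StatsResult(alpha=alpha)
    records = []
    for feat, fg in fold.groupby("feature"):
        fg = fg.dropna(subset=["fold_change"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(
                data=fg,
                dv="fold_change",
                within="timepoint",
                between=condition_col,
                subject="well",
            )
        result.anova[feat] = aov
        for tp, tg in fg.groupby("timepoint"):
            ctrl = tg.loc[tg[condition_col] == control_condition, "fold_change"].to_numpy()
            others = [c for c in conditions if c != control_condition]
            samples = [
                tg.loc[tg[condition_col] == c, "fold_change"].to_numpy() for c in others
            ]
            if ctrl.size < 2 or any(s.size < 2 for s in samples):
                raise ValueError(f"feature {feat!r} timepoint {tp!r}: <2 wells in a group")
            res = sps.dunnett(*samples, control=ctrl)
            for cond, p, stat in zip(others, res.pvalue, res.statistic):
                records.append(
                    {
                        "feature": feat,
                        "timepoint": tp,
                        "condition": cond,
                        "n_treated": int(tg[tg[condition_col] == cond]["well"].nunique()),
                        "n_control": int(tg[tg[condition_col] == control_condition]["well"].nunique()),
                        "mean_fold_change": float(
                            tg.loc[tg[condition_col] == cond, "fold_change"].mean()
                        ),
                        "statistic": float(stat),
                        "p_adj": float(p),
                        "significant": bool(p < alpha),
                    }
                )
    result.comparisons = pd.DataFrame.from_records(records)
    return result


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def plate_from_config(cfg: dict) -> tuple[PlateSpec, dict[str, str]]:
    """Build a :class:`PlateSpec` from a config mapping.

    Expected keys: ``timepoints``, ``electrodes_per_well``, ``master_seed``
    and ``conditions`` — a list of mappings with ``label``, ``wells`` (count),
    optional ``treatment``, ``gen`` (TrainGenSpec fields) and ``effect``
    (TreatmentEffect fields).  Returns the plate and a well -> condition-label
    map.
    """
    condition_map: dict[str, WellCondition] = {}
    labels: dict[str, str] = {}
    w = 0
    for cond in cfg["conditions"]:
        gen = TrainGenSpec(**cond.get("gen", {}))
        effect = TreatmentEffect(**cond.get("effect", {}))
        for _ in range(int(cond.get("wells", 1))):
            well_id = f"w{w:02d}"
            condition_map[well_id] = WellCondition(
                gen=gen,
                effect=effect,
                treatment=dict(cond.get("treatment", {})),
                label=cond["label"],
            )
            labels[well_id] = cond["label"]
            w += 1
    plate = PlateSpec(
        condition_map=condition_map,
        electrodes_per_well=int(cfg.get("electrodes_per_well", 16)),
        timepoints=tuple(cfg.get("timepoints", ("baseline", "30min", "60min", "1D", "2D", "7D"))),
        master_seed=int(cfg.get("master_seed", 0)),
    )
    return plate, labels


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, out_dir=None) -> dict:
    """Run the full analysis described by a config mapping or YAML path.

    Config keys:

    * ``simulate`` — plate config (see :func:`plate_from_config`), or
      ``input`` — path to a spike HDF5/CSV file with a ``conditions``
      well -> label map and ``control_condition``;
    * ``analysis`` — optional: ``baseline_timepoint`` (default "baseline"),
      ``control_condition`` (default "control"), ``synchrony`` (bool,
      default true), ``surrogates`` (``n_surrogates``, ``seed``),
      ``zero_inactive`` (bool), ``burst_params`` / ``filter_params`` field
      overrides, ``stats`` (bool, default true);
    * ``output_dir`` — where CSVs, the manifest and the log are written.

    Returns a dict of the in-memory results (feature/fold-change/stats
    tables); every stage's output is also written to ``output_dir``.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("output_dir", "spikewell_out"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("spikewell")
    root.addHandler(handler)
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: dict, out: Path) -> dict:
    ana = cfg.get("analysis", {})
    stage = "configuration"
    try:
        if "simulate" in cfg:
            stage = "simulate"
            plate, labels = plate_from_config(cfg["simulate"])
            sessions = generate_plate(plate)
            write_spike_h5(sessions, out / "spikes.h5")
        elif "input" in cfg:
            stage = "load"
            path = Path(cfg["input"])
            reader = read_spike_csv if path.suffix == ".csv" else read_spike_h5
            sessions = reader(path)
            labels = dict(cfg.get("conditions", {}))
        else:
            raise ValueError("config must name either 'simulate' or 'input'")

        stage = "features/synchrony"
        burst_params = BurstParams(**ana.get("burst_params", {}))
        filter_params = FilterParams(**ana.get("filter_params", {}))
        surrogate = (
            SurrogateSpec(**ana.get("surrogates", {})) if ana.get("synchrony", True) else None
        )
        well_df, electrode_df, pair_df = analyze_sessions(
            sessions,
            burst_params,
            filter_params,
            surrogate,
            zero_inactive=bool(ana.get("zero_inactive", False)),
        )
        well_df["condition"] = well_df["well"].map(labels)
        if well_df["condition"].isna().any():
            missing = sorted(well_df.loc[well_df["condition"].isna(), "well"].unique())
            raise ValueError(f"wells without a condition label: {missing}")
        write_feature_table(well_df, out / "well_features.csv")
        electrode_df.to_csv(out / "electrode_features.csv", index=False, na_rep="")
        pair_df.to_csv(out / "synchrony_pairs.csv", index=False, na_rep="")
        if surrogate is not None:
            well_df[["well", "timepoint", "condition", "mean_synchrony"]].to_csv(
                out / "synchrony_wells.csv", index=False, na_rep=""
            )

        stage = "baseline normalization"
        baseline_tp = ana.get("baseline_timepoint", "baseline")
        normalized = baseline_normalize(well_df, baseline_tp)

        stage = "control fold change"
        control = ana.get("control_condition", "control")
        fold = control_fold_change(normalized, control)
        fold.to_csv(out / "fold_change.csv", index=False, na_rep="")

        results = {
            "sessions": sessions,
            "well_features": well_df,
            "electrode_features": electrode_df,
            "synchrony_pairs": pair_df,
            "fold_change": fold,
            "stats": None,
        }
        if ana.get("stats", True):
            stage = "group statistics"
            stats = group_stats(fold, control)
            stats.comparisons.to_csv(out / "stats_comparisons.csv", index=False, na_rep="")
            with open(out / "stats_anova.json", "w") as fh:
                json.dump(
                    {f: t.to_dict(orient="records") for f, t in stats.anova.items()},
                    fh,
                    indent=2,
                    default=float,
                )
            results["stats"] = stats

        stage = "manifest"
        manifest = {
            "spikewell_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": _jsonable(cfg),
            "burst_params": asdict(burst_params),
            "filter_params": asdict(filter_params),
            "surrogates": asdict(surrogate) if surrogate else None,
            "n_sessions": len(sessions),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return results
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e


def _jsonable(obj):
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        return repr(obj)
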