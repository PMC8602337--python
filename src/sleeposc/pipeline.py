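"""End-to-end orchestration: simulate → preprocess → detect → aggregate → model.

A single config (dict or YAML) drives the whole chain.  All randomness
derives from one seed, forked per stage by name, so runs are reproducible
and changing one stage's stochastics does not perturb the others.  Every
intermediate artifact (events, densities, band powers, summaries, model
results) is written to the output directory along with a provenance JSON
recording the config hash, package versions and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .errors import CalibrationError, SleepOscError
from .io_preprocess import preprocess_recording, preset_specs
from .sleep_metrics import compute_sleep_stats
from .slow_waves import SWParams, detect_slow_waves
from .spectral import stage_band_powers
from .spindles import BANDS, calibrate_relpower_threshold, detect_spindles
from .stats import ModelSpec, aggregate, compare_models, fit_lmm, report_table
from .synthetic import CohortDesign, EffectSpec, generate_cohort

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "design": {},        # CohortDesign overrides
    "effects": {},       # EffectSpec overrides
    "thresholds": None,  # explicit {band: {stage: value}}; None -> calibrate
    "metrics": "all",
}

#: stage-keyed metrics get the full Condition*Stage model; the rest get
#: Condition (+ Melatonin) only
STAGE_METRIC_SUFFIXES = ("density", "amplitude", "duration", "frequency", "power")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def build_design(config: dict) -> CohortDesign:
    over = dict(config.get("design") or {})
    if "sessions_per_condition" in over:
        over["sessions_per_condition"] = dict(over["sessions_per_condition"])
    if "channel_labels" in over:
        over["channel_labels"] = tuple(over["channel_labels"])
    if "melatonin_naive_subjects" in over:
        over["melatonin_naive_subjects"] = tuple(over["melatonin_naive_subjects"])
    over.setdefault("seed", config.get("seed", 0))
    return CohortDesign(**over)


def build_effects(config: dict) -> EffectSpec:
    over = dict(config.get("effects") or {})
    return EffectSpec(**over)


def night_metric_rows(meta, events_by_band, sw_events, sw_density,
                      band_powers: pd.DataFrame, sleep_stats) -> list[dict]:
    """Tidy metric rows for one night (long format)."""
    base = {"subject_id": meta.subject_id, "session_id": meta.session_id,
            "condition": meta.condition, "melatonin": meta.melatonin}
    rows: list[dict] = []

    def add(metric, value, stage=None):
        if value is None or (isinstance(value, float) and not np.isfinite(value)):
            return
        rows.append({**base, "stage": stage, "metric": metric, "value": value})

    for band, (events, density) in events_by_band.items():
        pooled = density[density["channel"] == "pooled"].set_index("stage")["density"]
        for stage in ("N2", "N3"):
            add(f"{band}_spindle_density", pooled.get(stage, np.nan), stage)
            stage_events = [ev for ev in events if ev.stage == stage]
            if stage_events:
                add(f"{band}_spindle_amplitude",
                    float(np.mean([ev.p2p_amplitude for ev in stage_events])), stage)
                add(f"{band}_spindle_duration",
                    float(np.mean([ev.duration for ev in stage_events])), stage)
                add(f"{band}_spindle_frequency",
                    float(np.mean([ev.frequency for ev in stage_events])), stage)

    add("sw_density", sw_density)
    if sw_events:
        add("sw_amplitude", float(np.mean([ev.p2p_amplitude for ev in sw_events])))
        add("sw_duration", float(np.mean([ev.duration for ev in sw_events])))
        add("sw_slope", float(np.mean([ev.slope for ev in sw_events])))

    for _, r in band_powers.iterrows():
        if r["band"] == "sw":
            add("sw_band_power", r["power"])
        else:
            add(f"{r['band']}_spindle_band_power", r["power"], r["stage"])

    add("spt", sleep_stats.spt_min)
    add("tst", sleep_stats.tst_min)
    add("waso", sleep_stats.waso_min)
    return rows


def calibrate_subject_thresholds(nights) -> dict[str, dict[str, dict[str, float]]]:
    """Per-subject relative-power thresholds from each calibration night.

    ``nights`` is an iterable of (recording, hypnogram) pairs.  Returns
    ``{subject_id: {band: {stage: threshold}}}``; subjects without a
    calibration night are simply absent.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for recording, hypnogram in nights:
        meta = recording.meta
        if not meta.is_calibration_night:
            continue
        per_band = {}
        for name, band in BANDS.items():
            thr = calibrate_relpower_threshold(recording, hypnogram, band)
            per_band[name] = {st: t.threshold for st, t in thr.items()}
        out[meta.subject_id] = per_band
    return out


def run_pipeline(config: dict | None = None,
                 output_dir: str | Path | None = None) -> dict[str, Any]:
    """Run the full chain and return the result bundle.

    The bundle holds the tidy night-level metric table, the aggregated
    summaries, fitted model results, the contrast report, and AIC
    comparisons of full vs Condition-only models.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}
    t_start = time.time()
    timings: dict[str, float] = {}

    design = build_design(config)
    effects = build_effects(config)
    seed = int(config.get("seed", 0))

    t0 = time.time()
    nights = generate_cohort(design, effects, seed)
    timings["simulate"] = time.time() - t0

    t0 = time.time()
    processed = []
    eeg_spec = preset_specs()["EEG"]
    for night in nights:
        rec = preprocess_recording(night.recording, eeg_spec)
        processed.append((rec, night.hypnogram, night.truth))
    timings["preprocess"] = time.time() - t0

    t0 = time.time()
    if config.get("thresholds"):
        explicit = config["thresholds"]
        thresholds = {rec.meta.subject_id: explicit for rec, _, _ in processed}
    else:
        thresholds = calibrate_subject_thresholds(
            [(rec, hyp) for rec, hyp, _ in processed])
        missing = {rec.meta.subject_id for rec, _, _ in processed} - set(thresholds)
        if missing:
            raise CalibrationError(
                f"no calibration night for subjects {sorted(missing)}; supply "
                "explicit thresholds in the config")
    timings["calibrate"] = time.time() - t0

    t0 = time.time()
    all_rows: list[dict] = []
    event_tables: list[pd.DataFrame] = []
    for rec, hyp, _truth in processed:
        subj_thr = thresholds[rec.meta.subject_id]
        events_by_band = {}
        for name, band in BANDS.items():
            events, density = detect_spindles(rec, hyp, band, subj_thr[name],
                                              band_name=name)
            events_by_band[name] = (events, density)
            if events:
                df = pd.DataFrame([dataclasses.asdict(ev) for ev in events])
                df.insert(0, "subject_id", rec.meta.subject_id)
                df.insert(1, "session_id", rec.meta.session_id)
                df.insert(2, "condition", rec.meta.condition)
                df.insert(3, "melatonin", rec.meta.melatonin)
                event_tables.append(df)
        sw_events, sw_density = detect_slow_waves(rec, hyp, SWParams())
        powers = stage_band_powers(rec, hyp)
        stats = compute_sleep_stats(hyp)
        all_rows.extend(night_metric_rows(rec.meta, events_by_band, sw_events,
                                          sw_density, powers, stats))
    metrics = pd.DataFrame(all_rows)
    timings["detect"] = time.time() - t0

    t0 = time.time()
    staged = metrics[metrics["stage"].notna()]
    unstaged = metrics[metrics["stage"].isna()].drop(columns=["stage"])
    summary_staged = aggregate(staged, stage_key=True) if len(staged) else pd.DataFrame()
    summary_unstaged = (aggregate(unstaged, stage_key=False)
                        if len(unstaged) else pd.DataFrame())

    results = {}
    aic_comparisons = {}
    wanted = config.get("metrics", "all")
    for metric in sorted(metrics["metric"].unique()):
        if wanted != "all" and metric not in wanted:
            continue
        stage_keyed = metric in set(staged["metric"]) if len(staged) else False
        table = (summary_staged if stage_keyed else summary_unstaged)
        table = table[table["metric"] == metric]
        if table["subject_id"].nunique() < 2 or len(table) < 4:
            continue
        spec = ModelSpec(response=metric, include_stage=stage_keyed,
                         include_interaction=stage_keyed)
        try:
            results[metric] = fit_lmm(table, spec)
            reduced = ModelSpec(response=metric, include_stage=False,
                                include_interaction=False,
                                include_melatonin=False)
            aic_comparisons[metric] = compare_models(table, spec, reduced)
        except SleepOscError:
            continue
    report = report_table(results)
    timings["model"] = time.time() - t0

    bundle = {
        "metrics": metrics,
        "summary_staged": summary_staged,
        "summary_unstaged": summary_unstaged,
        "events": (pd.concat(event_tables, ignore_index=True)
                   if event_tables else pd.DataFrame()),
        "results": results,
        "aic_comparisons": aic_comparisons,
        "report": report,
        "thresholds": thresholds,
        "timings": timings,
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "night_metrics.csv", index=False)
        if len(summary_staged):
            summary_staged.to_csv(out / "summary_staged.csv", index=False)
        if len(summary_unstaged):
            summary_unstaged.to_csv(out / "summary_unstaged.csv", index=False)
        bundle["events"].to_csv(out / "events.csv", index=False)
        report.to_csv(out / "contrasts.csv", index=False)
        anova_rows = []
        for metric, res in results.items():
            a = res.anova.copy()
            a.insert(0, "metric", metric)
            anova_rows.append(a)
        if anova_rows:
            pd.concat(anova_rows, ignore_index=True).to_csv(
                out / "anova.csv", index=False)
        diag = pd.DataFrame([
            {"metric": m, "shapiro_stat": r.shapiro_stat,
             "shapiro_p": r.shapiro_p, "aic": r.aic, "singular": r.singular,
             "aic_full": aic_comparisons[m].aic_full if m in aic_comparisons else np.nan,
             "aic_reduced": (aic_comparisons[m].aic_reduced
                             if m in aic_comparisons else np.nan)}
            for m, r in results.items()])
        diag.to_csv(out / "diagnostics.csv", index=False)
        provenance = {
            "config_hash": _config_hash(config),
            "seed": seed,
            "sleeposc_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "total_s": round(time.time() - t_start, 3),
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)

    return bundle
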