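"""End-to-end driver: simulate -> features -> SOM -> ethogram -> speed ->
rest, with every artefact written as delimited text plus a manifest.

The pipeline mirrors the study's flow on synthetic data: a labelled
training set (balanced bouts of all 12 behaviours) trains and validates the
SOM; per-sex free-roaming schedules are rendered, classified, and analysed
for activity budgets, hourly profiles, locomotor speed/distance, and rest
bouts; the two sexes' long-rest durations are compared with the density
permutation test. All randomness flows from the config seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ethogram, evaluation, locomotion, rest, som
from .features import compute_features
from .io import PipelineConfig, write_features, write_labels
from .simulate import (CalibrationSpec, ScheduleSpec, default_regimes,
                       generate_calibration, generate_schedule, generate_trace,
                       sex_presets)
from .vocabulary import BEHAVIORS, LOCOMOTOR


def make_training_set(n_per_class: int = 60, bout_len: int = 10,
                      fs: float = 50.0, seed: int = 0,
                      regimes=None) -> pd.DataFrame:
    """Balanced labelled feature table emulating the scored-video training
    data: every behaviour appears in ``n_per_class`` epochs laid out as
    bouts of ``bout_len`` consecutive epochs."""
    rng = np.random.default_rng(seed)
    regimes = regimes or default_regimes()
    blocks = []
    for b in BEHAVIORS:
        blocks.extend([b] * n_per_class)
    labels = []
    per = {b: n_per_class for b in BEHAVIORS}
    order = list(BEHAVIORS)
    while any(per.values()):
        rng.shuffle(order)
        for b in order:
            take = min(bout_len, per[b])
            if take:
                labels.extend([b] * take)
                per[b] -= take
    trace = generate_trace(labels, regimes, fs=fs,
                           seed=int(rng.integers(2**31)))
    return compute_features(trace)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, outdir,
                 schedule_specs: dict[str, ScheduleSpec] | None = None) -> dict:
    """Run the full synthetic study; returns the result bundle and writes
    all tables plus ``manifest.json`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    regimes = default_regimes()
    results: dict = {}
    written: list[str] = []

    def save(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(name)

    # --- training data, SOM, evaluation -------------------------------
    train_feats = _stage("simulate-training", make_training_set,
                         fs=config.fs, seed=int(rng.integers(2**31)))
    feats_only = train_feats.drop(columns=["epoch_s", "hour", "behavior"])
    (tr_X, tr_y), (te_X, te_y) = _stage(
        "split", som.split_data, feats_only,
        train_feats["behavior"].to_numpy(object),
        som.TrainTestSplit(train_fraction=config.train_fraction,
                           seed=int(rng.integers(2**31))))
    model = _stage("train-som", som.train_som, tr_X,
                   grid_shape=config.grid_shape,
                   seed=int(rng.integers(2**31)))
    model = _stage("label-nodes", som.label_nodes, model, tr_X, tr_y)
    pred_te = _stage("predict-test", som.predict, model, te_X)
    cm = _stage("evaluate", evaluation.confusion, te_y, pred_te)
    metrics = evaluation.metrics_table(cm)
    results["confusion"] = cm
    results["metrics"] = metrics
    results["overall_accuracy"] = evaluation.overall_accuracy(cm)
    save(cm.reset_index(names="true"), "confusion_matrix.csv")
    save(metrics.reset_index(names="behavior"), "accuracy_metrics.csv")
    model.save(outdir / "som_model.json")
    written.append("som_model.json")

    # --- speed calibration --------------------------------------------
    calib = _stage("calibration", generate_calibration,
                   CalibrationSpec(seed=int(rng.integers(2**31))))
    speed_model = _stage("fit-speed", locomotion.fit_speed_model, calib)
    save(calib, "calibration_bouts.csv")
    speed_model.save(outdir / "speed_model.json")
    written.append("speed_model.json")
    results["speed_model"] = speed_model

    # --- per-sex wild data --------------------------------------------
    presets = sex_presets(duration_h=config.duration_h)
    budgets, rest_tables, bout_tables, stat_tables = {}, {}, {}, {}
    for sex in config.sexes:
        spec = (schedule_specs or {}).get(sex, presets.get(sex))
        if spec is None:
            raise RuntimeError(f"pipeline stage 'schedule' failed: no preset "
                               f"for sex {sex!r}")
        spec = ScheduleSpec(**{**spec.__dict__,
                               "seed": int(rng.integers(2**31))})
        sched = _stage(f"schedule-{sex}", generate_schedule, spec)
        trace = _stage(f"trace-{sex}", generate_trace,
                       sched["behavior"].to_numpy(object), regimes,
                       config.fs, int(rng.integers(2**31)))
        feats = _stage(f"features-{sex}", compute_features, trace,
                       config.epoch_s, spec.start_hour)
        pred = _stage(f"predict-{sex}", som.predict, model,
                      feats.drop(columns=["epoch_s", "hour", "behavior"]))
        feats["predicted"] = pred
        write_labels(pred, outdir / f"predicted_{sex}.csv")
        written.append(f"predicted_{sex}.csv")

        budgets[sex] = ethogram.activity_budget(pred).loc["overall"]
        profile = ethogram.hourly_profile(pred, feats["hour"])
        save(profile.reset_index(), f"hourly_profile_{sex}.csv")

        vba_hourly = ethogram.vba_max_aggregate(feats, by="hour")
        save(vba_hourly.reset_index(), f"vba_max_hourly_{sex}.csv")

        bouts = locomotion.extract_bouts(
            pred, LOCOMOTOR, epoch_vba=feats["vba_mean"].to_numpy(),
            epoch_s=config.epoch_s)
        if len(bouts):
            bouts = locomotion.predict_bout_speeds(speed_model, bouts)
            bouts["individual"] = sex
        bout_tables[sex] = bouts
        save(bouts, f"locomotor_bouts_{sex}.csv")

        rb = rest.stationary_bouts(pred, epoch_s=config.epoch_s)
        stat_tables[sex] = rb
        rest_tables[sex] = rest.filter_rest(rb, config.min_rest_minutes)
        save(rb, f"stationary_bouts_{sex}.csv")
        save(rest_tables[sex], f"rest_bouts_{sex}.csv")

    budget_df = pd.DataFrame(budgets).T
    budget_df.index.name = "sex"
    save(budget_df.reset_index(), "activity_budget_by_sex.csv")
    results["budgets"] = budget_df
    results["rest_bouts"] = rest_tables
    results["stationary_bouts"] = stat_tables
    results["locomotor_bouts"] = bout_tables

    all_bouts = pd.concat([b for b in bout_tables.values() if len(b)],
                          ignore_index=True) if any(
        len(b) for b in bout_tables.values()) else pd.DataFrame(
        columns=["individual", "start_s", "distance_m"])
    if len(all_bouts):
        daily = locomotion.daily_distance(all_bouts)
        save(daily, "daily_distance_km.csv")
        results["daily_distance"] = daily

    if (len(config.sexes) == 2
            and all(len(rest_tables[s]) for s in config.sexes)):
        a, b = (rest_tables[s]["duration_min"].to_numpy()
                for s in config.sexes)
        test = _stage("rest-density-test", rest.density_equality_test,
                      a, b, n_perm=config.n_perm,
                      seed=int(rng.integers(2**31)))
        results["rest_density_test"] = test
        pd.DataFrame([{"statistic": test.statistic, "p_value": test.p_value,
                       "n_perm": test.n_perm, "bandwidth": test.bandwidth}]
                     ).to_csv(outdir / "rest_density_test.csv", index=False)
        written.append("rest_density_test.csv")

    manifest = {"config": config.to_dict(), "files": sorted(written)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
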