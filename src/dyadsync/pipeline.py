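"""Stage-wise pipeline tying the modules into the two analyses.

Stages (each reads the previous stage's artifacts from the working
directory and writes its own, plus a JSON metadata file with the config
hash, seeds, and bookkeeping counts):

* ``simulate``  — synthetic classroom -> raw signals + session structure
* ``features``  — beat series -> windowed HR/SDNN tracks + HR1 (long CSV)
* ``decompose`` — raw EDA -> z-scored SCR/SCL tracks (long CSV)
* ``spc``       — tracks -> dyad-mean correlations vs the room-restricted
  bootstrap null, raw and task-change-filtered, Holm-corrected per family
* ``events``    — event log + SCR tracks -> filtered events, epochs,
  condition grand averages
* ``mwe``       — difference curves -> envelope bands and tests
* ``report``    — collects the results tables

The per-feature results table mirrors the tonic-analysis layout:
(feature, window, dyad_mean, ci_lo, ci_hi, p_raw, p_adj, n_dyads,
retained_fraction).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecg, eda, events as ev, io, mwe, spc
from .exceptions import InputError
from .series import FeatureSeries

STAGES = ("simulate", "features", "decompose", "spc", "events", "mwe", "report")


def _require(path: Path, stage_hint: str) -> Path:
    if not path.exists():
        raise InputError(f"missing upstream artifact {path.name}; "
                         f"run the '{stage_hint}' stage first")
    return path


def run_pipeline(config: io.PipelineConfig, stage: str, out_dir: str | Path) -> dict:
    """Run one stage; returns the stage's bookkeeping counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stage not in STAGES:
        raise InputError(f"unknown stage {stage!r}; stages are {STAGES}")
    return _DISPATCH[stage](config, out)


def stage_simulate(config: io.PipelineConfig, out: Path) -> dict:
    from .simulate import generate_classroom
    import dataclasses
    sim = dataclasses.replace(config.sim, seed=config.seeds["simulation"])
    classroom = generate_classroom(sim)
    io.write_classroom(classroom, out)
    counts = {"participants": len(classroom.participants),
              "dyads": len(classroom.dyad_map.dyads),
              "events": len(classroom.session_log.events)}
    io.write_metadata(out / "simulate.meta.json", config, **counts)
    return counts


def _load_session(out: Path):
    dyad_map = io.read_dyad_map(_require(out / "dyad_map.csv", "simulate"))
    events = io.read_events(_require(out / "events.csv", "simulate"))
    sched = io.read_role_schedule(_require(out / "role_schedule.csv", "simulate"))
    tc_path = out / "task_changes.csv"
    task_changes = (pd.read_csv(tc_path)["t_s"].tolist() if tc_path.exists() else [])
    log = ev.SessionLog(events, sched, task_changes)
    return dyad_map, log


def stage_features(config: io.PipelineConfig, out: Path) -> dict:
    dyad_map, _ = _load_session(out)
    session_len = config.sim.session_len
    tracks: dict[str, dict[str, FeatureSeries]] = {}
    windowed_store: dict[str, dict[str, ecg.WindowedFeature]] = {}
    for pid in dyad_map.participants:
        beats = io.read_beats(_require(out / "raw" / f"{pid}_beats.csv", "simulate"))
        feats: dict[str, FeatureSeries] = {}
        wstore: dict[str, ecg.WindowedFeature] = {}
        for wlen in config.window_lengths:
            hr_w, sdnn_w = ecg.windowed_features(beats, wlen, config.overlap_frac)
            feats[hr_w.name] = ecg.upsample_to_seconds(hr_w, session_len)
            feats[sdnn_w.name] = ecg.upsample_to_seconds(sdnn_w, session_len)
            wstore[hr_w.name], wstore[sdnn_w.name] = hr_w, sdnn_w
        feats["HR1"] = ecg.instantaneous_hr(beats, session_len)
        tracks[pid] = feats
        windowed_store[pid] = wstore
    io.write_long_format(tracks, out / "hrv_tracks.csv")
    # keep window starts/values for the filtered analysis
    rows = [{"participant_id": pid, "feature": name, "start_s": s, "value": v}
            for pid, ws in windowed_store.items()
            for name, w in ws.items()
            for s, v in zip(w.starts, w.values)]
    pd.DataFrame(rows).to_csv(out / "hrv_windows.csv", index=False)
    counts = {"participants": len(tracks),
              "features_per_participant": len(next(iter(tracks.values())))}
    io.write_metadata(out / "features.meta.json", config, **counts)
    return counts


def stage_decompose(config: io.PipelineConfig, out: Path) -> dict:
    dyad_map, _ = _load_session(out)
    tracks: dict[str, dict[str, FeatureSeries]] = {}
    excluded = []
    for pid in dyad_map.participants:
        path = out / "raw" / f"{pid}_eda.csv"
        if not path.exists():
            continue
        raw = io.read_eda(path)
        try:
            corrected, _ = eda.correct_artifacts(raw)
        except eda.QualityError:
            excluded.append(pid)
            continue
        dec = eda.decompose_cda(corrected)
        scr, scl = eda.to_second_tracks(dec)
        tracks[pid] = {"SCR": eda.zscore_session(scr),
                       "SCL": eda.zscore_session(scl)}
    if tracks:
        io.write_long_format(tracks, out / "eda_tracks.csv")
    counts = {"participants": len(tracks), "excluded": excluded}
    io.write_metadata(out / "decompose.meta.json", config, **counts)
    return counts


def _spc_row(result: spc.SpcResult, feature: str, window, retained: float) -> dict:
    return {"feature": feature, "window": window,
            "dyad_mean": result.dyad_mean, "ci_lo": result.ci[0],
            "ci_hi": result.ci[1], "p_raw": result.p_raw,
            "n_dyads": result.n_dyads, "retained_fraction": retained}


def stage_spc(config: io.PipelineConfig, out: Path) -> dict:
    dyad_map, log = _load_session(out)
    rng = np.random.default_rng(config.seeds["bootstrap"])
    rows = []
    families: list[list[int]] = []          # row indices per Holm family

    hrv_path = out / "hrv_tracks.csv"
    if hrv_path.exists():
        tracks = io.read_long_format(hrv_path)
        windows_df = pd.read_csv(out / "hrv_windows.csv")
        hrv_family = []
        for wlen in config.window_lengths:
            for feat in (f"HR{wlen}", f"SDNN{wlen}"):
                per = {p: tracks[p][feat] for p in tracks}
                res = spc.shuffled_pair_null(per, dyad_map, feat,
                                             config.n_boot, config.alpha, rng)
                hrv_family.append(len(rows))
                rows.append(_spc_row(res, feat, wlen, 1.0))
                # task-change-filtered variant; may be unusable when dense
                # forced behaviour leaves too few windows
                filt_tracks, retained = _filtered_tracks(
                    windows_df, feat, wlen, config, log)
                try:
                    res_f = spc.shuffled_pair_null(filt_tracks, dyad_map, feat,
                                                   config.n_boot, config.alpha,
                                                   rng)
                except (InputError, KeyError):
                    warnings.warn(f"filtered {feat} (window {wlen}s) skipped: "
                                  f"retained fraction {retained:.0%} too low")
                    continue
                hrv_family.append(len(rows))
                rows.append(_spc_row(res_f, feat + "_filtered", wlen, retained))
        families.append(hrv_family)

    eda_path = out / "eda_tracks.csv"
    if eda_path.exists():
        fast_tracks = io.read_long_format(eda_path)
        hr1 = {p: t for p, t in io.read_long_format(hrv_path).items()} \
            if hrv_path.exists() else {}
        fast_family = []
        for feat in ("SCR", "SCL"):
            per = {p: fast_tracks[p][feat] for p in fast_tracks}
            res = spc.shuffled_pair_null(per, dyad_map, feat,
                                         config.n_boot, config.alpha, rng)
            fast_family.append(len(rows))
            rows.append(_spc_row(res, feat, 1, 1.0))
        if hr1:
            per = {p: hr1[p]["HR1"] for p in hr1}
            res = spc.shuffled_pair_null(per, dyad_map, "HR1",
                                         config.n_boot, config.alpha, rng)
            fast_family.append(len(rows))
            rows.append(_spc_row(res, "HR1", 1, 1.0))
        families.append(fast_family)

    if not rows:
        raise InputError("no feature tracks found; run 'features' or "
                         "'decompose' first")
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    for fam in families:                     # two-family Holm split
        df.loc[fam, "p_adj"] = spc.holm_bonferroni(df.loc[fam, "p_raw"].tolist())
    df.to_csv(out / "spc_results.csv", index=False)
    counts = {"n_tests": len(df), "n_families": len(families)}
    io.write_metadata(out / "spc.meta.json", config, **counts)
    return counts


def _filtered_tracks(windows_df: pd.DataFrame, feat: str, wlen: int,
                     config: io.PipelineConfig, log: ev.SessionLog
                     ) -> tuple[dict[str, FeatureSeries], float]:
    """Per-participant step-hold tracks after forced-behaviour filtering."""
    out: dict[str, FeatureSeries] = {}
    fractions = []
    for pid, g in windows_df[windows_df["feature"] == feat].groupby(
            "participant_id", sort=True):
        w = ecg.WindowedFeature(feat, g["start_s"].to_numpy(),
                                g["value"].to_numpy(), float(wlen))
        w_f, retained = spc.filter_forced_behaviour(w, log, "task_change")
        fractions.append(retained)
        if w_f.values.size:
            out[str(pid)] = ecg.upsample_to_seconds(w_f, config.sim.session_len)
    return out, float(np.mean(fractions)) if fractions else 0.0


def stage_events(config: io.PipelineConfig, out: Path) -> dict:
    dyad_map, log = _load_session(out)
    tracks = io.read_long_format(_require(out / "eda_tracks.csv", "decompose"))
    events = ev.filter_events(log.events, config.min_event_separation_s)

    dyad_id_of: dict[str, str] = {}
    for room in dyad_map.rooms:
        for i, d in enumerate(room.dyads):
            for pid in d:
                dyad_id_of[pid] = f"{room.room_id}_d{i + 1}"

    epochs: list[ev.Epoch] = []
    n_dropped = 0
    for pid, feats in tracks.items():
        scr = feats["SCR"]
        my_events = [e for e in events if e.dyad_id == dyad_id_of.get(pid)]
        eps, dropped = ev.epoch_scr(scr, my_events, pid, log,
                                    config.event_window_s)
        epochs.extend(eps)
        n_dropped += dropped

    sets = ev.condition_grand_average(epochs)
    rows = []
    t_rel = np.arange(config.event_window_s[0], config.event_window_s[1] + 1)
    for cond, es in sets.items():
        for pid, curve in es.per_participant_means.items():
            for t, v in zip(t_rel, curve):
                rows.append({"condition": f"{cond[0]}x{cond[1]}",
                             "participant_id": pid, "t_rel_s": t, "value": v})
    pd.DataFrame(rows).to_csv(out / "epoch_condition_means.csv", index=False)
    grand = [{"condition": f"{c[0]}x{c[1]}", "t_rel_s": t, "value": v}
             for c, es in sets.items() if es.n_participants
             for t, v in zip(t_rel, es.grand_mean)]
    pd.DataFrame(grand).to_csv(out / "grand_averages.csv", index=False)
    counts = {"events_total": len(log.events), "events_retained": len(events),
              "epochs": len(epochs), "epochs_dropped": n_dropped}
    io.write_metadata(out / "events.meta.json", config, **counts)
    return counts


def stage_mwe(config: io.PipelineConfig, out: Path) -> dict:
    df = pd.read_csv(_require(out / "epoch_condition_means.csv", "events"))
    curves = {cond: g.pivot(index="participant_id", columns="t_rel_s",
                            values="value")
              for cond, g in df.groupby("condition")}
    t_rel = np.arange(config.event_window_s[0], config.event_window_s[1] + 1)
    results = {}
    for contrast, (ca, cb) in {"role": ("drivexpooled", "navigatexpooled"),
                               "outcome": ("pooledxpass", "pooledxfail")}.items():
        a, b = curves[ca], curves[cb]
        shared = a.index.intersection(b.index)
        if len(shared) < 3:
            continue
        diffs = (a.loc[shared] - b.loc[shared]).to_numpy()
        boot = mwe.bootstrap_mean_curves(diffs, config.n_boot,
                                         config.seeds["bootstrap"])
        sig, mask, band = mwe.mwe_difference_test(boot, config.alpha,
                                                  rng=config.seeds["split"])
        pd.DataFrame({"t_rel_s": t_rel, "lower": band.lower,
                      "upper": band.upper,
                      "naive_lower": band.naive_lower,
                      "naive_upper": band.naive_upper,
                      "mean": diffs.mean(axis=0),
                      "significant_flag": mask.astype(int)}
                     ).to_csv(out / f"mwe_band_{contrast}.csv", index=False)
        meta = {"k": band.k, "alpha": band.alpha, "n_train": config.n_boot // 2,
                "n_valid": config.n_boot // 2, "seed": config.seeds["split"],
                "centering": band.centering, "significant": sig,
                "n_participants": int(len(shared))}
        (out / f"mwe_band_{contrast}.meta.json").write_text(
            json.dumps(meta, indent=2))
        results[contrast] = sig
    io.write_metadata(out / "mwe.meta.json", config, contrasts=results)
    return {"contrasts": results}


def stage_report(config: io.PipelineConfig, out: Path) -> dict:
    artifacts = [p.name for p in sorted(out.glob("*.csv"))]
    io.write_metadata(out / "report.meta.json", config, artifacts=artifacts)
    return {"artifacts": artifacts}


_DISPATCH = {"simulate": stage_simulate, "features": stage_features,
             "decompose": stage_decompose, "spc": stage_spc,
             "events": stage_events, "mwe": stage_mwe, "report": stage_report}
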