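"""File formats and configuration.

One canonical long-format CSV — columns (participant_id, t_s, feature,
value), integer seconds — is the interchange format between all stages; a
simulated classroom written to disk is indistinguishable from imported
data.  Raw-rate EDA and beat times use per-participant two-column CSVs, the
dyad map a (room_id, participant_a, participant_b) CSV, the event log a
(t_s, dyad_id, kind, outcome) CSV and the role schedule a
(participant_id, start_s, end_s, role) CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import BeatSeries
from .eda import EdaRaw
from .events import Event, RoleInterval, SessionLog
from .exceptions import InputError
from .series import FeatureSeries
from .simulate import SimConfig, SyntheticClassroom
from .spc import DyadMap, Room

LONG_COLUMNS = ["participant_id", "t_s", "feature", "value"]


# ---------------------------------------------------------------------------
# long-format feature tracks

def write_long_format(tracks: dict[str, dict[str, FeatureSeries]],
                      path: str | Path) -> None:
    """Write {participant -> {feature -> FeatureSeries}} as the long CSV."""
    rows = []
    for pid in sorted(tracks):
        for feat in sorted(tracks[pid]):
            fs = tracks[pid][feat]
            ok = np.isfinite(fs.values)
            rows.append(pd.DataFrame({
                "participant_id": pid,
                "t_s": fs.seconds[ok],
                "feature": feat,
                "value": fs.values[ok],
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_long_format(path: str | Path) -> dict[str, dict[str, FeatureSeries]]:
    """Read the long CSV back into grid-checked per-participant tracks.

    Seconds absent from the file inside a track's span become NaN (missing
    is explicit, never dropped); duplicate (participant, t, feature) rows
    are an error naming the offending row.
    """
    df = pd.read_csv(path)
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"long-format file missing columns {sorted(missing)}")
    if not np.array_equal(df["t_s"], df["t_s"].astype(int)):
        raise InputError("t_s must be integer seconds")
    dup = df.duplicated(subset=["participant_id", "t_s", "feature"])
    if dup.any():
        row = df[dup].iloc[0]
        raise InputError("duplicate key row: participant "
                         f"{row['participant_id']}, t={row['t_s']}, "
                         f"feature {row['feature']}")
    out: dict[str, dict[str, FeatureSeries]] = {}
    for (pid, feat), g in df.groupby(["participant_id", "feature"], sort=True):
        t = g["t_s"].to_numpy(dtype=int)
        order = np.argsort(t)
        t, v = t[order], g["value"].to_numpy()[order]
        t0, t1 = int(t[0]), int(t[-1])
        vals = np.full(t1 - t0 + 1, np.nan)
        vals[t - t0] = v
        out.setdefault(str(pid), {})[str(feat)] = FeatureSeries(str(feat), vals, t0)
    return out


# ---------------------------------------------------------------------------
# session structure files

def write_dyad_map(dyad_map: DyadMap, path: str | Path) -> None:
    rows = [{"room_id": room.room_id, "participant_a": a, "participant_b": b}
            for room in dyad_map.rooms for a, b in room.dyads]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dyad_map(path: str | Path) -> DyadMap:
    df = pd.read_csv(path)
    rooms = [Room(str(rid), [(str(r.participant_a), str(r.participant_b))
                             for r in g.itertuples()])
             for rid, g in df.groupby("room_id", sort=True)]
    return DyadMap(rooms)


def write_event_log(log: SessionLog, path: str | Path) -> None:
    pd.DataFrame([{"t_s": e.t, "dyad_id": e.dyad_id, "kind": e.kind,
                   "outcome": e.outcome} for e in log.events]
                 ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[Event]:
    df = pd.read_csv(path)
    return [Event(float(r.t_s), str(r.kind), str(r.outcome), str(r.dyad_id))
            for r in df.itertuples()]


def write_role_schedule(log: SessionLog, path: str | Path) -> None:
    rows = [{"participant_id": pid, "start_s": iv.start_s, "end_s": iv.end_s,
             "role": iv.role}
            for pid in sorted(log.role_schedule)
            for iv in log.role_schedule[pid]]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_role_schedule(path: str | Path) -> dict[str, list[RoleInterval]]:
    df = pd.read_csv(path)
    out: dict[str, list[RoleInterval]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.participant_id), []).append(
            RoleInterval(float(r.start_s), float(r.end_s), str(r.role)))
    for ivals in out.values():
        ivals.sort(key=lambda iv: iv.start_s)
    return out


def write_task_changes(log: SessionLog, path: str | Path) -> None:
    pd.DataFrame({"t_s": log.task_changes}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# raw per-participant signals

def write_beats(beats: BeatSeries, path: str | Path) -> None:
    pd.DataFrame({"beat_time_s": beats.beat_times}).to_csv(path, index=False)


def read_beats(path: str | Path) -> BeatSeries:
    return BeatSeries(pd.read_csv(path)["beat_time_s"].to_numpy())


def write_eda(eda: EdaRaw, path: str | Path) -> None:
    df = pd.DataFrame({"conductance_uS": eda.samples})
    df.to_csv(path, index=False)
    Path(str(path) + ".meta.json").write_text(
        json.dumps({"sample_rate": eda.sample_rate, "t0": eda.t0}))


def read_eda(path: str | Path) -> EdaRaw:
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    samples = pd.read_csv(path)["conductance_uS"].to_numpy()
    return EdaRaw(samples, meta["sample_rate"], meta["t0"])


def write_classroom(classroom: SyntheticClassroom, out_dir: str | Path) -> None:
    """Materialise a classroom in the same formats the readers accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dyad_map(classroom.dyad_map, out / "dyad_map.csv")
    write_event_log(classroom.session_log, out / "events.csv")
    write_role_schedule(classroom.session_log, out / "role_schedule.csv")
    write_task_changes(classroom.session_log, out / "task_changes.csv")
    raw = out / "raw"
    raw.mkdir(exist_ok=True)
    for pid, part in sorted(classroom.participants.items()):
        if part.beats is not None:
            write_beats(part.beats, raw / f"{pid}_beats.csv")
        if part.eda is not None:
            write_eda(part.eda, raw / f"{pid}_eda.csv")


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """All tunables of the two pipelines, with every seed recorded."""

    sim: SimConfig = field(default_factory=SimConfig)
    window_lengths: tuple[int, ...] = (60, 300)
    overlap_frac: float = 1.0 / 3.0
    n_boot: int = 10_000
    n_perm: int = 1000
    alpha: float = 0.05
    lag_s: int = 10
    event_window_s: tuple[int, int] = (-10, 10)
    min_event_separation_s: float = 10.0
    seeds: dict = field(default_factory=lambda: {
        "simulation": 0, "bootstrap": 1, "split": 2, "permutation": 3})

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    """Recursively coerce to JSON-serialisable form (tuple keys -> strings)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in raw.pop("sim", {}).items()})
    for key in ("window_lengths", "event_window_s"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(sim=sim, **raw)


def write_metadata(path: str | Path, config: PipelineConfig, **counts) -> None:
    """Stage metadata: config hash + seeds + bookkeeping counts."""
    meta = {"config_hash": config.config_hash(), "seeds": config.seeds,
            **counts}
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
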