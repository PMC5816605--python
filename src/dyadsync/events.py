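"""Event-locked skin-conductance analysis.

Run/test events (the dyad compiles/runs the code or executes the assignment
tests) are pooled, thinned so that retained events are at least 10 s apart,
and epoched on the z-scored SCR track in a window of 10 s before to 10 s
after each event (21 samples at 1 Hz, event at index 10).  Epochs are
classified by the participant's role at event time (drive / navigate) and
the event outcome (pass / fail); per-participant condition means are
averaged with equal weights into grand averages, so productive dyads do not
dominate.  Lagged-difference curves (x(t) - x(t-10 s)) and per-participant
condition-difference curves feed the envelope-band inference stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import InputError
from .series import FeatureSeries

Role = Literal["drive", "navigate"]
Outcome = Literal["pass", "fail"]

EPOCH_WINDOW_S = (-10, 10)
MIN_EVENT_SEPARATION_S = 10.0
LAG_S = 10

ROLES: tuple[Role, ...] = ("drive", "navigate")
OUTCOMES: tuple[Outcome, ...] = ("pass", "fail")


@dataclass(frozen=True)
class Event:
    t: float
    kind: Literal["run", "test"]
    outcome: Outcome
    dyad_id: str


@dataclass
class RoleInterval:
    start_s: float
    end_s: float
    role: Role


@dataclass
class SessionLog:
    """Events, role schedule, and task changes for one classroom session."""

    events: list[Event]
    role_schedule: dict[str, list[RoleInterval]]   # participant -> intervals
    task_changes: list[float] = field(default_factory=list)
    room_id: str | None = None

    def __post_init__(self):
        for pid, ivals in self.role_schedule.items():
            for a, b in zip(ivals, ivals[1:]):
                if b.start_s < a.end_s:
                    raise InputError(f"overlapping role intervals for {pid}")

    def role_of(self, participant_id: str, t: float) -> Role | None:
        for iv in self.role_schedule.get(participant_id, ()):
            if iv.start_s <= t < iv.end_s:
                return iv.role
        return None

    def role_switch_times(self, participant_id: str | None = None) -> list[float]:
        """Instants at which any (or one) participant's role changes."""
        pids = [participant_id] if participant_id else list(self.role_schedule)
        times: set[float] = set()
        for pid in pids:
            ivals = self.role_schedule.get(pid, ())
            for iv in ivals[1:]:
                times.add(iv.start_s)
        return sorted(times)


# ---------------------------------------------------------------------------
# event filtering and epoching

def filter_events(events: Sequence[Event],
                  min_sep: float = MIN_EVENT_SEPARATION_S) -> list[Event]:
    """Thin dense event clusters, keeping the first event of each cluster.

    Per dyad (run and test kinds pooled), an event is retained iff its
    latency from the previously *retained* event is at least ``min_sep``;
    the first event is always retained.  Idempotent.
    """
    out: list[Event] = []
    last_kept: dict[str, float] = {}
    for ev in sorted(events, key=lambda e: (e.dyad_id, e.t)):
        t_prev = last_kept.get(ev.dyad_id)
        if t_prev is None or ev.t - t_prev >= min_sep:
            out.append(ev)
            last_kept[ev.dyad_id] = ev.t
    out.sort(key=lambda e: e.t)
    return out


@dataclass
class Epoch:
    participant_id: str
    event: Event
    role: Role
    values: np.ndarray    # 21 samples, t = -10 .. +10 s


def epoch_scr(track: FeatureSeries, events: Iterable[Event],
              participant_id: str, log: SessionLog,
              window: tuple[int, int] = EPOCH_WINDOW_S,
              ) -> tuple[list[Epoch], int]:
    """Extract event-locked epochs from one participant's (z-scored) track.

    Returns the epochs plus the count of events dropped because the window
    would extend past the recording edges.  Each epoch spans ``window``
    inclusive (21 samples for the default +/-10 s) with the event second at
    the centre index.
    """
    lo, hi = window
    n_dropped = 0
    epochs: list[Epoch] = []
    for ev in events:
        t = int(round(ev.t))
        vals = track.slice_seconds(t + lo, t + hi + 1)
        if np.any(~np.isfinite(vals)):
            n_dropped += 1
            continue
        role = log.role_of(participant_id, ev.t)
        if role is None:
            n_dropped += 1
            continue
        epochs.append(Epoch(participant_id, ev, role, vals))
    return epochs, n_dropped


# ---------------------------------------------------------------------------
# condition averages

Condition = tuple[str, str]   # (role or "pooled", outcome or "pooled")


def _conditions() -> list[Condition]:
    conds: list[Condition] = [(r, o) for r in ROLES for o in OUTCOMES]
    conds += [(r, "pooled") for r in ROLES]
    conds += [("pooled", o) for o in OUTCOMES]
    conds.append(("pooled", "pooled"))
    return conds


@dataclass
class EpochSet:
    """Per-participant means and the equal-weight grand average for one condition."""

    condition: Condition
    per_participant_means: dict[str, np.ndarray]
    counts: dict[str, int]

    @property
    def grand_mean(self) -> np.ndarray:
        if not self.per_participant_means:
            raise InputError(f"empty condition {self.condition}")
        return np.mean(list(self.per_participant_means.values()), axis=0)

    @property
    def n_participants(self) -> int:
        return len(self.per_participant_means)


def condition_grand_average(epochs: Sequence[Epoch],
                            room_of_participant: dict[str, str] | None = None,
                            room_id: str | None = None,
                            ) -> dict[Condition, EpochSet]:
    """Equal-weight condition averages over the four role x outcome cells
    plus pooled margins.

    Every participant contributes one curve (their own epoch mean) per
    condition; participants with zero epochs in a condition are absent, not
    zero-filled.  ``room_id`` restricts the average to one room's
    participants (subgroup comparisons).
    """
    if room_id is not None:
        if room_of_participant is None:
            raise InputError("room filter requires a participant->room map")
        epochs = [e for e in epochs
                  if room_of_participant.get(e.participant_id) == room_id]
    out: dict[Condition, EpochSet] = {}
    for cond in _conditions():
        role_c, out_c = cond
        per: dict[str, list[np.ndarray]] = {}
        for e in epochs:
            if role_c != "pooled" and e.role != role_c:
                continue
            if out_c != "pooled" and e.event.outcome != out_c:
                continue
            per.setdefault(e.participant_id, []).append(e.values)
        out[cond] = EpochSet(
            condition=cond,
            per_participant_means={p: np.mean(v, axis=0) for p, v in per.items()},
            counts={p: len(v) for p, v in per.items()},
        )
    return out


def lagged_difference(track: FeatureSeries, lag: int = LAG_S) -> FeatureSeries:
    """Difference of a track and itself lagged: d(t) = x(t) - x(t - lag).

    Computed on the continuous track before epoching so that the leading
    samples of an epoch window have context; the first ``lag`` seconds of
    the session are missing-flagged.
    """
    x = track.values
    d = np.full_like(x, np.nan)
    d[lag:] = x[lag:] - x[:-lag]
    return FeatureSeries(track.name + "_d", d, track.t0, track.units)


def condition_difference_curves(epoch_sets: dict[Condition, EpochSet],
                                contrast: Literal["role", "outcome"],
                                min_participants: int = 3,
                                ) -> tuple[np.ndarray, list[str]]:
    """Per-participant difference curves for a role or outcome contrast.

    role contrast: drive - navigate (outcomes pooled);
    outcome contrast: pass - fail (roles pooled).
    Participants lacking a mean in either condition are excluded.  Returns
    an (n_participants, n_samples) array and the contributing ids.
    """
    if contrast == "role":
        a, b = epoch_sets[("drive", "pooled")], epoch_sets[("navigate", "pooled")]
    elif contrast == "outcome":
        a, b = epoch_sets[("pooled", "pass")], epoch_sets[("pooled", "fail")]
    else:
        raise InputError(f"unknown contrast {contrast!r}")
    shared = sorted(set(a.per_participant_means) & set(b.per_participant_means))
    if len(shared) < min_participants:
        raise InputError(
            f"{contrast} contrast has only {len(shared)} participants with both "
            f"conditions (need >= {min_participants}); inference refused")
    curves = np.array([a.per_participant_means[p] - b.per_participant_means[p]
                       for p in shared])
    return curves, shared
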