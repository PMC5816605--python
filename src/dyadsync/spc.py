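"""Social physiological compliance (SPC) index and its bootstrap null.

SPC is operationalised as the arithmetic mean, over collaborating dyads, of
the within-dyad Pearson correlation of a per-second feature track.  The null
hypothesis — the observed compliance is an environmental (classroom)
confound rather than dyad-specific coupling — is sampled by repeatedly
drawing, within each room, as many random pairs of co-located participants
as there are true dyads and recording the mean of their correlations.  The
null distribution yields a percentile confidence interval and a one-tailed
p-value; p-values across features are corrected with the Holm-Bonferroni
step-down procedure.

Windows overlapping protocol-forced behaviour (task changes, role switches)
can be removed before correlation, mirroring the filtered analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence
import warnings

import numpy as np
from statsmodels.stats.multitest import multipletests

from .ecg import WindowedFeature
from .events import SessionLog
from .exceptions import InputError
from .series import FeatureSeries, aligned_values

DEFAULT_N_BOOT = 10_000
MIN_PAIRWISE_SECONDS = 30


@dataclass
class Room:
    room_id: str
    dyads: list[tuple[str, str]]

    @property
    def participants(self) -> list[str]:
        return [p for d in self.dyads for p in d]


@dataclass
class DyadMap:
    """Disjoint dyads grouped into rooms (recording sessions)."""

    rooms: list[Room]

    def __post_init__(self):
        seen: set[str] = set()
        for room in self.rooms:
            for a, b in room.dyads:
                if a == b or a in seen or b in seen:
                    raise InputError(f"dyad ({a}, {b}) not disjoint")
                seen.update((a, b))

    @property
    def dyads(self) -> list[tuple[str, str]]:
        return [d for r in self.rooms for d in r.dyads]

    @property
    def participants(self) -> list[str]:
        return [p for r in self.rooms for p in r.participants]

    def room_of(self) -> dict[str, str]:
        return {p: r.room_id for r in self.rooms for p in r.participants}


@dataclass
class SpcResult:
    """Dyad-mean correlation with its room-constrained bootstrap null."""

    feature_name: str
    dyad_mean: float
    null_samples: np.ndarray
    ci: tuple[float, float]
    p_raw: float
    n_dyads: int
    p_adj: float | None = None
    per_dyad: dict = field(default_factory=dict)
    retained_fraction: float = 1.0

    @property
    def exceeds_ci(self) -> bool:
        return self.dyad_mean > self.ci[1]


# ---------------------------------------------------------------------------
# correlations

def pairwise_correlation(a: FeatureSeries, b: FeatureSeries,
                         min_seconds: int = MIN_PAIRWISE_SECONDS) -> float:
    """Pearson correlation over pairwise-complete seconds; NaN if degenerate."""
    x, y = aligned_values(a, b)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_seconds:
        raise InputError(f"only {int(ok.sum())} pairwise-complete seconds "
                         f"(need >= {min_seconds})")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def dyad_mean_correlation(tracks: Mapping[str, FeatureSeries],
                          dyad_map: DyadMap) -> tuple[float, dict]:
    """Unweighted mean of within-dyad Pearson correlations.

    Dyads with a degenerate (zero-variance) track are excluded with a
    warning; an error is raised if no dyad survives.
    """
    per: dict[tuple[str, str], float] = {}
    for a, b in dyad_map.dyads:
        r = pairwise_correlation(tracks[a], tracks[b])
        if np.isnan(r):
            warnings.warn(f"dyad ({a}, {b}) excluded: degenerate track")
            continue
        per[(a, b)] = r
    if not per:
        raise InputError("all dyads degenerate; no correlation computable")
    return float(np.mean(list(per.values()))), per


def _room_corr_matrix(tracks: Mapping[str, FeatureSeries],
                      pids: Sequence[str]) -> np.ndarray:
    """Within-room correlation matrix over pairwise-complete seconds."""
    n = len(pids)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            try:
                r = pairwise_correlation(tracks[pids[i]], tracks[pids[j]])
            except InputError:
                r = np.nan
            mat[i, j] = mat[j, i] = r
    return mat


def shuffled_pair_null(tracks: Mapping[str, FeatureSeries],
                       dyad_map: DyadMap,
                       feature_name: str = "",
                       n_boot: int = DEFAULT_N_BOOT,
                       alpha: float = 0.05,
                       rng: np.random.Generator | int | None = None,
                       ) -> SpcResult:
    """Room-constrained shuffled-pair bootstrap null for the SPC index.

    Each of ``n_boot`` replicates draws, per room, as many unordered random
    pairs of distinct co-located participants as that room has true dyads —
    without replacement within a replicate, so a participant appears in at
    most one drawn pair per room per replicate — and records the mean of
    the drawn pair correlations.  Returns the null samples, the percentile
    CI at level 1 - alpha, and the one-tailed add-one p-value
    (1 + #{null >= observed}) / (1 + n_boot).
    """
    rng = np.random.default_rng(rng)
    dyad_mean, per = dyad_mean_correlation(tracks, dyad_map)

    room_draws: list[np.ndarray] = []   # per room: (n_boot, n_pairs) correlations
    n_pairs_total = 0
    for room in dyad_map.rooms:
        pids = room.participants
        if len(pids) < 2:
            warnings.warn(f"room {room.room_id} has < 2 participants; skipped")
            continue
        mat = _room_corr_matrix(tracks, pids)
        n_pairs = min(len(room.dyads), len(pids) // 2)
        # (n_boot, n) independent permutations; adjacent columns form pairs
        perms = np.argsort(rng.random((n_boot, len(pids))), axis=1)
        i_idx = perms[:, 0:2 * n_pairs:2]
        j_idx = perms[:, 1:2 * n_pairs:2]
        room_draws.append(mat[i_idx, j_idx])
        n_pairs_total += n_pairs
    if not room_draws:
        raise InputError("no room with >= 2 participants")

    all_draws = np.concatenate(room_draws, axis=1)      # (n_boot, total pairs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # replicates w/ no valid pair
        null_samples = np.nanmean(all_draws, axis=1)
    null_samples = null_samples[np.isfinite(null_samples)]
    if null_samples.size < max(100, n_boot // 10):
        raise InputError("too few valid bootstrap replicates "
                         f"({null_samples.size}/{n_boot}); tracks too degenerate")
    lo, hi = np.percentile(null_samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p_raw = (1 + int(np.sum(null_samples >= dyad_mean))) / (1 + null_samples.size)
    return SpcResult(feature_name=feature_name, dyad_mean=dyad_mean,
                     null_samples=null_samples, ci=(float(lo), float(hi)),
                     p_raw=p_raw, n_dyads=len(per), per_dyad=per)


# ---------------------------------------------------------------------------
# multiple-comparison correction

def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="holm")[1])


# ---------------------------------------------------------------------------
# forced-behaviour filtering

FilterMode = Literal["task_change", "task_and_role"]


def filter_forced_behaviour(windowed: WindowedFeature, log: SessionLog,
                            mode: FilterMode = "task_change",
                            low_retention_warn: float = 0.2,
                            ) -> tuple[WindowedFeature, float]:
    """Drop feature windows overlapping protocol-forced behaviour.

    A half-open window [start, start+len) is removed when it contains a
    task-change instant; in mode ``task_and_role`` also when it contains a
    role-switch instant.  Returns the filtered windows and the retained
    fraction; a warning is issued when retention falls below
    ``low_retention_warn`` (the filtered estimate is then unreliable).
    """
    instants = list(log.task_changes)
    if mode == "task_and_role":
        instants += log.role_switch_times()
    elif mode != "task_change":
        raise InputError(f"unknown filter mode {mode!r}")
    instants_arr = np.asarray(sorted(instants), dtype=float)

    starts, vals = windowed.starts, windowed.values
    if instants_arr.size == 0:
        return windowed, 1.0
    lo = np.searchsorted(instants_arr, starts, side="left")
    hi = np.searchsorted(instants_arr, starts + windowed.window_len, side="left")
    keep = hi == lo       # no instant inside the window
    retained = float(keep.mean()) if starts.size else 1.0
    if retained < low_retention_warn:
        warnings.warn(f"forced-behaviour filter retained only {retained:.0%} "
                      "of windows; filtered estimate unreliable")
    out = WindowedFeature(windowed.name, starts[keep], vals[keep],
                          windowed.window_len, windowed.units)
    return out, retained
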