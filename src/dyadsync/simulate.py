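"""Synthetic classroom sessions with known ground-truth coupling.

The generator emulates the study setting end to end so every downstream
stage is testable without recorded data: rooms of pair-programming dyads,
per-participant raw EDA (nominal 51.2 Hz) and beat series (ms precision),
role-switch schedules in 7-minute blocks with self-paced switch delays, and
run/test events with role- and outcome-specific skin-conductance responses
1-3 s after each event.

Coupling model
--------------
A slow arousal component is shared within dyads and within rooms.  With
independent unit-variance latents R (room), D (dyad) and E (individual),
each participant's slow component is

    s_i = sqrt(c_room) * R + sqrt(max(0, c_dyad - c_room)) * D
          + sqrt(1 - max(c_dyad, c_room)) * E,

so the within-dyad latent correlation is max(c_dyad, c_room) and the
within-room, cross-dyad correlation is c_room.  The component modulates the
log-IBI variance (so SDNN tracks carry the coupling) and the tonic EDA
drift.  Heart rate declines slowly from session start via an upward IBI
baseline drift.

Events are placed by a homogeneous Poisson process thinned to a 1 s minimum
separation (the event-logger granularity); each event injects a driver
impulse into both dyad members' EDA with the role x outcome amplitude and
lag from the configuration, convolved with the Bateman impulse response.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .ecg import BeatSeries
from .eda import EdaRaw, IrfParams
from .events import Event, RoleInterval, SessionLog
from .exceptions import ConfigError
from .spc import DyadMap, Room


def _default_response_amp() -> dict[tuple[str, str], float]:
    # failure is more arousing than success, and more so for the driver
    return {("drive", "fail"): 0.9, ("drive", "pass"): 0.55,
            ("navigate", "fail"): 0.55, ("navigate", "pass"): 0.40}


def _default_response_lag() -> dict[tuple[str, str], float]:
    # responses 1-3 s post-event; the navigator lags the driver
    return {("drive", "fail"): 1.5, ("drive", "pass"): 1.5,
            ("navigate", "fail"): 2.5, ("navigate", "pass"): 2.5}


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic classroom."""

    n_rooms: int = 4
    dyads_per_room: int = 7
    session_len: int = 1800                    # seconds
    dyad_coupling: float = 0.3                 # within-dyad slow-component corr
    room_coupling: float = 0.1                 # within-room slow-component corr
    event_rate: float = 0.4                    # run/test events per minute per dyad
    pass_prob: float = 0.35                    # successes are the rarer outcome
    response_amp: dict = field(default_factory=_default_response_amp)   # uS mass
    response_lag: dict = field(default_factory=_default_response_lag)   # seconds
    role_block: float = 420.0                  # 7-minute role maintenance
    switch_delay_range: tuple[float, float] = (2.0, 20.0)   # self-paced delay
    irf_tau: tuple[float, float] = (0.75, 2.0)
    noise_sd: dict = field(default_factory=lambda: {"eda": 0.02, "log_ibi": 0.05})
    seed: int = 0
    sample_rate: float = 51.2                  # raw EDA rate
    channels: tuple[str, ...] = ("ecg", "eda")

    # secondary physiology defaults
    base_ibi_ms: float = 850.0
    ibi_drift_frac: float = 0.06               # IBI rises (HR falls) over the session
    sdnn_gain: float = 0.35                    # log-variance modulation strength
    slow_timescale_s: float = 30.0
    spontaneous_scr_per_min: float = 3.0
    task_change_rate_per_min: float = 0.12

    def validate(self) -> None:
        checks = {
            "n_rooms": self.n_rooms >= 1,
            "dyads_per_room": self.dyads_per_room >= 1,
            "session_len": self.session_len > 0,
            "dyad_coupling": 0 <= self.dyad_coupling <= 1,
            "room_coupling": 0 <= self.room_coupling <= 1,
            "event_rate": self.event_rate >= 0,
            "pass_prob": 0 <= self.pass_prob <= 1,
            "role_block": self.role_block > 0,
            "switch_delay_range": 0 <= self.switch_delay_range[0] <= self.switch_delay_range[1],
            "irf_tau": 0 < self.irf_tau[0] < self.irf_tau[1],
            "sample_rate": self.sample_rate > 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ConfigError(name, f"value {getattr(self, name)!r} out of range")
        if not (self.dyad_coupling == 0 or self.dyad_coupling >= self.room_coupling):
            raise ConfigError("dyad_coupling",
                              "must be 0 or >= room_coupling (see coupling model)")


@dataclass
class Participant:
    participant_id: str
    dyad_id: str
    room_id: str
    beats: BeatSeries | None
    eda: EdaRaw | None


@dataclass
class SyntheticClassroom:
    participants: dict[str, Participant]
    session_log: SessionLog
    dyad_map: DyadMap
    ground_truth: dict
    config: SimConfig


# ---------------------------------------------------------------------------

def _slow_component(rng: np.random.Generator, n: int, timescale_s: float) -> np.ndarray:
    """Unit-variance smooth (GP-like) component on the 1 Hz grid."""
    x = gaussian_filter1d(rng.standard_normal(n + 8 * int(timescale_s)),
                          sigma=timescale_s, mode="wrap")[: n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _beat_times(rng: np.random.Generator, cfg: SimConfig, s_slow: np.ndarray
                ) -> np.ndarray:
    """Vectorised lognormal IBI process around a drifting baseline.

    Slow components are evaluated at approximate beat times (they vary over
    ~30 s, so the approximation is immaterial); the fast log-IBI noise scale
    is modulated by exp(sdnn_gain * s_i), which carries the injected
    coupling into the SDNN tracks.
    """
    T = cfg.session_len
    n_max = int(T * 1000.0 / (0.6 * cfg.base_ibi_ms)) + 8
    t_approx = np.arange(n_max) * cfg.base_ibi_ms / 1000.0
    t_approx = np.clip(t_approx, 0, T - 1)
    s_at = s_slow[t_approx.astype(int)]
    base = cfg.base_ibi_ms * (1.0 + cfg.ibi_drift_frac * t_approx / T)
    sigma = cfg.noise_sd["log_ibi"] * np.exp(cfg.sdnn_gain * s_at)
    ibis_ms = np.exp(np.log(base) + sigma * rng.standard_normal(n_max))
    beats = np.cumsum(ibis_ms) / 1000.0
    return beats[beats <= T]


def _role_schedule(rng: np.random.Generator, cfg: SimConfig, a: str, b: str
                   ) -> dict[str, list[RoleInterval]]:
    """Alternating drive/navigate blocks with self-paced switch delays."""
    first_driver = a if rng.random() < 0.5 else b
    t = 0.0
    sched: dict[str, list[RoleInterval]] = {a: [], b: []}
    driver = first_driver
    while t < cfg.session_len:
        delay = rng.uniform(*cfg.switch_delay_range) if t > 0 else 0.0
        start = min(t + delay, cfg.session_len)
        end = min(start + cfg.role_block, cfg.session_len)
        if end > start:
            navigator = b if driver == a else a
            sched[driver].append(RoleInterval(start, end, "drive"))
            sched[navigator].append(RoleInterval(start, end, "navigate"))
        t = start + cfg.role_block
        driver = b if driver == a else a
    return sched


def _dyad_events(rng: np.random.Generator, cfg: SimConfig, dyad_id: str
                 ) -> list[Event]:
    """Homogeneous Poisson run/test events, thinned to >= 1 s separation."""
    lo, hi = 60.0, max(cfg.session_len - 30.0, 61.0)
    n = rng.poisson(cfg.event_rate * (hi - lo) / 60.0)
    times = np.sort(rng.uniform(lo, hi, n))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= 1.0:
            kept.append(float(t))
    evs = []
    for t in kept:
        kind = "run" if rng.random() < 0.75 else "test"
        outcome = "pass" if rng.random() < cfg.pass_prob else "fail"
        evs.append(Event(round(t, 0), kind, outcome, dyad_id))
    return evs


def _eda_trace(rng: np.random.Generator, cfg: SimConfig, s_slow: np.ndarray,
               impulses: list[tuple[float, float]]) -> tuple[EdaRaw, np.ndarray]:
    """Tonic drift + (driver impulses (x) Bateman IRF) + noise at sample_rate."""
    fs = cfg.sample_rate
    n = int(round(cfg.session_len * fs))
    t_sec = np.minimum((np.arange(n) / fs).astype(int), cfg.session_len - 1)

    scl0 = rng.uniform(1.5, 4.0)
    walk = gaussian_filter1d(rng.standard_normal(n), sigma=60.0 * fs,
                             mode="nearest")
    walk *= 0.3 / max(walk.std(), 1e-12)
    tonic = scl0 + 0.25 * s_slow[t_sec] + walk

    # driver is a density (uS/s); an impulse of mass A uS.s occupies one sample
    driver = np.zeros(n)
    n_spont = rng.poisson(cfg.spontaneous_scr_per_min * cfg.session_len / 60.0)
    for t in rng.uniform(0, cfg.session_len, n_spont):
        driver[min(int(t * fs), n - 1)] += rng.exponential(0.25) * fs
    for t, amp in impulses:
        i = int(round(t * fs))
        if 0 <= i < n:
            driver[i] += amp * fs

    kernel = IrfParams(*cfg.irf_tau).kernel(fs)
    scr = np.convolve(driver, kernel)[:n] / fs
    samples = tonic + scr + rng.normal(0.0, cfg.noise_sd["eda"], n)
    return EdaRaw(np.clip(samples, 0.011, None), fs), driver


def generate_classroom(config: SimConfig) -> SyntheticClassroom:
    """Generate a full synthetic classroom (deterministic under the seed)."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = cfg.session_len

    w_room = np.sqrt(cfg.room_coupling)
    w_dyad = np.sqrt(max(0.0, cfg.dyad_coupling - cfg.room_coupling))
    w_ind = np.sqrt(max(0.0, 1.0 - w_room ** 2 - w_dyad ** 2))

    rooms: list[Room] = []
    participants: dict[str, Participant] = {}
    events: list[Event] = []
    role_schedule: dict[str, list[RoleInterval]] = {}
    truth_components: dict[str, np.ndarray] = {}
    truth_impulses: dict[str, list[tuple[float, float]]] = {}

    pid_counter = 1
    for r in range(cfg.n_rooms):
        room_id = f"room{r + 1}"
        R = _slow_component(rng, T, cfg.slow_timescale_s)
        dyads: list[tuple[str, str]] = []
        for d in range(cfg.dyads_per_room):
            dyad_id = f"{room_id}_d{d + 1}"
            D = _slow_component(rng, T, cfg.slow_timescale_s)
            a, b = f"p{pid_counter:03d}", f"p{pid_counter + 1:03d}"
            pid_counter += 2
            dyads.append((a, b))

            sched = _role_schedule(rng, cfg, a, b)
            role_schedule.update(sched)
            dyad_events = _dyad_events(rng, cfg, dyad_id)
            events.extend(dyad_events)

            for pid in (a, b):
                E = _slow_component(rng, T, cfg.slow_timescale_s)
                s = w_room * R + w_dyad * D + w_ind * E
                truth_components[pid] = s

                impulses: list[tuple[float, float]] = []
                log = SessionLog([], {pid: sched[pid]})
                for ev in dyad_events:
                    role = log.role_of(pid, ev.t)
                    if role is None:
                        continue
                    key = (role, ev.outcome)
                    impulses.append((ev.t + cfg.response_lag[key],
                                     cfg.response_amp[key]))
                truth_impulses[pid] = impulses

                beats = (BeatSeries(_beat_times(rng, cfg, s))
                         if "ecg" in cfg.channels else None)
                eda = None
                if "eda" in cfg.channels:
                    eda, _ = _eda_trace(rng, cfg, s, impulses)
                participants[pid] = Participant(pid, dyad_id, room_id, beats, eda)
        rooms.append(Room(room_id, dyads))

    events.sort(key=lambda e: e.t)
    n_changes = np.random.default_rng(cfg.seed + 1).poisson(
        cfg.task_change_rate_per_min * T / 60.0 * cfg.n_rooms)
    task_changes = sorted(np.random.default_rng(cfg.seed + 2)
                          .uniform(0, T, n_changes).tolist())
    log = SessionLog(events, role_schedule, task_changes)
    dyad_map = DyadMap(rooms)
    truth = {
        "dyad_coupling": max(cfg.dyad_coupling, cfg.room_coupling)
        if cfg.dyad_coupling > 0 else cfg.room_coupling,
        "excess_dyad_coupling": (max(0.0, cfg.dyad_coupling - cfg.room_coupling)
                                 if cfg.dyad_coupling > 0 else 0.0),
        "room_coupling": cfg.room_coupling,
        "components": truth_components,
        "impulses": truth_impulses,
    }
    return SyntheticClassroom(participants, log, dyad_map, truth, cfg)


def generate_null_classroom(config: SimConfig) -> SyntheticClassroom:
    """Classroom with no dyad-specific coupling and equalised event responses.

    Room-level coupling is retained, so the null classroom keeps the
    environmental confound that the room-restricted bootstrap is designed
    to absorb; all SPC and envelope tests are under their null on this
    output.
    """
    amp = np.mean(list(config.response_amp.values()))
    lag = np.mean(list(config.response_lag.values()))
    flat_amp = {k: float(amp) for k in config.response_amp}
    flat_lag = {k: float(lag) for k in config.response_lag}
    null_cfg = replace(copy.deepcopy(config), dyad_coupling=0.0,
                       response_amp=flat_amp, response_lag=flat_lag)
    out = generate_classroom(null_cfg)
    out.ground_truth["excess_dyad_coupling"] = 0.0
    return out
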