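"""Cardiac feature tracks from beat series.

The input contract starts at R-peak times (beat times in seconds on the
session clock); R-peak detection from raw ECG is upstream of this package.
From the inter-beat-interval (IBI) series we compute:

* windowed mean heart rate (HR) and SDNN — the standard deviation of
  normal-to-normal IBIs — in 60 s and 300 s windows that overlap by one
  third (steps of 20 s and 100 s), step-hold upsampled to 1 Hz; and
* per-second instantaneous heart rate (HR1), the inverse of the mean IBI
  terminating in each second.

SDNN uses the sample (n-1) standard deviation, the dominant convention in
HRV tooling.  Beats are screened for abnormal (e.g. ectopic) intervals
before windowing: IBIs outside a physiological range or deviating more
than a relative tolerance from a running median are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .exceptions import InputError
from .series import FeatureSeries

#: Default abnormal-beat screen: physiological IBI range (ms) and the maximum
#: relative deviation from the running median before an IBI is excluded.
IBI_RANGE_MS = (300.0, 2000.0)
IBI_MEDIAN_TOL = 0.30
_MEDIAN_KERNEL = 11

#: HR1 forward fill is capped: seconds more than this far from the last beat
#: stay missing instead of carrying a fabricated value.
HR1_MAX_FFILL_S = 3


@dataclass
class BeatSeries:
    """R-peak times for one participant session.

    ``beat_times`` are seconds from session-clock zero, strictly increasing.
    ``ibis`` are the successive differences in milliseconds.
    """

    beat_times: np.ndarray

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size == 0:
            raise InputError("empty beat series")
        if self.beat_times.ndim != 1 or np.any(np.diff(self.beat_times) <= 0):
            raise InputError("beat times must be 1-D and strictly increasing")

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals in ms; ibis[n] terminates at beat_times[n+1]."""
        return np.diff(self.beat_times) * 1000.0

    def __len__(self) -> int:
        return self.beat_times.size


def normal_ibi_mask(ibis: np.ndarray,
                    ibi_range_ms: tuple[float, float] = IBI_RANGE_MS,
                    median_tol: float = IBI_MEDIAN_TOL) -> np.ndarray:
    """True for IBIs that pass the normal-beat screen."""
    ibis = np.asarray(ibis, dtype=float)
    ok = (ibis >= ibi_range_ms[0]) & (ibis <= ibi_range_ms[1])
    if ibis.size >= 3:
        k = min(_MEDIAN_KERNEL, ibis.size if ibis.size % 2 == 1 else ibis.size - 1)
        running = medfilt(ibis, kernel_size=k)
        with np.errstate(divide="ignore", invalid="ignore"):
            ok &= np.abs(ibis - running) <= median_tol * running
    return ok


@dataclass
class WindowedFeature:
    """Feature values attached to window start times (pre-upsampling)."""

    name: str
    starts: np.ndarray   # window start seconds
    values: np.ndarray   # one value per window, NaN where < 2 usable IBIs
    window_len: float
    units: str = ""


def windowed_features(beats: BeatSeries,
                      window_len: float = 60.0,
                      overlap_frac: float = 1.0 / 3.0,
                      screen_abnormal: bool = True,
                      ) -> tuple[WindowedFeature, WindowedFeature]:
    """Windowed mean HR and SDNN over half-open windows [start, start+len).

    Successive windows overlap by ``overlap_frac`` (default one third, i.e.
    steps of 20 s / 100 s for the 60 s / 300 s windows).  An IBI belongs to
    the window containing its terminating beat.  Windows extending past the
    last beat are not emitted; windows with fewer than two usable IBIs are
    flagged missing (NaN), not raised.
    """
    if window_len <= 0:
        raise InputError("window_len must be positive")
    if not (0 <= overlap_frac < 1):
        raise InputError("overlap_frac must be in [0, 1)")
    step = window_len * (1.0 - overlap_frac)
    span = beats.beat_times[-1]
    if span < window_len:
        raise InputError(f"beats span {span:.1f}s, shorter than one {window_len:.0f}s window")

    ibis = beats.ibis
    term = beats.beat_times[1:]          # terminating beat of each IBI
    good = normal_ibi_mask(ibis) if screen_abnormal else np.ones(ibis.size, bool)

    n_win = int(np.floor((span - window_len) / step + 1e-9)) + 1
    # snap float-fuzzed starts (e.g. 60 * (1 - 1/3) steps) onto clean values
    starts = np.round(np.arange(n_win) * step, 9)
    hr = np.full(n_win, np.nan)
    sdnn = np.full(n_win, np.nan)
    for w, s in enumerate(starts):
        sel = good & (term >= s) & (term < s + window_len)
        vals = ibis[sel]
        if vals.size >= 2:
            hr[w] = 60000.0 / vals.mean()
            sdnn[w] = vals.std(ddof=1)
    suffix = f"{int(round(window_len))}"
    return (WindowedFeature("HR" + suffix, starts, hr, window_len, "bpm"),
            WindowedFeature("SDNN" + suffix, starts, sdnn, window_len, "ms"))


def upsample_to_seconds(windowed: WindowedFeature, session_len: int) -> FeatureSeries:
    """Step-hold expansion of window values onto the 1 Hz session grid.

    Second ``t`` takes the value of the most recent window start <= t;
    seconds before the first window start are missing-flagged.
    """
    if windowed.values.size == 0:
        raise InputError("no window values to upsample")
    secs = np.arange(int(session_len))
    idx = np.searchsorted(windowed.starts, secs, side="right") - 1
    out = np.full(secs.size, np.nan)
    has = idx >= 0
    out[has] = windowed.values[idx[has]]
    return FeatureSeries(windowed.name, out, t0=0, units=windowed.units)


def instantaneous_hr(beats: BeatSeries,
                     session_len: int | None = None,
                     max_ffill_s: int = HR1_MAX_FFILL_S) -> FeatureSeries:
    """Per-second instantaneous HR: 60000 / mean(IBIs terminating that second).

    Seconds with no terminating beat carry the previous second's value,
    forward-filled for at most ``max_ffill_s`` seconds; leading seconds
    before any IBI stay missing.
    """
    if session_len is None:
        session_len = int(np.ceil(beats.beat_times[-1]))
    ibis = beats.ibis
    sec = np.floor(beats.beat_times[1:]).astype(int)
    keep = (sec >= 0) & (sec < session_len)
    sums = np.bincount(sec[keep], weights=ibis[keep], minlength=session_len)
    counts = np.bincount(sec[keep], minlength=session_len)

    out = np.full(session_len, np.nan)
    has = counts > 0
    out[has] = 60000.0 * counts[has] / sums[has]

    # capped forward fill
    idx = np.where(has, np.arange(session_len), -1)
    last = np.maximum.accumulate(idx)
    fill = (~has) & (last >= 0) & (np.arange(session_len) - last <= max_ffill_s)
    out[fill] = out[last[fill]]
    return FeatureSeries("HR1", out, t0=0, units="bpm")
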