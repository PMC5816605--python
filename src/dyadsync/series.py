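"""Per-second feature tracks on a common session clock.

All pipeline stages exchange :class:`FeatureSeries`: a named 1 Hz track whose
samples sit on integer seconds of the session clock (second 0 = start of the
baseline period).  Missing samples are represented explicitly as NaN, never
dropped, so tracks from different participants stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

#: Feature names used pipeline-wide.
KNOWN_FEATURES = ("HR60", "SDNN60", "HR300", "SDNN300", "HR1", "SCR", "SCL")


@dataclass
class FeatureSeries:
    """A named per-second physiological feature track.

    Parameters
    ----------
    name : str
        Feature identifier, e.g. ``"SDNN60"`` or ``"SCR"``.
    values : ndarray
        One float per second; NaN marks a missing second.
    t0 : int
        Session-clock second of the first sample.
    units : str
        ``"bpm"``, ``"ms"``, ``"uS"`` or ``"z"``.
    degenerate : bool
        Set when the track had zero variance at normalisation time.
    """

    name: str
    values: np.ndarray
    t0: int = 0
    units: str = ""
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError(f"feature track '{self.name}' must be 1-D")

    def __len__(self) -> int:
        return self.values.size

    @property
    def seconds(self) -> np.ndarray:
        """Session-clock second of every sample."""
        return self.t0 + np.arange(self.values.size)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def value_at(self, t: int) -> float:
        """Value at session second ``t`` (NaN outside the track)."""
        i = int(t) - self.t0
        if i < 0 or i >= self.values.size:
            return float("nan")
        return float(self.values[i])

    def slice_seconds(self, start: int, stop: int) -> np.ndarray:
        """Values for session seconds ``start .. stop-1``, NaN-padded."""
        out = np.full(stop - start, np.nan)
        lo = max(start, self.t0)
        hi = min(stop, self.t0 + self.values.size)
        if hi > lo:
            out[lo - start: hi - start] = self.values[lo - self.t0: hi - self.t0]
        return out


def aligned_values(a: FeatureSeries, b: FeatureSeries) -> tuple[np.ndarray, np.ndarray]:
    """Overlay two tracks on the union of their clocks and return paired values."""
    start = min(a.t0, b.t0)
    stop = max(a.t0 + len(a), b.t0 + len(b))
    return a.slice_seconds(start, stop), b.slice_seconds(start, stop)
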