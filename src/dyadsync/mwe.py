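"""Minimum-width envelopes: simultaneous confidence bands for curve sets.

A naive pointwise percentile band controls the error rate per time point
only; over an m-sample curve the family-wise chance that a curve exits the
band somewhere is far above alpha.  The minimum-width envelope (MWE)
controls the family-wise rate: starting from the pointwise min/max envelope
of a training set of curves, a greedy pass removes, k times, the curve whose
removal most shrinks the total envelope area; k is then tuned on a held-out
validation split so that a target fraction (default 95%) of validation
curves lies *entirely* inside the band.  A mean curve drawn from the same
distribution then stays fully inside the band with probability about
1 - alpha, whatever the autocorrelation of the curves.

Two hypothesis tests on per-participant difference curves are provided:

* bootstrap-centred: resample participant means, build the MWE around the
  observed difference, reject if zero exits the band at any time point;
* permutation-centred: flip condition labels within participants to build a
  zero-centred null MWE, reject if the observed mean difference exits it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import InputError

DEFAULT_ALPHA = 0.05
MIN_CURVES_FOR_TEST = 40


def as_curve_matrix(curves) -> np.ndarray:
    c = np.asarray(curves, dtype=float)
    if c.ndim != 2:
        raise InputError("curve set must be 2-D (n_curves x n_samples)")
    if not np.all(np.isfinite(c)):
        raise InputError("curves must be finite")
    return c


@dataclass
class EnvelopeBand:
    """Simultaneous band with its tuning parameter and naive comparison band."""

    lower: np.ndarray
    upper: np.ndarray
    k: int
    alpha: float = DEFAULT_ALPHA
    centering: Literal["bootstrap", "permutation", "raw"] = "raw"
    naive_lower: np.ndarray | None = None
    naive_upper: np.ndarray | None = None
    under_coverage: bool = False

    @property
    def area(self) -> float:
        return float(np.sum(self.upper - self.lower))

    def contains(self, curves: np.ndarray) -> np.ndarray:
        """Per curve: does the whole curve lie within [lower, upper]?"""
        c = np.atleast_2d(np.asarray(curves, dtype=float))
        return np.all((c >= self.lower) & (c <= self.upper), axis=1)

    def zero_outside(self) -> np.ndarray:
        """Time mask where zero lies outside the band."""
        return (self.lower > 0) | (self.upper < 0)


def naive_pointwise_band(curves, alpha: float = DEFAULT_ALPHA
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-point (alpha/2, 1-alpha/2) empirical percentile band."""
    c = as_curve_matrix(curves)
    if c.shape[0] < 20:
        raise InputError("need >= 20 curves for a percentile band")
    lo = np.percentile(c, 100 * alpha / 2, axis=0)
    hi = np.percentile(c, 100 * (1 - alpha / 2), axis=0)
    return lo, hi


# ---------------------------------------------------------------------------
# greedy envelope

def _greedy_removal_iter(curves: np.ndarray):
    """Yield indices removed by the area-greedy rule, one per step.

    At each step the curve whose removal most reduces the total envelope
    area (sum over time of upper - lower) is removed; ties break to the
    lowest curve index.  Duplicated extreme values yield zero reduction for
    any single copy, which the top-two bookkeeping handles naturally.
    Lazy, so callers that stop after a few removals pay only for those.
    """
    n, _ = curves.shape
    active = np.ones(n, dtype=bool)
    for _ in range(n - 1):
        idx = np.flatnonzero(active)
        sub = curves[idx]
        m = sub.shape[0]
        if m <= 1:
            return
        part = np.partition(sub, (0, 1, m - 2, m - 1), axis=0)
        bot1, bot2 = part[0], part[1]
        top2, top1 = part[m - 2], part[m - 1]
        red = (np.where(sub == top1, top1 - top2, 0.0)
               + np.where(sub == bot1, bot2 - bot1, 0.0)).sum(axis=1)
        best = int(np.argmax(red))          # first max = lowest index tie-break
        yield int(idx[best])
        active[idx[best]] = False


def _greedy_removal_order(curves: np.ndarray, k_max: int) -> list[int]:
    """First ``k_max`` greedy removals (see :func:`_greedy_removal_iter`)."""
    out: list[int] = []
    for i in _greedy_removal_iter(curves):
        if len(out) >= k_max:
            break
        out.append(i)
    return out


def greedy_mwe(training, k: int, alpha: float = DEFAULT_ALPHA) -> EnvelopeBand:
    """Envelope of the training curves after k greedy removals.

    k = 0 is the pointwise min/max of all training curves (every training
    curve fully inside); band bounds are the min/max of the surviving
    curves, with no interpolation or inflation.
    """
    c = as_curve_matrix(training)
    n = c.shape[0]
    if not (0 <= k < n):
        raise InputError(f"k must satisfy 0 <= k < n_curves ({n}); got {k}")
    removed = _greedy_removal_order(c, k)
    keep = np.ones(n, dtype=bool)
    keep[removed] = False
    sub = c[keep]
    return EnvelopeBand(lower=sub.min(axis=0), upper=sub.max(axis=0),
                        k=k, alpha=alpha)


def tune_k(training, validation, target: float = 0.95,
           alpha: float = DEFAULT_ALPHA) -> tuple[int, EnvelopeBand]:
    """Largest k whose envelope still contains >= target of validation curves.

    Bands are nested in k (removing curves can only shrink a min/max
    envelope), so validation coverage is non-increasing and the search
    stops at the first k that under-covers.  If even k = 0 misses the
    target, k = 0 is returned with ``under_coverage=True`` and a warning.
    """
    tr = as_curve_matrix(training)
    va = as_curve_matrix(validation)
    if tr.shape[1] != va.shape[1]:
        raise InputError("training and validation grids differ")
    n = tr.shape[0]
    naive_lo, naive_hi = (naive_pointwise_band(tr, alpha)
                          if n >= 20 else (None, None))

    def band_at(removed: list[int]) -> EnvelopeBand:
        keep = np.ones(n, dtype=bool)
        keep[removed] = False
        sub = tr[keep]
        return EnvelopeBand(sub.min(axis=0), sub.max(axis=0), len(removed),
                            alpha, naive_lower=naive_lo, naive_upper=naive_hi)

    band = band_at([])
    if band.contains(va).mean() < target:
        warnings.warn("even the full (k=0) envelope under-covers the "
                      "validation set")
        band.under_coverage = True
        return 0, band
    removed: list[int] = []
    best: list[int] = []
    for idx in _greedy_removal_iter(tr):     # nested bands: stop at first miss
        removed.append(idx)
        if band_at(removed).contains(va).mean() >= target:
            best = list(removed)
        else:
            break
    return len(best), band_at(best)


# ---------------------------------------------------------------------------
# hypothesis tests on difference curves

def bootstrap_mean_curves(diff_curves, n_boot: int,
                          rng: np.random.Generator | int | None = None
                          ) -> np.ndarray:
    """Bootstrap distribution of the participant-mean difference curve."""
    c = as_curve_matrix(diff_curves)
    rng = np.random.default_rng(rng)
    n = c.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    return c[idx].mean(axis=1)


def mwe_difference_test(diff_curves, alpha: float = DEFAULT_ALPHA,
                        target: float | None = None,
                        rng: np.random.Generator | int | None = None,
                        ) -> tuple[bool, np.ndarray, EnvelopeBand]:
    """Bootstrap-centred MWE test on a set of bootstrap-mean difference curves.

    ``diff_curves`` is the bootstrap sample of mean difference curves (built
    with :func:`bootstrap_mean_curves`).  The sample is split at random into
    equal train/validation halves, k is tuned so the band contains
    >= 1 - alpha of the validation curves, and the difference is significant
    iff zero lies outside the band at any time point.  Returns
    (significant, per-time significance mask, band).
    """
    c = as_curve_matrix(diff_curves)
    if c.shape[0] < MIN_CURVES_FOR_TEST:
        raise InputError(f"need >= {MIN_CURVES_FOR_TEST} bootstrap curves; "
                         f"got {c.shape[0]} — raise the bootstrap count")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(c.shape[0])
    half = c.shape[0] // 2
    train, valid = c[perm[:half]], c[perm[half:2 * half]]
    _, band = tune_k(train, valid, target=target if target is not None
                     else 1 - alpha, alpha=alpha)
    band.centering = "bootstrap"
    mask = band.zero_outside()
    return bool(mask.any()), mask, band


def permutation_mwe_test(cond_a, cond_b, n_perm: int = 1000,
                         alpha: float = DEFAULT_ALPHA,
                         rng: np.random.Generator | int | None = None,
                         ) -> tuple[bool, EnvelopeBand]:
    """Permutation-centred MWE test on paired per-participant condition means.

    Under the null, the condition labels are exchangeable within a
    participant, so flipping the sign of each participant's difference curve
    generates null mean-difference curves; the MWE built on these is centred
    on zero, and the contrast is significant iff the observed mean
    difference exits the band at any time point.
    """
    a = as_curve_matrix(cond_a)
    b = as_curve_matrix(cond_b)
    if a.shape != b.shape:
        raise InputError("condition arrays must be paired (same shape)")
    if n_perm < 200:
        warnings.warn("n_perm < 200 limits the resolution of alpha")
    rng = np.random.default_rng(rng)
    d = a - b
    observed = d.mean(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.shape[0]))
    null_curves = (signs @ d) / d.shape[0]
    perm = rng.permutation(n_perm)
    half = n_perm // 2
    _, band = tune_k(null_curves[perm[:half]], null_curves[perm[half:2 * half]],
                     target=1 - alpha, alpha=alpha)
    band.centering = "permutation"
    outside = (observed < band.lower) | (observed > band.upper)
    return bool(outside.any()), band
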