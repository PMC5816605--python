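"""Calibration and recovery studies run on the synthetic generator.

These studies are the package's empirical self-checks: because the study's
recorded classroom data is external, correctness is demonstrated by
statistical calibration (null rejection rates, CI coverage) and parameter
recovery (injected coupling and event responses found by the pipeline) on
synthetic classrooms whose ground truth is known.  All randomness flows
from a single seed argument.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import ecg, mwe, spc
from .series import FeatureSeries
from .simulate import SimConfig, generate_classroom, generate_null_classroom

EPOCH_SAMPLES = 21


def _smooth_curves(rng: np.random.Generator, n: int, m: int = EPOCH_SAMPLES,
                   smooth_sigma: float = 2.0) -> np.ndarray:
    """Smooth Gaussian-process-like curves (autocorrelated, unit-ish scale)."""
    x = gaussian_filter1d(rng.standard_normal((n, m + 8)), sigma=smooth_sigma,
                          axis=1, mode="reflect")[:, 4:4 + m]
    return x / x.std()


def mwe_validation_containment(seed: int, n_participants: int = 20,
                               n_per_split: int = 500) -> dict:
    """Tuned-envelope containment of held-out bootstrap difference curves.

    Simulates per-participant smooth difference curves, bootstrap-resamples
    the participant mean, splits the bootstrap sample into equal train and
    validation halves, tunes k on the validation split, and reports the
    percentage of validation curves fully inside the band.
    """
    rng = np.random.default_rng(seed)
    diffs = _smooth_curves(rng, n_participants)
    boot = mwe.bootstrap_mean_curves(diffs, 2 * n_per_split, rng)
    perm = rng.permutation(2 * n_per_split)
    train, valid = boot[perm[:n_per_split]], boot[perm[n_per_split:]]
    k, band = mwe.tune_k(train, valid, target=0.95)
    contained = float(band.contains(valid).mean())
    return {"containment_pct": 100.0 * contained, "k": k,
            "n": n_per_split}


def mwe_null_rejection_rate(seed: int, n_replicates: int = 1000,
                            n_participants: int = 20,
                            n_boot: int = 1000) -> dict:
    """Family-wise Type-I rate of the bootstrap-centred MWE difference test.

    Each replicate draws two condition-mean curves per participant from the
    same distribution (no true effect), forms difference curves, bootstraps
    the participant mean, tunes the envelope, and rejects if zero exits the
    band at any time point.
    """
    root = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        rng = np.random.default_rng(root.integers(2 ** 31))
        a = _smooth_curves(rng, n_participants)
        b = _smooth_curves(rng, n_participants)
        boot = mwe.bootstrap_mean_curves(a - b, n_boot, rng)
        sig, _, _ = mwe.mwe_difference_test(boot, alpha=0.05, rng=rng)
        rejections += int(sig)
    return {"rejection_rate": rejections / n_replicates, "n": n_replicates}


def _sdnn_tracks(classroom, window_len: int = 60,
                 overlap: float = 1.0 / 3.0) -> dict[str, FeatureSeries]:
    T = classroom.config.session_len
    out = {}
    for pid, part in classroom.participants.items():
        _, sdnn = ecg.windowed_features(part.beats, window_len, overlap)
        out[pid] = ecg.upsample_to_seconds(sdnn, T)
    return out


def spc_null_ci_coverage(seed: int, n_replicates: int = 500,
                         n_boot: int = 2000,
                         config: SimConfig | None = None) -> dict:
    """Null-classroom coverage of the shuffled-pair bootstrap 95% CI.

    Generates classrooms with zero dyad-specific coupling, computes the
    dyad-mean SDNN60-track correlation and its room-restricted bootstrap
    CI, and reports the percentage of replicates whose dyad mean does not
    exceed the CI upper bound.
    """
    if config is None:
        config = SimConfig(n_rooms=4, dyads_per_room=7, session_len=1800,
                           channels=("ecg",))
    root = np.random.default_rng(seed)
    within = 0
    for _ in range(n_replicates):
        rep_seed = int(root.integers(2 ** 31))
        classroom = generate_null_classroom(
            dataclasses.replace(config, seed=rep_seed))
        tracks = _sdnn_tracks(classroom)
        res = spc.shuffled_pair_null(tracks, classroom.dyad_map, "SDNN60",
                                     n_boot=n_boot, rng=rep_seed + 1)
        within += int(res.dyad_mean <= res.ci[1])
    return {"coverage_pct": 100.0 * within / n_replicates, "n": n_replicates}


def coupling_monotonicity(seed: int, couplings=(0.0, 0.3, 0.6),
                          n_seeds: int = 3,
                          config: SimConfig | None = None) -> dict:
    """Measured dyad-mean SDNN correlation across injected coupling levels."""
    if config is None:
        config = SimConfig(n_rooms=2, dyads_per_room=4, session_len=1200,
                           room_coupling=0.0, channels=("ecg",))
    root = np.random.default_rng(seed)
    seeds = [int(root.integers(2 ** 31)) for _ in range(n_seeds)]
    means = {}
    for c in couplings:
        vals = []
        for s in seeds:
            cfg = dataclasses.replace(config, dyad_coupling=c, seed=s)
            classroom = generate_classroom(cfg)
            m, _ = spc.dyad_mean_correlation(_sdnn_tracks(classroom),
                                             classroom.dyad_map)
            vals.append(m)
        means[c] = float(np.mean(vals))
    ordered = [means[c] for c in couplings]
    return {"means": means, "monotone": all(a < b for a, b in
                                            zip(ordered, ordered[1:]))}
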