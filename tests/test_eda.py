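"""EDA artifact repair, tonic/phasic decomposition, and normalisation."""

import numpy as np
import pytest

from dyadsync.eda import (EdaRaw, IrfParams, compound_error, correct_artifacts,
                          decompose_cda, driver_error_terms, estimate_irf,
                          to_second_tracks, zscore_session, _tonic_baseline)
from dyadsync.exceptions import InputError, QualityError
from dyadsync.series import FeatureSeries

FS = 51.2


def forward_simulate(impulses, duration_s, tonic=2.0, irf=None, noise=0.0,
                     seed=0):
    """Known driver (x) Bateman kernel + tonic: the decomposition oracle."""
    irf = irf or IrfParams()
    n = int(duration_s * FS)
    k = irf.kernel(FS)
    driver = np.zeros(n)
    for t, mass in impulses:
        driver[int(t * FS)] += mass * FS
    scr = np.convolve(driver, k)[:n] / FS
    rng = np.random.default_rng(seed)
    samples = tonic + scr + (rng.normal(0, noise, n) if noise else 0.0)
    return EdaRaw(samples, FS), scr, driver


class TestArtifactCorrection:
    def test_clean_signal_untouched(self):
        t = np.arange(0, 30, 1 / FS)
        raw = EdaRaw(2 + 0.5 * np.sin(2 * np.pi * 0.05 * t), FS)
        fixed, mask = correct_artifacts(raw)
        assert not mask.any()
        assert np.array_equal(fixed.samples, raw.samples)

    def test_spike_repaired(self):
        t = np.arange(0, 30, 1 / FS)
        clean = 2 + 0.5 * np.sin(2 * np.pi * 0.05 * t)
        spiked = clean.copy()
        spiked[700] += 20.0
        fixed, mask = correct_artifacts(EdaRaw(spiked, FS))
        assert mask[700]
        assert np.abs(fixed.samples - clean).max() < 0.05

    def test_majority_artifact_raises_quality_error(self):
        bad = np.full(int(10 * FS), 75.0)     # out of range
        bad[: int(4 * FS)] = 2.0
        with pytest.raises(QualityError):
            correct_artifacts(EdaRaw(bad, FS))

    def test_too_short_signal(self):
        with pytest.raises(InputError):
            correct_artifacts(EdaRaw(np.full(10, 2.0), FS))


class TestKernel:
    def test_unit_area_and_peak_time(self):
        irf = IrfParams(0.75, 2.0)
        k = irf.kernel(FS)
        assert k.sum() / FS == pytest.approx(1.0, abs=1e-6)
        assert np.argmax(k) / FS == pytest.approx(irf.peak_time_s, abs=2 / FS)

    def test_invalid_taus(self):
        with pytest.raises(InputError):
            IrfParams(2.0, 0.75)
        with pytest.raises(InputError):
            IrfParams(1.0, 1.0)


class TestDecomposition:
    def test_constant_input(self):
        dec = decompose_cda(EdaRaw(np.full(int(60 * FS), 2.0), FS))
        assert np.allclose(dec.scl, 2.0, atol=1e-6)
        assert np.abs(dec.driver).max() < 1e-6
        assert np.abs(dec.scr).max() < 1e-6

    def test_zero_signal_all_components_zero(self):
        dec = decompose_cda(EdaRaw(np.zeros(int(60 * FS)), FS))
        for comp in (dec.scl, dec.driver, dec.scr, dec.residual):
            assert np.abs(comp).max() < 1e-9

    def test_conservation_is_exact(self):
        raw, _, _ = forward_simulate([(10, 1.0), (40, 0.5)], 80, noise=0.02)
        dec = decompose_cda(raw)
        assert np.allclose(dec.reconstruct(), raw.samples, atol=1e-10)

    def test_impulse_round_trip(self):
        raw, scr_true, _ = forward_simulate([(10.0, 1.0)], 120)
        dec = decompose_cda(raw)
        i0, i1 = int(8 * FS), int(12 * FS)
        peak_t = (i0 + np.argmax(dec.driver[i0:i1])) / FS
        assert abs(peak_t - 10.0) <= 1.0
        rel = (np.sqrt(np.mean((dec.scr - scr_true) ** 2))
               / np.sqrt(np.mean(scr_true ** 2)))
        assert rel < 0.10
        assert dec.driver.min() >= 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_driver_mass_recovery_across_seeds(self, seed):
        r = np.random.default_rng(seed)
        impulses = [(t, a) for t, a in zip(r.uniform(5, 190, 25),
                                           r.exponential(0.7, 25))]
        raw, _, driver_true = forward_simulate(impulses, 200, noise=0.01,
                                               seed=seed)
        dec = decompose_cda(raw)
        assert dec.driver.sum() == pytest.approx(driver_true.sum(), rel=0.15)

    def test_tau_order_enforced(self):
        with pytest.raises(InputError):
            decompose_cda(EdaRaw(np.full(int(60 * FS), 2.0), FS),
                          IrfParams(2.0, 0.5))


class TestIrfEstimation:
    def test_parameter_recovery_within_20pct(self):
        r = np.random.default_rng(3)
        impulses = [(t, a) for t, a in zip(r.uniform(5, 290, 40),
                                           r.exponential(0.8, 40))]
        raw, _, _ = forward_simulate(impulses, 300, noise=0.01, seed=3)
        est = estimate_irf(raw)
        assert est.tau1 == pytest.approx(0.75, rel=0.20)
        assert est.tau2 == pytest.approx(2.0, rel=0.20)

    def test_true_kernel_beats_mismatched_kernel(self):
        r = np.random.default_rng(4)
        impulses = [(t, a) for t, a in zip(r.uniform(5, 190, 30),
                                           r.exponential(0.8, 30))]
        raw, _, _ = forward_simulate(impulses, 200, noise=0.01, seed=4)
        phasic = raw.samples - _tonic_baseline(raw.samples, FS)
        assert (compound_error(phasic, FS, 0.75, 2.0)
                < compound_error(phasic, FS, 0.2, 8.0))

    def test_all_zero_signal_returns_defaults(self):
        est = estimate_irf(EdaRaw(np.zeros(int(90 * FS)), FS))
        assert (est.tau1, est.tau2) == (0.75, 2.0)
        neg, ind = driver_error_terms(np.zeros(100))
        assert neg == 0.0 and ind == 0.0


class TestSecondTracks:
    def test_constant_passthrough(self):
        dec = decompose_cda(EdaRaw(np.full(int(10 * FS), 3.0), FS))
        scr, scl = to_second_tracks(dec)
        assert np.allclose(scl.values, 3.0, atol=1e-6)
        assert len(scl) == 10

    def test_block_mean_oracle(self):
        vals = np.arange(int(4 * FS), dtype=float)
        dec = decompose_cda(EdaRaw(np.full(vals.size, 1.0), FS))
        dec.scr = vals                      # inject known samples
        scr, _ = to_second_tracks(dec)
        sec = np.floor(np.arange(vals.size) / FS).astype(int)
        for s in range(4):
            assert scr.values[s] == pytest.approx(vals[sec == s].mean())

    def test_length_is_ceil_duration(self):
        dec = decompose_cda(EdaRaw(np.full(int(7.5 * FS), 1.0), FS))
        _, scl = to_second_tracks(dec)
        assert len(scl) == 8


class TestZscore:
    def test_three_point_example(self):
        z = zscore_session(FeatureSeries("SCR", [1.0, 2.0, 3.0]))
        assert np.allclose(z.values, [-1.0, 0.0, 1.0])

    def test_normalisation_contract(self, rng):
        z = zscore_session(FeatureSeries("SCR", rng.normal(5, 2, 500)))
        assert z.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.values.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(3, 1, 300)
        z1 = zscore_session(FeatureSeries("SCR", x))
        z2 = zscore_session(FeatureSeries("SCR", 4.2 * x + 1.7))
        assert np.allclose(z1.values, z2.values, atol=1e-10)

    def test_constant_track_degenerate(self):
        z = zscore_session(FeatureSeries("SCL", np.full(50, 2.0)))
        assert np.allclose(z.values, 0.0)
        assert z.degenerate
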