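"""SPC index, room-restricted bootstrap null, Holm correction, filtering."""

import numpy as np
import pytest
from scipy import stats

from dyadsync.ecg import WindowedFeature
from dyadsync.events import SessionLog
from dyadsync.exceptions import InputError
from dyadsync.series import FeatureSeries
from dyadsync.spc import (DyadMap, Room, dyad_mean_correlation,
                          filter_forced_behaviour, holm_bonferroni,
                          shuffled_pair_null)


def tracks_with_correlation(rng, r, n=200):
    """Two tracks whose sample Pearson correlation is exactly r."""
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x          # orthogonalise
    z /= z.std()
    y = r * x + np.sqrt(1 - r ** 2) * z
    return FeatureSeries("F", x), FeatureSeries("F", y)


class TestDyadMeanCorrelation:
    def test_identical_tracks_give_one(self, rng):
        x = FeatureSeries("F", rng.standard_normal(100))
        tracks = {"a": x, "b": x, "c": x, "d": x}
        dmap = DyadMap([Room("r1", [("a", "b"), ("c", "d")])])
        mean, per = dyad_mean_correlation(tracks, dmap)
        assert mean == pytest.approx(1.0)

    def test_arithmetic_mean_of_dyad_correlations(self, rng):
        a, b = tracks_with_correlation(rng, 0.5)
        c, d = tracks_with_correlation(rng, -0.1)
        dmap = DyadMap([Room("r1", [("a", "b"), ("c", "d")])])
        mean, _ = dyad_mean_correlation({"a": a, "b": b, "c": c, "d": d}, dmap)
        assert mean == pytest.approx(0.2, abs=1e-9)

    def test_independent_tracks_mean_near_zero(self, rng):
        n_dyads, n_sec = 20, 500
        tracks, dyads = {}, []
        for i in range(n_dyads):
            a, b = f"a{i}", f"b{i}"
            tracks[a] = FeatureSeries("F", rng.standard_normal(n_sec))
            tracks[b] = FeatureSeries("F", rng.standard_normal(n_sec))
            dyads.append((a, b))
        mean, _ = dyad_mean_correlation(tracks, DyadMap([Room("r1", dyads)]))
        assert abs(mean) < 3 / np.sqrt(n_dyads * n_sec) * 10

    def test_degenerate_dyad_excluded_with_warning(self, rng):
        a, b = tracks_with_correlation(rng, 0.4)
        const = FeatureSeries("F", np.full(200, 1.0))
        dmap = DyadMap([Room("r1", [("a", "b"), ("c", "d")])])
        with pytest.warns(UserWarning, match="degenerate"):
            mean, per = dyad_mean_correlation(
                {"a": a, "b": b, "c": const, "d": const}, dmap)
        assert len(per) == 1
        with pytest.raises(InputError):
            dyad_mean_correlation({"a": const, "b": const,
                                   "c": const, "d": const}, dmap)

    def test_disjointness_enforced(self):
        with pytest.raises(InputError):
            DyadMap([Room("r1", [("a", "b"), ("b", "c")])])


class TestShuffledPairNull:
    def test_degenerate_room_all_identical(self, rng):
        x = FeatureSeries("F", rng.standard_normal(100))
        tracks = {p: x for p in "abcd"}
        dmap = DyadMap([Room("r1", [("a", "b"), ("c", "d")])])
        res = shuffled_pair_null(tracks, dmap, n_boot=200, rng=0)
        assert np.allclose(res.null_samples, 1.0)
        assert res.dyad_mean == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_no_null_pair_spans_rooms(self, rng):
        # room A tracks all equal one pattern, room B another: any cross-room
        # pair would correlate ~0, so every null sample must equal 1 exactly
        xa = FeatureSeries("F", rng.standard_normal(200))
        xb = FeatureSeries("F", rng.standard_normal(200))
        tracks = {"a1": xa, "a2": xa, "a3": xa, "a4": xa,
                  "b1": xb, "b2": xb, "b3": xb, "b4": xb}
        dmap = DyadMap([Room("A", [("a1", "a2"), ("a3", "a4")]),
                        Room("B", [("b1", "b2"), ("b3", "b4")])])
        res = shuffled_pair_null(tracks, dmap, n_boot=500, rng=1)
        assert np.allclose(res.null_samples, 1.0)

    def test_p_value_smoothing_bound(self, rng):
        tracks, dyads = {}, []
        for i in range(4):
            a, b = tracks_with_correlation(rng, 0.9)
            tracks[f"a{i}"], tracks[f"b{i}"] = a, b
            dyads.append((f"a{i}", f"b{i}"))
        res = shuffled_pair_null(tracks, DyadMap([Room("r", dyads)]),
                                 n_boot=300, rng=2)
        assert res.p_raw >= 1 / (1 + 300)
        assert res.ci[0] <= res.ci[1]
        assert -1 <= res.dyad_mean <= 1

    def test_null_p_values_uniform(self):
        """Exchangeable dyad assignment => p ~ U(0,1) (KS check)."""
        ps = []
        for rep in range(200):
            r = np.random.default_rng(rep)
            tracks = {f"p{i}": FeatureSeries("F", r.standard_normal(120))
                      for i in range(8)}
            dmap = DyadMap([Room("r1", [("p0", "p1"), ("p2", "p3"),
                                        ("p4", "p5"), ("p6", "p7")])])
            res = shuffled_pair_null(tracks, dmap, n_boot=199, rng=r)
            ps.append(res.p_raw)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3


class TestHolm:
    def test_textbook_step_down(self):
        assert holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03]) == pytest.approx([0.03])

    def test_capping_monotonicity_and_dominance(self, rng):
        p = list(rng.uniform(0.001, 1.0, 10))
        adj = holm_bonferroni(p)
        assert all(0 < a <= 1 for a in adj)
        order = np.argsort(p)
        assert np.all(np.diff(np.array(adj)[order]) >= -1e-12)
        bonf = np.minimum(np.array(p) * len(p), 1.0)
        assert np.all(np.array(adj) <= bonf + 1e-12)
        assert np.all(np.array(adj) >= np.array(p) - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            holm_bonferroni([0.0, 0.5])
        with pytest.raises(InputError):
            holm_bonferroni([1.5])


class TestForcedBehaviourFilter:
    def make_windows(self, starts, wlen=60):
        return WindowedFeature("SDNN60", np.array(starts, float),
                               np.arange(len(starts), dtype=float), wlen)

    def test_interval_containment_rule(self):
        log = SessionLog([], {}, task_changes=[50.0])
        w, retained = filter_forced_behaviour(
            self.make_windows([0, 40, 80]), log)
        assert list(w.starts) == [80.0]
        assert retained == pytest.approx(1 / 3)

    def test_no_events_is_identity(self):
        log = SessionLog([], {}, task_changes=[])
        w, retained = filter_forced_behaviour(self.make_windows([0, 40, 80]), log)
        assert retained == 1.0
        assert list(w.starts) == [0.0, 40.0, 80.0]

    def test_low_retention_warns(self):
        log = SessionLog([], {}, task_changes=list(np.arange(10.0, 400.0, 25.0)))
        with pytest.warns(UserWarning, match="retained"):
            _, retained = filter_forced_behaviour(
                self.make_windows(list(range(0, 300, 20)), wlen=300), log)
        assert retained < 0.2
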