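"""Subset scoring, optimal-subset selection and tracking margins."""

import numpy as np
import pytest

import fidmargin as fm
from conftest import make_trace
from oracles import brute_force_subset


class TestSubsetMeanTrace:
    def test_singleton_returns_member_trace(self):
        t = make_trace("m1", [0, 1, 2])
        mean = fm.subset_mean_trace([t], ["m1"])
        np.testing.assert_array_equal(mean.displacement_mm, t.displacement_mm)

    def test_two_member_arithmetic_mean(self):
        a = make_trace("a", [0, 1, 2])
        b = make_trace("b", [0, 3, 6])
        mean = fm.subset_mean_trace([a, b], ["a", "b"])
        np.testing.assert_array_equal(mean.displacement_mm[:, 2], [0, 2, 4])

    def test_mean_of_identical_traces_is_idempotent(self):
        traces = [make_trace(f"m{i}", [0, 2, 5, 2]) for i in range(4)]
        mean = fm.subset_mean_trace(traces, [t.object_id for t in traces])
        np.testing.assert_array_equal(mean.displacement_mm,
                                      traces[0].displacement_mm)

    def test_unknown_id_and_empty_subset_rejected(self):
        t = make_trace("m1", [0, 1])
        with pytest.raises(KeyError):
            fm.subset_mean_trace([t], ["nope"])
        with pytest.raises(ValueError):
            fm.subset_mean_trace([t], [])


class TestFScore:
    def test_identical_traces_score_zero(self):
        t = make_trace("t", [0, 2, 4, 2, 0])
        sc = fm.f_score(t, make_trace("s", [0, 2, 4, 2, 0]))
        assert sc.f_value == 0.0
        np.testing.assert_array_equal(sc.per_axis_max_abs_diff, 0.0)

    def test_hand_computed_rms_example(self):
        # I-S differences (0,1,2,1,0), 5 phases, 3 axes pooled:
        # f = sqrt((0+1+4+1+0)/15) = 0.6325 mm
        u_t = make_trace("t", [0, 2, 4, 2, 0])
        u_s = make_trace("s", [0, 1, 2, 1, 0])
        sc = fm.f_score(u_t, u_s)
        assert sc.f_value == pytest.approx(np.sqrt(6.0 / 15.0), abs=1e-9)
        np.testing.assert_array_equal(sc.per_axis_max_abs_diff, [0, 0, 2.0])

    def test_invariant_under_common_constant_offset(self):
        rng = np.random.default_rng(0)
        u_t = fm.MotionTrace("t", rng.normal(size=(6, 3)))
        u_s = fm.MotionTrace("s", rng.normal(size=(6, 3)))
        base = fm.f_score(u_t, u_s)
        shift = np.array([3.0, -1.0, 7.0])
        shifted = fm.f_score(
            fm.MotionTrace("t", u_t.displacement_mm + shift),
            fm.MotionTrace("s", u_s.displacement_mm + shift))
        assert shifted.f_value == pytest.approx(base.f_value, abs=1e-12)

    def test_phase_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fm.f_score(make_trace("t", [0, 1]), make_trace("s", [0, 1, 2]))


class TestSelectOptimalSubset:
    def test_exact_match_singleton_wins(self):
        m1 = make_trace("1", [0, 2, 4, 2])
        m2 = make_trace("2", [0, 5, 9, 5])
        u_t = make_trace("gtv", [0, 2, 4, 2])
        res = fm.select_optimal_subset(u_t, [m1, m2])
        assert res.optimal_subset == ("1",)
        assert res.f_optimal == 0.0
        np.testing.assert_array_equal(res.itv_tracking_margin_mm, 0.0)

    def test_pair_mean_beats_singletons(self):
        a = make_trace("A", [0, 1, 2, 1, 0])
        b = make_trace("B", [0, 3, 6, 3, 0])
        u_t = make_trace("gtv", [0, 2, 4, 2, 0])
        res = fm.select_optimal_subset(u_t, [a, b])
        assert res.optimal_subset == ("A", "B")
        assert res.f_optimal == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.itv_tracking_margin_mm, 0.0,
                                   atol=1e-12)
        singles = [s for s in res.all_scores if len(s.subset) == 1]
        assert all(s.f_value > 0 for s in singles)

    def test_optimum_never_worse_than_best_singleton(self):
        rng = np.random.default_rng(7)
        traces = [fm.MotionTrace(str(i), rng.normal(size=(8, 3)))
                  for i in range(5)]
        u_t = fm.MotionTrace("gtv", rng.normal(size=(8, 3)))
        res = fm.select_optimal_subset(u_t, traces)
        best_single = min(
            fm.f_score(u_t, t).f_value for t in traces)
        assert res.f_optimal <= best_single + 1e-12

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(123)
        for trial in range(100):
            n_f = int(rng.integers(2, 7))
            n_phases = int(rng.integers(4, 9))
            traces = {str(i): rng.normal(size=(n_phases, 3)) * 3
                      for i in range(n_f)}
            # some trials: plant an exact subset mean so f=0 ties exist
            if trial % 3 == 0:
                subset = rng.choice(n_f, size=2, replace=False)
                u_t = np.mean([traces[str(i)] for i in subset], axis=0)
            else:
                u_t = rng.normal(size=(n_phases, 3)) * 3
            res = fm.select_optimal_subset(
                fm.MotionTrace("gtv", u_t),
                [fm.MotionTrace(k, v) for k, v in traces.items()])
            oracle = brute_force_subset(u_t, traces)
            assert tuple(sorted(res.optimal_subset)) == tuple(
                sorted(oracle["subset"]))
            assert res.f_optimal == pytest.approx(oracle["f"], abs=1e-12)
            np.testing.assert_allclose(res.itv_tracking_margin_mm,
                                       oracle["margin"], atol=1e-12)

    def test_margin_invariant_under_global_rigid_shift(self):
        rng = np.random.default_rng(2)
        traces = [fm.MotionTrace(str(i), rng.normal(size=(6, 3)))
                  for i in range(4)]
        u_t = fm.MotionTrace("gtv", rng.normal(size=(6, 3)))
        base = fm.select_optimal_subset(u_t, traces)
        shift = np.array([1.0, -2.0, 0.5])
        shifted = fm.select_optimal_subset(
            fm.MotionTrace("gtv", u_t.displacement_mm + shift),
            [fm.MotionTrace(t.object_id, t.displacement_mm + shift)
             for t in traces])
        assert shifted.optimal_subset == base.optimal_subset
        np.testing.assert_allclose(shifted.itv_tracking_margin_mm,
                                   base.itv_tracking_margin_mm, atol=1e-12)

    def test_planted_subset_recovered_as_noise_vanishes(self):
        rng = np.random.default_rng(42)
        n_f, n_phases = 5, 10
        traces = {str(i): rng.normal(size=(n_phases, 3)) * 4
                  for i in range(n_f)}
        planted = ("1", "3")
        mean = np.mean([traces[i] for i in planted], axis=0)
        margins = []
        for sigma in (0.5, 0.05, 0.005):
            u_t = mean + rng.normal(scale=sigma, size=(n_phases, 3))
            res = fm.select_optimal_subset(
                fm.MotionTrace("gtv", u_t),
                [fm.MotionTrace(k, v) for k, v in traces.items()])
            margins.append(res.itv_tracking_margin_mm.max())
            if sigma <= 0.05:
                assert res.optimal_subset == planted
        assert margins[2] < margins[0]
        assert margins[2] < 0.02

    def test_distance_tiebreak_prefers_closer_marker(self):
        # two markers with identical traces: f ties at every subset size
        t1 = make_trace("1", [0, 1, 2])
        t2 = make_trace("2", [0, 1, 2])
        u_t = make_trace("gtv", [0, 1, 2])
        res = fm.select_optimal_subset(
            u_t, [t1, t2],
            marker_positions_mm={"1": (0, 0, 80), "2": (0, 0, 10)},
            gtv_position_mm=(0, 0, 0))
        assert res.optimal_subset == ("2",)
        assert res.gtv_to_marker_distance_mm == {"2": 10.0}

    def test_enumeration_cap_and_empty_candidates(self):
        traces = [make_trace(str(i), [0, 1]) for i in range(13)]
        u_t = make_trace("gtv", [0, 1])
        with pytest.raises(ValueError, match="cap"):
            fm.select_optimal_subset(u_t, traces)
        with pytest.raises(ValueError):
            fm.select_optimal_subset(u_t, traces[:3], candidate_ids=[])
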