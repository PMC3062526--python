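"""CCS-level statistics: scission association, disappearance, scaling."""

import numpy as np
import pytest

from pph.ccs import (CCSRecord, assign_lifetime_classes, assign_size_classes,
                     ccs_statistics, classify_scission_detected,
                     correlate_ccs_measures, detect_disappearance,
                     negative_edge_kernel, normalize_by_cell, scaling_statistic,
                     size_statistic)
from pph.screening import ScissionEvent
from pph.synthetic import family_profile
from pph.tracking import Track


def make_track(tid, frames, row=20.0, col=20.0):
    t = Track(id=tid, frame_interval_s=4.0)
    for f in frames:
        t.frames.append(f)
        t.positions.append((row, col))
        t.areas.append(5)
        t.intensities.append(100.0)
    return t


def event(eid, frame, row, col):
    return ScissionEvent(id=eid, detection_frame=frame, position=(row, col),
                         track_id=eid)


class TestScissionDetected:
    def test_event_six_px_away_is_undetected(self):
        flags = classify_scission_detected([make_track(0, range(10))],
                                           [event(0, 5, 20.0, 26.1)])
        assert flags == {0: False}

    def test_event_within_five_px_detects(self):
        flags = classify_scission_detected([make_track(0, range(10))],
                                           [event(0, 5, 20.0, 25.0)])
        assert flags == {0: True}

    def test_track_must_be_alive_at_event_frame(self):
        flags = classify_scission_detected([make_track(0, range(10))],
                                           [event(0, 30, 20.0, 20.0)])
        assert flags == {0: False}

    def test_no_events_all_undetected(self):
        flags = classify_scission_detected([make_track(0, range(5))], [])
        assert flags == {0: False}


class TestCCSStatistics:
    def test_identical_groups_p_one_equal_medians(self):
        recs = ([CCSRecord(i, True, 1.0 + i, 40.0 + i) for i in range(5)]
                + [CCSRecord(10 + i, False, 1.0 + i, 40.0 + i)
                   for i in range(5)])
        out = ccs_statistics(recs)
        assert out["lifetime_s"]["median_detected"] == \
            out["lifetime_s"]["median_undetected"]
        assert out["lifetime_s"]["p_value"] == pytest.approx(1.0)

    def test_lognormal_median_offset_recovered_and_significant(self):
        rng = np.random.default_rng(12)
        det = rng.lognormal(np.log(189.0), 0.8, 200)
        und = rng.lognormal(np.log(38.0), 0.8, 200)
        recs = ([CCSRecord(i, True, 1.0, lt) for i, lt in enumerate(det)]
                + [CCSRecord(500 + i, False, 1.0, lt)
                   for i, lt in enumerate(und)])
        out = ccs_statistics(recs)["lifetime_s"]
        ratio = out["median_detected"] / out["median_undetected"]
        assert ratio == pytest.approx(189.0 / 38.0, rel=0.2)
        assert out["p_value"] < 0.05

    def test_single_element_groups(self):
        recs = [CCSRecord(0, True, 1.0, 50.0), CCSRecord(1, False, 2.0, 60.0)]
        out = ccs_statistics(recs)
        assert out["lifetime_s"]["median_detected"] == 50.0
        assert out["lifetime_s"]["median_undetected"] == 60.0


class TestDisappearance:
    def padded(self, values):
        v = np.asarray(values, float)
        return np.concatenate([v, np.full(20, v[-1])])

    def test_constant_trace_rejected_by_screen(self):
        clc = self.padded(np.full(41, 100.0) +
                          np.sin(np.arange(41)))   # no net drop
        assert detect_disappearance(clc, np.zeros(len(clc))) is None

    def test_clean_step_down_found_at_step_frame(self):
        """Brute-force convolution oracle: t0 equals the argmax of an
        explicitly computed edge response."""
        rng = np.random.default_rng(13)
        n = 45
        clc = np.where(np.arange(n) < 25, 100.0, 0.0) + rng.normal(0, 1.0, n)
        clc = self.padded(clc)
        tfr5 = np.zeros(len(clc))
        out = detect_disappearance(clc, tfr5)
        assert out is not None
        kernel = negative_edge_kernel(36.0, 4.0, 41)
        resp = []
        half = 20
        pad = np.concatenate([np.full(half, clc[0]), clc,
                              np.full(half, clc[-1])])
        for i in range(len(clc)):
            resp.append(np.dot(kernel, pad[i:i + 41]))
        assert out.t0_frame == int(np.argmax(resp))
        assert abs(out.t0_frame - 25) <= 1
        assert not out.has_scission

    def test_tfr5_step_of_24_units_is_below_threshold(self):
        clc = self.padded(np.where(np.arange(45) < 25, 100.0, 0.0)
                          + np.random.default_rng(0).normal(0, 1, 45))
        tfr5 = np.zeros(len(clc))
        tfr5[30:] = 24.0
        out = detect_disappearance(clc, tfr5)
        assert out is not None and not out.has_scission
        tfr5[30:] = 26.0
        out = detect_disappearance(clc, tfr5)
        assert out.has_scission
        assert out.dt_scission_s == (30 - out.t0_frame) * 4.0

    def test_short_trace_returns_none(self):
        assert detect_disappearance(np.zeros(10), np.zeros(10)) is None


class TestClasses:
    def test_three_distinct_values_one_per_tertile(self):
        classes = assign_size_classes(np.array([1.0, 2.0, 3.0]))
        assert sorted(classes) == [1, 2, 3]

    def test_tertile_boundary_goes_to_lower_class(self):
        sizes = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        classes = assign_size_classes(sizes)
        lo, hi = np.percentile(sizes, [100 / 3, 200 / 3])
        assert all(c == 1 for s, c in zip(sizes, classes) if s <= lo)

    def test_lifetime_cuts_120_480(self):
        lts = np.array([50.0, 120.0, 121.0, 480.0, 481.0])
        assert list(assign_lifetime_classes(lts)) == [1, 1, 2, 2, 3]

    def test_per_cell_normalization(self):
        vals = np.array([1.0, 3.0, 10.0, 30.0])
        cells = np.array([0, 0, 1, 1])
        out = normalize_by_cell(vals, cells)
        assert np.allclose(out, [0.5, 1.5, 0.5, 1.5])

    def test_size_window_is_minus18_to_minus10_s(self):
        f = np.zeros(41)
        f[16:19] = 30.0   # pH 7.4 samples at -18, -14, -10 s
        assert size_statistic(f) == pytest.approx(30.0)
        f2 = np.zeros(41)
        f2[19] = 99.0     # -6 s: outside the window
        assert size_statistic(f2) == 0.0

    def test_amplitude_proportional_classes_recovered(self):
        rng = np.random.default_rng(14)
        true_class = np.repeat([1, 2, 3], 60)
        sizes = true_class * 10.0 + rng.normal(0, 1.0, 180)
        got = assign_size_classes(sizes)
        assert np.mean(got == true_class) >= 0.9


class TestScalingStatistic:
    def traces_for(self, classes, scale_per_class=0.0, seed=15):
        rng = np.random.default_rng(seed)
        t = np.linspace(-82, 76, 80)
        base = np.exp(-(t + 3) ** 2 / 40.0)
        return np.stack([
            (1.0 + scale_per_class * c) * base + rng.normal(0, 0.05, 80)
            for c in classes])

    def test_identical_traces_give_zero_statistic(self):
        classes = np.repeat([1, 2, 3], 10)
        traces = np.tile(np.linspace(0, 1, 80), (30, 1))
        out = scaling_statistic(traces, classes, n_boot=200,
                                rng=np.random.default_rng(0))
        assert out["stat"] == pytest.approx(0.0, abs=1e-12)

    def test_random_assignment_falls_inside_null_ci(self):
        rng = np.random.default_rng(16)
        classes = rng.permutation(np.repeat([1, 2, 3], 20))
        traces = self.traces_for(np.zeros(60, int), 0.0)
        out = scaling_statistic(traces, classes, n_boot=500,
                                rng=np.random.default_rng(1))
        assert out["ci95"][0] <= out["stat"] <= out["ci95"][1]
        assert not out["significant"]

    def test_amplitude_proportional_scaling_is_significant(self):
        classes = np.repeat([1, 2, 3], 20)
        traces = self.traces_for(classes, scale_per_class=0.5)
        out = scaling_statistic(traces, classes, n_boot=500,
                                rng=np.random.default_rng(2))
        assert out["significant"]

    def test_small_bootstrap_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            scaling_statistic(np.zeros((6, 80)), np.repeat([1, 2, 3], 2),
                              n_boot=10, rng=np.random.default_rng(0))


class TestCorrelations:
    def test_identical_vectors_rho_one(self):
        x = np.arange(20.0)
        out = correlate_ccs_measures(x, x, x)
        assert out["tfr7_vs_clc"]["rho"] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        x = np.arange(20.0)
        out = correlate_ccs_measures(x[::-1], x, x)
        assert out["tfr7_vs_clc"]["rho"] == pytest.approx(-1.0)

    def test_independent_size_and_quantized_cargo_uncorrelated(self):
        """CCS size varies; cargo per vesicle is quantized and
        independent — rank correlation vanishes at n=800."""
        rng = np.random.default_rng(17)
        size = rng.lognormal(0, 0.8, 800)
        clc = size * rng.lognormal(0, 0.1, 800)
        cargo = rng.normal(50.0, 5.0, 800)          # independent of size
        out = correlate_ccs_measures(clc, size, cargo)
        assert abs(out["tfr7_vs_tfr5"]["rho"]) < 0.1
        assert out["tfr7_vs_clc"]["rho"] > 0.9

    def test_small_n_flagged_unreliable(self):
        x = np.arange(5.0)
        assert not correlate_ccs_measures(x, x, x)["p_reliable"]
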