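"""Peak displacement/force, T_PF and condition summaries."""
import numpy as np
import pytest

from trapforge import Trace, event_metrics, peak_window, summarize_condition, \
    time_at_peak_force
from trapforge.detect import DetectedEvent
from trapforge.features import ecdf


def make_trace(x, rate=5000.0, k=0.04):
    return Trace(np.asarray(x, dtype=float), rate, k)


def bruteforce_peak(x, start, end, w=25):
    best, best_i = -np.inf, start
    for i in range(start, end - w + 1):
        m = x[i:i + w].mean()
        if m > best:
            best, best_i = m, i
    return best, best_i


class TestPeakWindow:
    def test_constant_event(self):
        x = np.zeros(2000)
        x[500:1500] = 30.0
        ev = DetectedEvent(500, 1500, 0.2)
        peak, start = peak_window(make_trace(x), ev)
        assert peak == 30.0
        assert start == 500

    def test_ramp_then_plateau(self):
        x = np.zeros(3000)
        x[1000:1500] = np.linspace(0, 40, 500, endpoint=False)
        x[1500:2500] = 40.0
        ev = DetectedEvent(1000, 2500, 0.3)
        peak, start = peak_window(make_trace(x), ev)
        assert peak == pytest.approx(40.0)
        assert start >= 1500

    def test_single_spike_averaged_down(self):
        # one 100 nm sample in a 20 nm plateau: peak = (24*20 + 100)/25
        x = np.full(2000, 0.0)
        x[500:1000] = 20.0
        x[700] = 100.0
        ev = DetectedEvent(500, 1000, 0.1)
        peak, _ = peak_window(make_trace(x), ev)
        assert peak == pytest.approx((24 * 20 + 100) / 25)

    def test_matches_bruteforce(self, rng):
        x = rng.normal(10, 5, 4000)
        ev = DetectedEvent(300, 3700, 0.68)
        trace = make_trace(x)
        peak, start = peak_window(trace, ev)
        b_peak, b_start = bruteforce_peak(x, 300, 3700)
        assert peak == pytest.approx(b_peak, abs=1e-10)
        assert start == b_start

    def test_short_event_flagged_uses_event_mean(self, rng, caplog):
        x = rng.normal(5, 1, 1000)
        ev = DetectedEvent(100, 110, 0.002)
        peak, start = peak_window(make_trace(x), ev)
        assert peak == pytest.approx(x[100:110].mean())
        assert start == 100

    def test_offset_shifts_peak_linearly(self, rng):
        x = rng.normal(10, 3, 3000)
        ev = DetectedEvent(500, 2500, 0.4)
        trace = make_trace(x)
        peak, _ = peak_window(trace, ev)
        peak2, _ = peak_window(make_trace(x + 7.5), ev)
        assert peak2 == pytest.approx(peak + 7.5, abs=1e-9)


class TestTimeAtPeakForce:
    def test_peak_at_start_gives_full_lifetime(self):
        ev = DetectedEvent(1000, 6000, 1.0)
        t = time_at_peak_force(make_trace(np.zeros(7000)), ev, 1000)
        assert t == pytest.approx(1.0)

    def test_arithmetic(self):
        # 1 s event, peak window starts at 0.6 s -> T_PF 0.4 s, k_det 2.5/s
        ev = DetectedEvent(0, 5000, 1.0)
        t = time_at_peak_force(make_trace(np.zeros(5000)), ev, 3000)
        assert t == pytest.approx(0.4)
        assert 1.0 / t == pytest.approx(2.5)

    def test_monotone_event_peak_abuts_end(self):
        x = np.zeros(3000)
        x[1000:2000] = np.linspace(0, 40, 1000)
        ev = DetectedEvent(1000, 2000, 0.2)
        trace = make_trace(x)
        peak, start = peak_window(trace, ev)
        t = time_at_peak_force(trace, ev, start)
        assert t == pytest.approx(25 / 5000.0)  # exactly the window length

    def test_peak_outside_event_rejected(self):
        ev = DetectedEvent(100, 200, 0.02)
        with pytest.raises(ValueError):
            time_at_peak_force(make_trace(np.zeros(300)), ev, 250)


class TestSummaries:
    def make_metrics(self):
        x = np.zeros(30_000)
        events = []
        for i, (s, dur, level) in enumerate(
                [(2000, 1000, 20.0), (8000, 3000, 35.0), (15000, 2000, 28.0)]):
            x[s:s + dur] = level
            events.append(DetectedEvent(s, s + dur, dur / 5000.0))
        return event_metrics(make_trace(x, k=0.06), events)

    def test_peak_force_is_stiffness_times_displacement(self):
        m = self.make_metrics()
        np.testing.assert_allclose(m.peak_force, 0.06 * m.peak_displacement)

    def test_tpf_never_exceeds_lifetime(self):
        m = self.make_metrics()
        assert (m.t_pf <= m.t_on + 1e-12).all()

    def test_condition_rate_is_reciprocal_mean_dwell(self):
        import pandas as pd
        m = pd.DataFrame({"t_on": [0.5, 1.0], "peak_displacement": [20, 30],
                          "peak_force": [0.8, 1.2], "t_pf": [0.2, 0.6],
                          "k_det": [5.0, 1.6667], "k_trap": [0.04, 0.04],
                          "condition": ["c", "c"]})
        s = summarize_condition(m)
        assert s.k_det.iloc[0] == pytest.approx(2.5)  # 1/mean({0.2, 0.6})

    def test_single_event_group_flagged(self):
        import pandas as pd
        m = pd.DataFrame({"t_on": [0.5], "peak_displacement": [20.0],
                          "peak_force": [0.8], "t_pf": [0.2], "k_det": [5.0],
                          "k_trap": [0.04], "condition": ["c"]})
        s = summarize_condition(m)
        assert s.t_on_sem.iloc[0] == 0.0
        assert not s.sem_defined.iloc[0]

    def test_ecdf_reaches_one(self, rng):
        v, p = ecdf(rng.exponential(0.3, 100))
        assert p[-1] == 1.0
        assert np.all(np.diff(v) >= 0)
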