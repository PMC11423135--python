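"""Trace loading, onset detection and pre-fit conditioning."""

import numpy as np
import pandas as pd
import pytest

from leafactin.trace import (
    FluorescenceTrace,
    TraceError,
    detect_onset,
    log_subsample,
    moving_average,
    read_trace_csv,
    truncate_at_max,
    write_trace_csv,
)


def make_trace(t, y, **kw):
    return FluorescenceTrace(time_s=np.asarray(t, float),
                             signal=np.asarray(y, float), **kw)


def step_trace(n=2000, onset_frac=0.1, f0=100.0, fm=500.0, noise=0.0, seed=0):
    t = np.linspace(0, 1, n, endpoint=False)
    y = np.where(t < onset_frac, f0, fm).astype(float)
    if noise:
        y += np.random.default_rng(seed).normal(scale=noise, size=n)
    return make_trace(t, y)


class TestTraceContract:
    def test_rate_inferred_from_time_axis(self):
        tr = make_trace(np.arange(100) * 1e-6, np.zeros(100))
        assert tr.rate_hz == pytest.approx(1e6)

    def test_non_monotone_time_rejected(self):
        t = np.arange(100.0)
        t[50] = 10.0
        with pytest.raises(TraceError, match="increasing"):
            make_trace(t, np.zeros(100))

    def test_short_trace_rejected(self):
        with pytest.raises(TraceError, match="short"):
            make_trace(np.arange(10.0), np.zeros(10))

    def test_nonfinite_rejected(self):
        y = np.zeros(100)
        y[3] = np.nan
        with pytest.raises(TraceError, match="finite"):
            make_trace(np.arange(100.0), y)


class TestCsvIO:
    def test_round_trip(self, tmp_path):
        tr = step_trace(500)
        path = tmp_path / "t.csv"
        write_trace_csv(tr, path)
        back = read_trace_csv(path)
        np.testing.assert_array_equal(back.time_s, tr.time_s)
        np.testing.assert_array_equal(back.signal, tr.signal)

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame({"a": range(100), "b": range(100)}).to_csv(path, index=False)
        with pytest.raises(TraceError, match="time_s"):
            read_trace_csv(path)

    def test_nonfinite_rows_dropped(self, tmp_path):
        tr = step_trace(500)
        df = pd.DataFrame({"time_s": tr.time_s, "signal": tr.signal})
        df.loc[7, "signal"] = np.nan
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        assert len(read_trace_csv(path)) == 499

    def test_shuffled_time_rejected(self, tmp_path):
        rng = np.random.default_rng(0)
        path = tmp_path / "t.csv"
        pd.DataFrame({"time_s": rng.permutation(100).astype(float),
                      "signal": np.zeros(100)}).to_csv(path, index=False)
        with pytest.raises(TraceError, match="increasing"):
            read_trace_csv(path)

    def test_acquisition_rate_from_file(self, tmp_path):
        t = np.arange(3000) / 3e6
        path = tmp_path / "t.csv"
        pd.DataFrame({"time_s": t, "signal": np.ones_like(t)}).to_csv(path, index=False)
        assert read_trace_csv(path).rate_hz == pytest.approx(3e6, rel=1e-6)


class TestDetectOnset:
    def test_noiseless_step(self):
        tr = step_trace(2000, onset_frac=0.1, f0=100.0, fm=500.0)
        res = detect_onset(tr)
        assert res.onset_time_s == pytest.approx(0.1, abs=2e-3)
        assert res.F0_estimate == pytest.approx(500.0)

    def test_noisy_step_onset_within_two_samples(self):
        tr = step_trace(5000, onset_frac=0.1, f0=100.0, fm=500.0,
                        noise=4.0, seed=3)
        res = detect_onset(tr)
        true_idx = int(np.searchsorted(tr.time_s, 0.1))
        assert abs(res.onset_index - true_idx) <= 2

    def test_constant_signal_raises(self):
        tr = make_trace(np.arange(200.0), np.full(200, 7.0))
        with pytest.raises(TraceError, match="no rise"):
            detect_onset(tr)

    def test_already_risen_signal_flagged(self):
        t = np.arange(200) * 1e-3
        y = 100.0 + 400.0 * (1 - np.exp(-t / 5e-3))
        res = detect_onset(make_trace(t, y))
        assert res.no_baseline and res.onset_index == 0

    def test_affine_invariance(self):
        tr = step_trace(3000, noise=2.0, seed=1)
        res = detect_onset(tr)
        res2 = detect_onset(tr.with_data(tr.time_s, 3.5 * tr.signal + 40.0))
        assert res2.onset_index == res.onset_index


class TestMovingAverage:
    def test_constant_preserved(self):
        tr = make_trace(np.arange(500.0), np.full(500, 3.3))
        np.testing.assert_allclose(moving_average(tr, 50).signal, 3.3)

    def test_window_one_is_identity(self):
        tr = step_trace(500)
        np.testing.assert_array_equal(moving_average(tr, 1).signal, tr.signal)

    def test_noise_reduction_scaling(self, rng):
        n, w = 100_000, 25
        tr = make_trace(np.arange(n, dtype=float), rng.normal(size=n))
        sd = moving_average(tr, w).signal[w:-w].std()
        assert sd == pytest.approx(1 / np.sqrt(w), rel=0.2)

    def test_window_out_of_range(self):
        tr = step_trace(100)
        with pytest.raises(ValueError):
            moving_average(tr, 50)

    def test_preserves_length_and_range(self):
        tr = step_trace(1000, noise=5.0)
        out = moving_average(tr, 20)
        assert len(out) == len(tr)
        assert out.signal.min() >= tr.signal.min() - 1e-9
        assert out.signal.max() <= tr.signal.max() + 1e-9


class TestLogSubsample:
    def make_aligned(self, n=1_000_000, t_end=1.0):
        t = np.arange(1, n + 1) * (t_end / n)  # 1 us .. 1 s
        return make_trace(t, np.sin(t))

    def test_count_bound_six_decades(self):
        tr = self.make_aligned()
        out = log_subsample(tr, per_decade=200)
        assert len(out) <= 6 * 200 + 1

    def test_idempotent(self):
        tr = self.make_aligned(100_000)
        once = log_subsample(tr, 100)
        twice = log_subsample(once, 100)
        np.testing.assert_array_equal(once.time_s, twice.time_s)

    def test_short_trace_bounded_by_per_decade(self):
        t = 1.0 + np.arange(500) * 1e-3  # less than one decade
        out = log_subsample(make_trace(t, np.ones_like(t)), per_decade=50)
        assert len(out) <= 51

    def test_pre_onset_samples_kept(self):
        t = np.arange(-50, 1000, dtype=float) * 1e-3
        out = log_subsample(make_trace(t, np.ones_like(t)), 20)
        assert (out.time_s <= 0).sum() == 51

    def test_monotone_and_endpoints(self):
        tr = self.make_aligned(50_000)
        out = log_subsample(tr, 30)
        assert np.all(np.diff(out.time_s) > 0)
        assert out.time_s[0] == tr.time_s[0]
        assert out.time_s[-1] == tr.time_s[-1]

    def test_low_density_rejected(self):
        with pytest.raises(ValueError):
            log_subsample(self.make_aligned(1000), per_decade=5)


class TestTruncateAtMax:
    def test_monotone_rise_unchanged(self):
        t = np.linspace(0, 1, 1000)
        tr = make_trace(t, 1 - np.exp(-5 * t))
        assert len(truncate_at_max(tr)) == len(tr)

    def test_decay_removed(self):
        t = np.linspace(0, 1, 2000)
        y = np.where(t < 0.5, t, 0.5 - 0.2 * (t - 0.5))
        out = truncate_at_max(make_trace(t, y))
        assert out.time_s[-1] == pytest.approx(0.5, abs=1e-2)
        # the global maximum of the raw signal is retained
        assert len(out) - 1 >= np.argmax(y)
        assert np.all(np.diff(out.signal)[:-20] >= 0)

    def test_flat_trace_unchanged(self):
        tr = make_trace(np.arange(200.0), np.ones(200))
        assert len(truncate_at_max(tr)) == 200
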