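"""Parsing, filtering, saccade detection, desaccading, and trial QC."""

import logging

import numpy as np
import pytest

import aspursuit as asp
from aspursuit.errors import ConfigurationError, ParseError, UnusableTraceError
from aspursuit.preprocess import EyeTrace, QCReport, SaccadeInterval


def make_trace(n=1000, fs=1000.0, x=None, y=None, t0=-0.3):
    t = t0 + np.arange(n) / fs
    x = np.zeros(n) if x is None else x
    y = np.zeros(n) if y is None else y
    return EyeTrace(time=t, x=x, y=y, sample_rate=fs)


class TestParsing:
    @pytest.mark.parametrize("fmt", ["tsv", "asc"])
    def test_write_parse_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        trace = make_trace(x=rng.normal(size=1000), y=rng.normal(size=1000))
        path = tmp_path / f"trace.{fmt}"
        if fmt == "tsv":
            asp.write_trace_tsv(trace, path, header_meta={"seed": 3})
        else:
            asp.write_trace_asc(trace, path)
        back = asp.parse_samples(path, format=fmt)
        assert np.allclose(back.x, trace.x, atol=1e-8)
        assert np.allclose(back.y, trace.y, atol=1e-8)
        assert np.allclose(back.time, trace.time, atol=1e-9)

    def test_simulator_output_survives_round_trip(self, tmp_path):
        cond = asp.KinematicCondition("v11c", 11.0, 0.0, 0.5, 45.0)
        trace = asp.simulate_trial(cond, 3.0, asp.GenerativeParams(), seed=1)
        path = tmp_path / "sim.tsv"
        asp.write_trace_tsv(trace, path)
        back = asp.parse_samples(path, format="tsv")
        assert np.allclose(back.x, trace.x, atol=1e-8)

    def test_timestamp_gap_filled_with_missing(self, tmp_path, caplog):
        path = tmp_path / "gap.tsv"
        lines = ["time_s\tx_deg\ty_deg"]
        for i in list(range(60)) + list(range(70, 130)):  # 10-sample hole
            lines.append(f"{i / 1000.0:.6f}\t{0.1 * i:.6f}\t0.0")
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level(logging.WARNING):
            trace = asp.parse_samples(path, format="tsv")
        assert len(trace) == 130
        assert np.isnan(trace.x[60:70]).all()
        assert not np.isnan(trace.x[:60]).any()
        assert "missing samples" in caplog.text

    def test_non_monotone_timestamps_raise_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("0.000\t0\t0\n0.001\t0\t0\n0.001\t0\t0\n")
        with pytest.raises(ParseError, match="monoton"):
            asp.parse_samples(path, format="tsv")

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "trace.bin"
        path.write_text("")
        with pytest.raises(ConfigurationError, match="tsv"):
            asp.parse_samples(path, format="edf")


class TestFiltering:
    def test_constant_position_zero_velocity(self):
        trace = make_trace(x=np.full(1000, 3.7), y=np.full(1000, -1.2))
        out = asp.filter_and_differentiate(trace)
        assert np.allclose(out.vx, 0.0, atol=1e-9)
        assert np.allclose(out.vy, 0.0, atol=1e-9)

    def test_5hz_sinusoid_amplitude_matches_analytic_derivative(self):
        t = np.arange(2000) / 1000.0
        trace = make_trace(n=2000, x=np.sin(2 * np.pi * 5 * t), t0=0.0)
        out = asp.filter_and_differentiate(trace)
        measured = np.max(np.abs(out.vx[200:-200]))
        assert measured == pytest.approx(2 * np.pi * 5, rel=0.02)

    def test_60hz_sinusoid_strongly_attenuated(self):
        t = np.arange(2000) / 1000.0
        trace = make_trace(n=2000, x=np.sin(2 * np.pi * 60 * t), t0=0.0)
        out = asp.filter_and_differentiate(trace)
        measured = np.max(np.abs(out.vx[200:-200]))
        assert measured < 0.1 * 2 * np.pi * 60

    def test_zero_phase_no_lag_on_symmetric_pulse(self):
        n = 1001
        t = np.arange(n) / 1000.0
        x = np.exp(-((t - t[n // 2]) ** 2) / (2 * 0.02**2))
        out = asp.filter_and_differentiate(make_trace(n=n, x=x, t0=0.0))
        filt = out.x
        assert np.allclose(filt, filt[::-1], atol=1e-9)  # symmetric in == symmetric out
        assert np.argmax(filt) == n // 2

    def test_short_trace_flagged_unusable(self):
        with pytest.raises(UnusableTraceError):
            asp.filter_and_differentiate(make_trace(n=30))


class TestSaccadeDetection:
    def _pursuit_trace(self, n=1000, speed=10.0):
        t = -0.3 + np.arange(n) / 1000.0
        x = np.cumsum(np.full(n, speed / 1000.0))
        return asp.filter_and_differentiate(make_trace(n=n, x=x))

    def test_clean_pursuit_has_no_saccades(self):
        assert asp.detect_saccades(self._pursuit_trace()) == []

    def test_single_pulse_yields_single_interval(self):
        cond = asp.KinematicCondition("v11c", 11.0, 0.0, 0.5, 0.0)
        params = asp.GenerativeParams(saccade_rate=0.0, position_noise_sd=0.0)
        trace = asp.simulate_trial(cond, 3.0, params, seed=0, with_saccades=False, with_noise=False)
        # inject one 150 deg/s raised-cosine pulse at t = 0.2 s
        pulse = (trace.time >= 0.2) & (trace.time < 0.23)
        phase = (trace.time[pulse] - 0.2) / 0.03
        extra = np.cumsum(150 * 0.5 * (1 - np.cos(2 * np.pi * phase))) / 1000.0
        x = trace.x.copy()
        x[pulse] += extra
        x[trace.time >= 0.23] += extra[-1]
        out = asp.filter_and_differentiate(
            EyeTrace(time=trace.time, x=x, y=trace.y, sample_rate=1000.0)
        )
        intervals = asp.detect_saccades(out)
        assert len(intervals) == 1
        assert intervals[0].start <= 0.2 <= intervals[0].end
        assert intervals[0].peak_velocity > 30.0

    def test_all_missing_velocity_warns_empty(self, caplog):
        trace = self._pursuit_trace()
        trace.vx[:] = np.nan
        trace.vy[:] = np.nan
        with caplog.at_level(logging.WARNING):
            assert asp.detect_saccades(trace) == []

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            SaccadeInterval(start=0.2, end=0.1, peak_velocity=50, detection_rule="absolute")


class TestDesaccadeAndQC:
    def _velocity_trace(self, n=801, t0=-0.3):
        trace = make_trace(n=n, t0=t0)
        trace.vx = np.zeros(n)
        trace.vy = np.zeros(n)
        return trace

    def test_clean_trial_kept(self):
        trace = self._velocity_trace()
        _, report = asp.desaccade_and_qc(trace, [], "exp1a")
        assert not report.excluded
        assert report.onset_window_missing == 0.0

    def test_desaccading_blanks_only_inside_intervals(self):
        trace = self._velocity_trace()
        trace.vx = np.random.default_rng(0).normal(size=len(trace))
        iv = SaccadeInterval(start=0.1, end=0.15, peak_velocity=100, detection_rule="absolute")
        out, _ = asp.desaccade_and_qc(trace, [iv], "exp1a")
        inside = (trace.time >= 0.1) & (trace.time <= 0.15)
        assert np.isnan(out.vx[inside]).all()
        assert np.array_equal(out.vx[~inside], trace.vx[~inside])

    def test_onset_window_exclusion_is_strictly_more_than(self):
        # exp1a window [-100, 200] ms holds 301 samples; the 40% line is 120.4
        for n_missing, expect_excluded in [(117, False), (124, True)]:
            trace = self._velocity_trace()
            idx = np.flatnonzero((trace.time >= -0.1) & (trace.time <= 0.2))[:n_missing]
            trace.vx[idx] = np.nan
            _, report = asp.desaccade_and_qc(trace, [], "exp1a")
            assert report.excluded is expect_excluded
            if expect_excluded:
                assert "onset-window" in report.reason

    def test_overall_exclusion_rule(self):
        # exp1b: window cap 70% in [-100, 100] ms, overall cap 60%
        for frac, expect_excluded in [(0.59, False), (0.61, True)]:
            trace = self._velocity_trace()
            outside = np.flatnonzero((trace.time > 0.105) | (trace.time < -0.105))
            n_missing = int(round(frac * len(trace)))
            trace.vx[outside[:n_missing]] = np.nan
            _, report = asp.desaccade_and_qc(trace, [], "exp1b")
            assert report.excluded is expect_excluded, frac
            if expect_excluded:
                assert "overall" in report.reason

    def test_exclusion_monotone_in_missingness(self):
        order = np.random.default_rng(1).permutation(801)
        excluded_seen = False
        for k in range(0, 801, 80):
            trace = self._velocity_trace()
            trace.vx[order[:k]] = np.nan
            _, report = asp.desaccade_and_qc(trace, [], "exp1a")
            if excluded_seen:
                assert report.excluded  # adding missing never rescues a trial
            excluded_seen = excluded_seen or report.excluded
        assert excluded_seen

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError, match="profile"):
            asp.desaccade_and_qc(self._velocity_trace(), [], "exp7")

    def test_qc_report_invariants(self):
        with pytest.raises(ValueError):
            QCReport(onset_window_missing=0.5, overall_missing=0.2, excluded=True, reason="")
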