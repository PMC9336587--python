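import numpy as np
import pytest

from brainthermo import (
    GeneratorConfig,
    PatientSeriesParams,
    RhythmConfig,
    TemperatureSeries,
    classify_daily_rhythm,
    cosinor_fit,
    estimate_period,
    extract_daily_extrema,
    gen_patient_series,
    preprocess_series,
    summary_stats,
)
from brainthermo.rhythm import (
    DegenerateFitError,
    IneligibleWindowError,
    cosinor_scan_sse,
)


def _sinusoid(period=24.0, amp=1.0, mesor=38.5, phase=18.0, span=96.0, dt=0.25,
              noise=0.0, seed=0):
    t = np.arange(0.0, span + 1e-9, dt)
    y = mesor + amp * np.cos(2 * np.pi * (t - phase) / period)
    if noise > 0:
        y = y + np.random.default_rng(seed).normal(0, noise, t.size)
    return TemperatureSeries(times=t, values=y, preprocessed=True)


class TestPreprocess:
    def test_clean_series_only_initial_trim(self):
        s = _sinusoid(span=48.0)
        s.preprocessed = False
        out, window = preprocess_series(s)
        assert out.times[0] >= 2.0
        assert window.summary_eligible and window.rhythm_eligible
        assert "implausible_value" not in window.reasons

    def test_negative_artefact_beside_gap_removed(self):
        t = np.concatenate([np.arange(0, 24, 1 / 60), np.arange(24.5, 48, 1 / 60)])
        y = np.full(t.size, 38.0)
        n_first = np.sum(t < 24)
        y[n_first - 1] = -99.0  # impossible value at the gap edge
        s = TemperatureSeries(times=t, values=y)
        out, window = preprocess_series(s)
        assert np.all(out.values > 0)
        assert "implausible_value" in window.reasons

    def test_ttm_masking_blocks_rhythm_eligibility(self):
        t = np.arange(0.0, 30.0, 1 / 60)
        y = 38.0 + 0.3 * np.cos(2 * np.pi * t / 24)
        ttm = (t >= 10.0) & (t < 20.0)
        y[ttm] = 34.0
        s = TemperatureSeries(times=t, values=y, ttm_mask=ttm)
        out, window = preprocess_series(s)
        assert window.summary_eligible  # >=24 h raw span
        assert not window.rhythm_eligible  # <36 h continuous after masking

    def test_idempotent(self):
        cfg = GeneratorConfig(seed=5)
        s, _ = gen_patient_series(cfg, rhythmic=True)
        once, w1 = preprocess_series(s)
        twice, w2 = preprocess_series(once)
        assert np.array_equal(once.times, twice.times)
        assert np.array_equal(once.values, twice.values)
        assert (w1.start_time, w1.end_time) == (w2.start_time, w2.end_time)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            TemperatureSeries(times=np.array([]), values=np.array([]))


class TestCosinorFit:
    def test_noiseless_exact_recovery(self, clean_sinusoid):
        fit = cosinor_fit(clean_sinusoid, period=24.0)
        assert fit.mesor == pytest.approx(38.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(0.5, abs=1e-8)
        assert fit.acrophase == pytest.approx(18.0, abs=1e-6)
        assert fit.p_value < 1e-10

    def test_constant_series_not_significant(self):
        t = np.arange(0.0, 48.0, 0.5)
        rng = np.random.default_rng(3)
        s = TemperatureSeries(times=t, values=37.0 + rng.normal(0, 1e-6, t.size),
                              preprocessed=True)
        fit = cosinor_fit(s, period=24.0)
        assert fit.amplitude < 1e-5

    def test_noisy_amplitude_recovery(self):
        s = _sinusoid(amp=0.8, noise=0.2, span=72.0, dt=1 / 60, seed=11)
        fit = cosinor_fit(s, period=24.0)
        assert fit.amplitude == pytest.approx(0.8, abs=0.1)

    def test_linear_trend_alone_not_significant(self):
        """The null model is a straight line, so pure drift is no rhythm."""
        t = np.arange(0.0, 72.0, 0.25)
        rng = np.random.default_rng(4)
        y = 37.0 + 0.02 * t + rng.normal(0, 0.05, t.size)
        fit = cosinor_fit(TemperatureSeries(times=t, values=y, preprocessed=True))
        assert fit.p_value > 0.01

    def test_degenerate_design_raises(self):
        t = np.array([0.0, 24.0, 48.0])  # all at the same phase
        s = TemperatureSeries(times=t, values=np.array([38.0, 38.1, 37.9]),
                              preprocessed=True)
        with pytest.raises(DegenerateFitError):
            cosinor_fit(s, period=24.0)


class TestEstimatePeriod:
    @pytest.mark.parametrize("tau", [20.0, 24.0, 26.0, 30.0])
    def test_estimators_match_dense_grid_oracle(self, tau):
        """Cosinor scan and Lomb-Scargle find the planted period within one
        grid step of a dense brute-force SSE search."""
        s = _sinusoid(period=tau, span=96.0, dt=0.25)
        config = RhythmConfig()
        dense = np.arange(16.0, 32.0001, 0.02)
        oracle = dense[np.argmin(cosinor_scan_sse(s.times, s.values, dense))]
        assert oracle == pytest.approx(tau, abs=0.02)
        for method in ("cosinor_scan", "lomb_scargle"):
            period, p = estimate_period(s, method=method, config=config)
            assert abs(period - oracle) <= config.scan_step + 1e-9
            assert p < 0.05

    def test_harmonic_regression_reports_24(self):
        s = _sinusoid(period=24.0)
        period, p = estimate_period(s, method="harmonic_regression")
        assert period == 24.0 and p < 1e-10

    def test_short_series_range_error(self):
        s = _sinusoid(span=20.0)
        with pytest.raises(IneligibleWindowError):
            estimate_period(s, method="cosinor_scan")

    def test_white_noise_rarely_significant(self):
        rng_hits = 0
        n_rep = 50
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            t = np.arange(0.0, 96.0, 0.25)
            s = TemperatureSeries(times=t, values=38.0 + rng.normal(0, 0.3, t.size),
                                  preprocessed=True)
            _, p = estimate_period(s, method="cosinor_scan")
            rng_hits += p < 0.05
        # scan-corrected significance: ~alpha of white series at most
        assert rng_hits <= n_rep * 0.05 + 3 * np.sqrt(n_rep * 0.05 * 0.95)


class TestClassifier:
    def test_rhythmic_sinusoid_detected(self):
        cfg = GeneratorConfig(seed=21)
        s, truth = gen_patient_series(cfg, rhythmic=True)
        series, window = preprocess_series(s)
        call = classify_daily_rhythm(series, window)
        assert call.is_rhythmic is True
        assert call.criterion_partial and call.criterion_whole

    def test_partial_rhythm_satisfies_criterion_one(self):
        """Flat first segment followed by a 24 h sinusoid is still rhythmic:
        the in-part criterion needs only part of the series."""
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 84.0, 1 / 12)
        y = np.where(
            t < 36.0, 38.0,
            38.0 + 1.0 * np.cos(2 * np.pi * (t - 50.0) / 24.0),
        ) + rng.normal(0, 0.1, t.size)
        s = TemperatureSeries(times=t, values=y, preprocessed=True)
        series, window = preprocess_series(s)
        call = classify_daily_rhythm(series, window)
        assert call.criterion_partial
        assert call.is_rhythmic is True

    def test_30h_period_not_rhythmic(self):
        cfg = GeneratorConfig(seed=22, patient=PatientSeriesParams(period_h=30.0))
        for i in range(5):
            s, _ = gen_patient_series(cfg, rhythmic=True, index=i)
            series, window = preprocess_series(s)
            assert classify_daily_rhythm(series, window).is_rhythmic is False

    def test_short_series_not_classifiable(self):
        cfg = GeneratorConfig(seed=23, patient=PatientSeriesParams(length_h=30.0))
        s, _ = gen_patient_series(cfg, rhythmic=False)
        series, window = preprocess_series(s)
        call = classify_daily_rhythm(series, window)
        assert call.is_rhythmic is None  # distinct from "not rhythmic"


class TestExtremaAndSummaries:
    def test_planted_extrema_recovered(self):
        s = _sinusoid(span=48.0, dt=1 / 60, amp=1.0, phase=18.0, mesor=38.5)
        window_series, window = preprocess_series(
            TemperatureSeries(times=s.times, values=s.values, clock_anchor=8.0)
        )
        ext = extract_daily_extrema(window_series, window)
        assert len(ext) == 1  # 46 h window -> one full day block
        row = ext.iloc[0]
        assert row["max"] == pytest.approx(39.5, abs=1e-3)
        assert row["min"] == pytest.approx(37.5, abs=1e-3)

    def test_first_occurrence_tie_break(self):
        t = np.arange(0.0, 25.0, 1.0)
        y = np.full(t.size, 38.0)
        y[3] = y[15] = 39.0  # max occurs at 03:00 and again at 15:00
        s = TemperatureSeries(times=t, values=y, clock_anchor=0.0, preprocessed=True)
        from brainthermo import AnalysisWindow
        window = AnalysisWindow(start_time=0.0, end_time=25.0)
        ext = extract_daily_extrema(s, window)
        assert ext.iloc[0]["time_of_max"] == pytest.approx(3.0)

    def test_sparse_day_withheld(self):
        t = np.concatenate([np.arange(0, 5, 1 / 60), np.arange(23.9, 48, 1 / 60)])
        y = np.full(t.size, 38.0)
        s = TemperatureSeries(times=t, values=y, preprocessed=True)
        from brainthermo import AnalysisWindow
        window = AnalysisWindow(start_time=0.0, end_time=48.0)
        ext = extract_daily_extrema(s, window)
        assert bool(ext.iloc[0]["flagged"])  # day 0 has ~21% coverage
        assert not bool(ext.iloc[1]["flagged"])

    def test_extrema_commute_with_constant_shift(self):
        s = _sinusoid(span=48.0, dt=0.25)
        from brainthermo import AnalysisWindow
        w = AnalysisWindow(start_time=0.0, end_time=48.0)
        e0 = extract_daily_extrema(s, w)
        s2 = TemperatureSeries(times=s.times, values=s.values + 1.5, preprocessed=True)
        e1 = extract_daily_extrema(s2, w)
        assert np.allclose(e1["max"], e0["max"] + 1.5)
        assert np.allclose(e1["time_of_max"], e0["time_of_max"])

    def test_summary_stats_closed_form(self):
        s = _sinusoid(span=48.0, dt=1 / 60, mesor=38.6, amp=1.6)
        from brainthermo import AnalysisWindow
        w = AnalysisWindow(start_time=0.0, end_time=48.0)
        stats_ = summary_stats(s, w)
        assert stats_["mean"] == pytest.approx(38.6, abs=0.01)
        assert stats_["min"] == pytest.approx(37.0, abs=0.01)
        assert stats_["max"] == pytest.approx(40.2, abs=0.01)
        assert stats_["range"] == pytest.approx(3.2, abs=0.02)

    def test_constant_day(self):
        t = np.arange(0.0, 24.1, 0.5)
        s = TemperatureSeries(times=t, values=np.full(t.size, 38.0), preprocessed=True)
        from brainthermo import AnalysisWindow
        w = AnalysisWindow(start_time=0.0, end_time=24.0)
        st_ = summary_stats(s, w)
        assert st_["mean"] == 38.0 and st_["range"] == 0.0

    def test_ineligible_window_signals(self):
        t = np.arange(0.0, 10.0, 0.5)
        s = TemperatureSeries(times=t, values=np.full(t.size, 38.0), preprocessed=True)
        from brainthermo import AnalysisWindow
        w = AnalysisWindow(start_time=0.0, end_time=10.0, summary_eligible=False)
        with pytest.raises(IneligibleWindowError):
            summary_stats(s, w)


class TestGeneratorDeterminism:
    def test_fixed_seed_reproducible(self):
        cfg = GeneratorConfig(seed=99)
        s1, t1 = gen_patient_series(cfg, rhythmic=True)
        s2, t2 = gen_patient_series(cfg, rhythmic=True)
        assert np.array_equal(s1.times, s2.times)
        assert np.array_equal(s1.values, s2.values)
        assert t1 == t2

    def test_substreams_independent(self):
        cfg = GeneratorConfig(seed=99)
        s1, _ = gen_patient_series(cfg, rhythmic=True, index=0)
        s2, _ = gen_patient_series(cfg, rhythmic=True, index=1)
        assert not np.array_equal(s1.values, s2.values)
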