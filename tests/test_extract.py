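"""Tests for beat segmentation and component extraction."""

import numpy as np
import pytest

import pulsedecomp as pdc
from pulsedecomp.errors import InvalidParameterError
from conftest import match_beats_to_truth


class TestFindBeats:
    def test_noise_free_session_all_beats_within_4ms(self, clean_session):
        spec, stream, truth = clean_session
        onsets = pdc.find_beats(pdc.DerivativeStream(stream, spec.sample_rate))
        expected = truth["onset_sample"].to_numpy()
        assert onsets.size == len(truth)
        tol = int(round(4e-3 * spec.sample_rate))  # 4 ms
        errs = np.array([np.min(np.abs(onsets - e)) for e in expected])
        assert np.all(errs <= tol)

    def test_all_zero_stream_empty(self):
        stream = pdc.DerivativeStream(np.zeros(4096), 512.0)
        assert pdc.find_beats(stream).size == 0

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            pdc.find_beats(pdc.DerivativeStream(np.zeros(100), 512.0))

    def test_onsets_strictly_increasing_and_refractory(self, noisy_session):
        spec, stream, _ = noisy_session
        onsets = pdc.find_beats(pdc.DerivativeStream(stream, spec.sample_rate))
        ibi_ms = np.diff(onsets) * 1e3 / spec.sample_rate
        assert np.all(ibi_ms >= 300.0)
        assert np.all(ibi_ms <= 2000.0)

    def test_detection_efficiency_clean_stream(self, noisy_extraction):
        *_, report = noisy_extraction
        assert report.beat_detection_efficiency >= 0.92


class TestIntegrateStream:
    def test_round_trip_correlation(self, clean_session):
        spec, stream, truth = clean_session
        integ = pdc.integrate_stream(pdc.DerivativeStream(stream, spec.sample_rate))
        true_pulse = np.cumsum(stream) / spec.sample_rate
        # compare beat-local shapes (the baseline high-pass removes the mean)
        o = truth["onset_sample"].to_numpy()
        n = int(0.9 * np.diff(o).min())
        cors = [
            np.corrcoef(integ[s : s + n], true_pulse[s : s + n])[0, 1]
            for s in o[2:-2]
        ]
        assert np.min(cors) >= 0.99

    def test_zero_in_zero_out(self):
        out = pdc.integrate_stream(pdc.DerivativeStream(np.zeros(2048), 512.0))
        assert np.allclose(out, 0.0)

    def test_white_noise_bounded_no_random_walk(self):
        rng = np.random.default_rng(0)
        stream = pdc.DerivativeStream(rng.normal(size=512 * 120), 512.0)
        out = pdc.integrate_stream(stream)
        # a raw random walk spreads with time; the integrator output must
        # stay stationary (late-window variance comparable to early)
        n = out.size
        var_first = np.var(out[: n // 4])
        var_last = np.var(out[-n // 4 :])
        assert var_last < 5 * var_first
        assert np.max(np.abs(out)) < 10 * np.sqrt(var_first)

    def test_drift_free_windows(self, noisy_session):
        spec, stream, _ = noisy_session
        integ = pdc.integrate_stream(pdc.DerivativeStream(stream, spec.sample_rate))
        win = int(10 * spec.sample_rate)
        means = [integ[i : i + win].mean() for i in range(0, integ.size - win, win)]
        amp = integ.max() - integ.min()
        assert np.max(np.abs(means)) < 0.05 * amp


class TestLocateComponents:
    @staticmethod
    def _beat_segment(delays, amps, width=45.0, noise_sd=0.0, seed=0, period=1000.0):
        comps = tuple(
            pdc.ComponentSpec(delay=d, amplitude=a, width=width) for d, a in zip(delays, amps)
        )
        spec = pdc.SessionSpec(
            stages=(pdc.StageSpec(0, 20.0),),
            noise_sd=noise_sd,
            seed=seed,
            base_hr_bpm=60e3 / period,
            components=comps,
        )
        stream, truth = pdc.synthesize_session(spec)
        ds = pdc.DerivativeStream(stream, 512.0)
        integ = pdc.integrate_stream(ds)
        onsets = truth["onset_sample"].to_numpy()
        seg = integ[onsets[3] : onsets[4]]
        return seg

    def test_known_delays_recovered(self):
        seg = self._beat_segment([90.0, 190.0, 330.0], [1.0, 0.3, 0.4])
        cs = pdc.locate_components(seg, 512.0)
        assert cs.complete
        assert cs.p3_time - cs.p1_time == pytest.approx(240.0, abs=4.0)
        assert cs.p2_time - cs.p1_time == pytest.approx(100.0, abs=4.0)

    def test_single_component_flagged_invalid(self):
        seg = self._beat_segment([90.0], [1.0])
        cs = pdc.locate_components(seg, 512.0)
        assert cs.p2_time is None and cs.p3_time is None
        assert not cs.complete

    def test_short_segment_rejected(self):
        with pytest.raises(InvalidParameterError):
            pdc.locate_components(np.zeros(100), 512.0)

    def test_component_efficiency_clean_cohort(self, noisy_extraction):
        *_, report = noisy_extraction
        assert report.component_detection_efficiency >= 0.90


class TestBeatMetrics:
    def test_t13_subtraction(self):
        cs = pdc.extract.ComponentSet(
            p1_time=160.0, p1_amp=1.0, p2_time=260.0, p2_amp=0.3,
            p3_time=400.0, p3_amp=0.4, envelope_max=1.0,
        )
        m = pdc.beat_metrics(cs)
        assert m["t13"] == pytest.approx(240.0)

    def test_ai_zero_when_equal_heights(self):
        cs = pdc.extract.ComponentSet(
            p1_time=160.0, p1_amp=0.7, p2_time=260.0, p2_amp=0.7,
            p3_time=400.0, p3_amp=0.4, envelope_max=1.0,
        )
        assert pdc.beat_metrics(cs)["ai"] == pytest.approx(0.0)

    def test_missing_component_gives_none(self):
        cs = pdc.extract.ComponentSet(
            p1_time=160.0, p1_amp=1.0, p2_time=None, p2_amp=None,
            p3_time=None, p3_amp=None, envelope_max=1.0,
        )
        m = pdc.beat_metrics(cs)
        assert m["t13"] is None and m["p2p1"] is None and m["ai"] is None

    def test_p2p1_recovered_from_session(self, noisy_extraction):
        _, truth, beats, _ = noisy_extraction
        merged = match_beats_to_truth(beats, truth)
        ok = merged[merged["valid"].astype(bool)]
        err = ok["p2p1"] - ok["p2p1_true"]
        assert abs(err.mean()) < 0.03
        assert ok["p2p1"].mean() == pytest.approx(0.30, abs=0.03)


class TestSnrGate:
    def test_clean_stream_passes(self, clean_session):
        spec, stream, _ = clean_session
        snr, ok = pdc.snr_gate(stream[: int(8 * spec.sample_rate)], spec.sample_rate)
        assert ok and snr > 10.0

    def test_white_noise_fails(self):
        rng = np.random.default_rng(1)
        snr, ok = pdc.snr_gate(rng.normal(size=4096), 512.0)
        assert not ok
        assert snr == pytest.approx(0.0, abs=3.0)  # flat spectrum ≈ 0 dB

    def test_monotone_in_noise_level(self, model_link):
        stages = (pdc.StageSpec(0, 12.0),)
        snrs = []
        for noise in (0.0, 0.02, 0.05, 0.1, 0.3):
            spec = pdc.SessionSpec(stages=stages, noise_sd=noise, seed=5)
            stream, _ = pdc.synthesize_session(spec, model_link=model_link)
            snr, _ = pdc.snr_gate(stream, 512.0)
            snrs.append(snr)
        assert all(a >= b - 0.5 for a, b in zip(snrs, snrs[1:]))

    def test_short_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            pdc.snr_gate(np.zeros(256), 512.0)


class TestClosedLoop:
    def test_t13_recovery_single_subject(self, noisy_extraction):
        _, truth, beats, _ = noisy_extraction
        merged = match_beats_to_truth(beats, truth)
        ok = merged[merged["valid"].astype(bool)]
        g = ok.groupby("lbnp_mmhg").agg(ext=("t13", "mean"), tru=("t13_ms", "mean"))
        rmse = float(np.sqrt(((g["ext"] - g["tru"]) ** 2).mean()))
        assert rmse < 5.0

    def test_window_containment(self, noisy_extraction):
        _, _, beats, _ = noisy_extraction
        valid = beats[beats["valid"].astype(bool)]
        t12 = valid["p2_time"] - valid["p1_time"]
        t13 = valid["t13"]
        assert ((t12 >= 69.0) & (t12 <= 141.0)).all()
        assert ((t13 >= 179.0) & (t13 <= 401.0)).all()

    def test_rate_independence(self, model_link):
        medians = {}
        for fs in (256.0, 512.0, 1024.0):
            spec = pdc.SessionSpec(
                stages=(pdc.StageSpec(0, 30.0),), sample_rate=fs, noise_sd=0.02, seed=3
            )
            stream, truth = pdc.synthesize_session(spec, model_link=model_link)
            beats, _ = pdc.extract_session(pdc.DerivativeStream(stream, fs), truth=truth)
            medians[fs] = beats.loc[beats["valid"].astype(bool), "t13"].median()
        # within one sample period of the coarsest rate
        assert abs(medians[256.0] - medians[512.0]) <= 1e3 / 256.0
        assert abs(medians[1024.0] - medians[512.0]) <= 1e3 / 512.0

    def test_heart_rate_separation(self, model_link):
        # period shrinks, pressures fixed: T13 flat while IBI falls
        stages = (
            pdc.StageSpec(0, 30.0, 0.0, 0.0),
            pdc.StageSpec(-15, 30.0, 0.0, 10.0),
            pdc.StageSpec(-30, 30.0, 0.0, 25.0),
        )
        spec = pdc.SessionSpec(stages=stages, seed=7)
        stream, truth = pdc.synthesize_session(spec, model_link=model_link)
        beats, _ = pdc.extract_session(
            pdc.DerivativeStream(stream, spec.sample_rate), truth=truth
        )
        ok = beats[beats["valid"].astype(bool)]
        t = ok["onset_sample"].to_numpy() / spec.sample_rate
        ibi = np.diff(ok["onset_sample"].to_numpy()) * 1e3 / spec.sample_rate
        ibi_slope = np.polyfit(t[1:], ibi, 1)[0]
        t13_slope = np.polyfit(t, ok["t13"].to_numpy(), 1)[0]
        assert ibi_slope < -1.0  # ms per second, clearly negative
        assert abs(t13_slope) < 0.05


class TestQualityReport:
    def test_no_beats_warning_on_silence(self):
        stream = pdc.DerivativeStream(np.zeros(int(512 * 10)), 512.0)
        with pytest.warns(UserWarning):
            beats, report = pdc.extract_session(stream)
        assert report.beats_detected == 0
        assert report.no_beats_warning
        assert len(beats) == 0

    def test_efficiencies_in_unit_interval(self, noisy_extraction):
        *_, report = noisy_extraction
        assert 0.0 <= report.beat_detection_efficiency <= 1.0
        assert 0.0 <= report.component_detection_efficiency <= 1.0
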