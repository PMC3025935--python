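"""Beat segmentation and component-pulse extraction.

Implements the decomposition algorithm on a sensor-derivative stream:

1. a peak finder identifies heartbeats in the derivative stream;
2. a Bessel-filtered digital integrator reconstructs the pulse waveform;
3. the second derivative of the reconstructed beat locates the renal and
   iliac component pulses via its inversions inside physiological search
   windows ([70, 140] ms and [180, 400] ms after the primary peak);
4. a low-pass filter isolates the primary systolic peak;
5. a spectral signal-to-noise gate excludes low-fidelity stretches.

Per-beat outputs are the T13 delay, the P2P1 amplitude ratio, the
augmentation index and the second-derivative d/a ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidParameterError

__all__ = [
    "DerivativeStream",
    "ExtractSettings",
    "ComponentSet",
    "BeatRecord",
    "QualityReport",
    "find_beats",
    "integrate_stream",
    "locate_components",
    "beat_metrics",
    "snr_gate",
    "extract_session",
]


@dataclass(frozen=True)
class DerivativeStream:
    """A single-channel derivative recording."""

    samples: np.ndarray
    sample_rate: float = 512.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.sample_rate > 0:
            raise InvalidParameterError("sample_rate must be > 0")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("stream contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class ExtractSettings:
    """Tunable algorithm settings (defaults are the documented values)."""

    p2_window_ms: tuple[float, float] = (70.0, 140.0)
    p3_window_ms: tuple[float, float] = (180.0, 400.0)
    integrator_order: int = 4
    integrator_hz: float = 20.0
    baseline_hp_hz: float = 0.3
    primary_lp_hz: float = 8.0
    beat_lp_hz: float = 18.0
    refractory_ms: float = 300.0
    max_ibi_ms: float = 2000.0
    beat_threshold_frac: float = 0.35
    inversion_depth_frac: float = 0.30
    snr_band_hz: tuple[float, float] = (0.5, 15.0)
    snr_threshold_db: float = 10.0
    snr_ceiling_db: float = 60.0
    snr_window_s: float = 4.0


@dataclass
class ComponentSet:
    """Located component pulses of one beat.  Times are ms from beat
    onset; amplitudes are integrated-waveform units above the diastolic
    foot.  Missing components are None."""

    p1_time: float
    p1_amp: float
    p2_time: Optional[float]
    p2_amp: Optional[float]
    p3_time: Optional[float]
    p3_amp: Optional[float]
    envelope_max: float
    sdptg_a: Optional[float] = None
    sdptg_d: Optional[float] = None

    @property
    def complete(self) -> bool:
        return self.p2_time is not None and self.p3_time is not None


@dataclass
class BeatRecord:
    """One analyzed beat."""

    onset_sample: int
    p1_time: float
    p1_amp: float
    p2_time: Optional[float]
    p2_amp: Optional[float]
    p3_time: Optional[float]
    p3_amp: Optional[float]
    t13: Optional[float]
    p2p1: Optional[float]
    ai: Optional[float]
    d_over_a: Optional[float]
    snr_db: float
    valid: bool


@dataclass
class QualityReport:
    """Stream-level quality summary."""

    beats_detected: int
    beats_expected: Optional[int]
    beat_detection_efficiency: Optional[float]
    component_detection_efficiency: float
    snr_db_median: float
    no_beats_warning: bool = False

    def as_dict(self) -> dict:
        return {
            "beats_detected": self.beats_detected,
            "beats_expected": self.beats_expected,
            "beat_detection_efficiency": self.beat_detection_efficiency,
            "component_detection_efficiency": self.component_detection_efficiency,
            "snr_db_median": self.snr_db_median,
            "no_beats_warning": self.no_beats_warning,
        }


def _sos_lowpass(order: int, cutoff_hz: float, fs: float, ftype: str = "bessel"):
    wn = min(cutoff_hz / (fs / 2.0), 0.99)
    design = signal.bessel if ftype == "bessel" else signal.butter
    return design(order, wn, btype="lowpass", output="sos")


def find_beats(stream: DerivativeStream, settings: ExtractSettings = ExtractSettings()) -> np.ndarray:
    """Detect beat onsets in the derivative stream.

    The stream is smoothed with a low-pass Bessel filter; upstroke maxima
    above an adaptive threshold and separated by the refractory interval
    mark beats.  The onset of each beat is the zero-crossing of the
    smoothed derivative preceding its maximal positive excursion.
    Returns strictly increasing onset sample indices (empty if no beats).
    """
    fs = stream.sample_rate
    x = stream.samples
    if x.size < 2 * fs:
        raise InvalidParameterError("need at least 2 s of signal")
    if not np.any(x != 0.0):
        return np.array([], dtype=int)
    sos = _sos_lowpass(4, settings.beat_lp_hz, fs)
    sm = signal.sosfiltfilt(sos, x)
    dist = max(1, int(round(settings.refractory_ms * fs / 1e3)))
    peaks, _ = signal.find_peaks(sm, distance=dist)
    if peaks.size == 0:
        return np.array([], dtype=int)
    heights = sm[peaks]
    thr = settings.beat_threshold_frac * np.percentile(heights, 85)
    if thr <= 0:
        return np.array([], dtype=int)
    peaks = peaks[heights >= thr]
    onsets = []
    lookback = int(round(settings.refractory_ms * fs / 1e3))
    zero_back = int(round(0.04 * fs))  # zero-crossing search span below the foot
    for p in peaks:
        lo = max(0, p - lookback)
        seg = sm[lo : p + 1]
        # rise foot: last sample at or below 3% of the upstroke peak,
        # then the zero-crossing just before it (hysteresis against noise)
        below = np.nonzero(seg <= 0.03 * sm[p])[0]
        foot = lo + (int(below[-1]) if below.size else 0)
        lo2 = max(lo, foot - zero_back)
        zeros = np.nonzero(sm[lo2 : foot + 1] <= 0)[0]
        onset = lo2 + int(zeros[-1]) if zeros.size else foot
        if onsets and onset <= onsets[-1]:
            continue
        onsets.append(onset)
    return np.asarray(onsets, dtype=int)


def integrate_stream(stream: DerivativeStream, settings: ExtractSettings = ExtractSettings()) -> np.ndarray:
    """Reconstruct the pulse waveform from the derivative stream.

    Cumulative summation followed by a zero-phase low-pass Bessel filter
    (the digital integrator) and a slow baseline high-pass that removes
    integration drift, so the output carries no random-walk growth even
    for noise-only input.
    """
    fs = stream.sample_rate
    x = np.cumsum(stream.samples) / fs
    if not np.any(x != 0.0):
        return x
    sos_lp = _sos_lowpass(settings.integrator_order, settings.integrator_hz, fs)
    y = signal.sosfiltfilt(sos_lp, x)
    wn = settings.baseline_hp_hz / (fs / 2.0)
    sos_hp = signal.butter(2, wn, btype="highpass", output="sos")
    return signal.sosfiltfilt(sos_hp, y)


def _parabolic_vertex(y: np.ndarray, i: int) -> float:
    """Sub-sample extremum location by parabolic interpolation around i."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def _second_derivative(seg: np.ndarray) -> np.ndarray:
    """Central-difference second derivative (in sample units)."""
    return np.gradient(np.gradient(seg))


def _find_inversion(
    sd: np.ndarray, lo: int, hi: int, depth_frac: float, scale: float
) -> Optional[float]:
    """Earliest qualifying second-derivative inversion in [lo, hi).

    Qualifying = interior local minimum with depth at least ``depth_frac``
    of the deepest minimum in the window AND at least 0.5% of the beat's
    curvature scale (guards against naming filter ripple a component).
    Refined by parabolic interpolation; returns a fractional sample index
    clipped to the window, or None when no component is present."""
    lo = max(lo, 1)
    hi = min(hi, sd.size - 1)
    if hi <= lo + 2:
        return None
    w = sd[lo:hi]
    floor = w.min()
    abs_gate = -5e-3 * scale
    if floor >= 0 or floor > abs_gate:
        return None
    idx = np.nonzero(
        (w[1:-1] <= w[:-2])
        & (w[1:-1] <= w[2:])
        & (w[1:-1] <= depth_frac * floor)
        & (w[1:-1] <= abs_gate)
    )[0]
    if idx.size == 0:
        # a minimum clipped by the window edge is not a detection
        interior = int(np.argmin(w))
        if interior <= 0 or interior >= w.size - 1:
            return None
        i = lo + interior
    else:
        i = lo + 1 + int(idx[0])
    return float(np.clip(_parabolic_vertex(sd, i), lo, hi))


def _sdptg_waves(sd: np.ndarray, i1: int, fs: float) -> tuple[Optional[float], Optional[float]]:
    """Label the second-derivative a-e waves and return (a, d) amplitudes.

    a is the first dominant maximum (on the systolic upstroke), then
    alternating extrema b (min), c (max), d (min)."""
    hi = min(sd.size, i1 + int(0.25 * fs))
    up = sd[:hi]
    if up.size < 5:
        return None, None
    a_idx = int(np.argmax(up))
    a = sd[a_idx]
    if a <= 0:
        return None, None
    # walk alternating extrema after a
    extrema = []
    want_min = True
    i = a_idx + 1
    limit = min(sd.size - 1, i1 + int(0.35 * fs))
    while i < limit and len(extrema) < 3:
        if want_min and sd[i] <= sd[i - 1] and sd[i] <= sd[i + 1]:
            extrema.append(i)
            want_min = False
        elif not want_min and sd[i] >= sd[i - 1] and sd[i] >= sd[i + 1]:
            extrema.append(i)
            want_min = True
        i += 1
    if len(extrema) < 3:
        return a, None
    d_idx = extrema[2]  # b (min), c (max), d (min)
    return float(a), float(sd[d_idx])


def locate_components(
    segment: np.ndarray,
    sample_rate: float,
    settings: ExtractSettings = ExtractSettings(),
) -> ComponentSet:
    """Locate the component pulses within one integrated beat segment.

    The primary peak is the global maximum of the low-passed segment; the
    renal and iliac components are second-derivative inversions in the
    [P1+70, P1+140] ms and [P1+180, P1+400] ms windows.  Amplitudes are
    read from the integrated waveform above the pre-systolic foot.
    """
    fs = sample_rate
    seg = np.asarray(segment, dtype=float)
    if seg.size < 0.4 * fs:
        raise InvalidParameterError("beat segment must cover at least 400 ms")

    sos = _sos_lowpass(2, settings.primary_lp_hz, fs, ftype="butter")
    lp = signal.sosfiltfilt(sos, seg)
    i1 = int(np.argmax(lp))
    # refine on the full-band segment near the low-passed maximum
    w = max(1, int(0.03 * fs))
    lo1 = max(0, i1 - w)
    i1 = lo1 + int(np.argmax(seg[lo1 : min(seg.size, i1 + w + 1)]))
    p1_pos = _parabolic_vertex(seg, i1)
    foot = float(np.min(seg[: max(1, i1)]))
    p1_amp = float(np.interp(p1_pos, np.arange(seg.size), seg) - foot)

    sd = _second_derivative(seg)

    def window(bounds_ms: tuple[float, float]) -> tuple[int, int]:
        lo = i1 + int(round(bounds_ms[0] * fs / 1e3))
        hi = i1 + int(round(bounds_ms[1] * fs / 1e3))
        return lo, min(hi, seg.size - 1)

    sd_scale = float(np.max(np.abs(sd)))
    result: dict[str, Optional[float]] = {}
    for key, bounds in (("p2", settings.p2_window_ms), ("p3", settings.p3_window_ms)):
        lo, hi = window(bounds)
        pos = _find_inversion(sd, lo, hi, settings.inversion_depth_frac, sd_scale)
        if pos is None:
            result[f"{key}_time"] = None
            result[f"{key}_amp"] = None
        else:
            result[f"{key}_time"] = (pos - p1_pos) * 1e3 / fs
            result[f"{key}_amp"] = float(np.interp(pos, np.arange(seg.size), seg) - foot)

    a_amp, d_amp = _sdptg_waves(sd, i1, fs)
    cs = ComponentSet(
        p1_time=p1_pos * 1e3 / fs,
        p1_amp=p1_amp,
        p2_time=None if result["p2_time"] is None else result["p2_time"] + p1_pos * 1e3 / fs,
        p2_amp=result["p2_amp"],
        p3_time=None if result["p3_time"] is None else result["p3_time"] + p1_pos * 1e3 / fs,
        p3_amp=result["p3_amp"],
        envelope_max=float(np.max(seg) - foot),
        sdptg_a=a_amp,
        sdptg_d=d_amp,
    )
    return cs


def beat_metrics(components: ComponentSet) -> dict[str, Optional[float]]:
    """Per-beat metrics from a located component set.

    T13 = p3_time - p1_time (ms); P2P1 = p2_amp / p1_amp; augmentation
    index AI = (p2_amp - p1_amp) / envelope maximum; d/a from the labelled
    second-derivative waves.  Metrics whose inputs are missing are None —
    never fabricated.
    """
    t13 = p2p1 = ai = d_over_a = None
    if components.p3_time is not None:
        t13 = components.p3_time - components.p1_time
    if components.p2_amp is not None and components.p1_amp > 0:
        p2p1 = components.p2_amp / components.p1_amp
        if components.envelope_max > 0:
            ai = (components.p2_amp - components.p1_amp) / components.envelope_max
    if components.sdptg_a and components.sdptg_d is not None:
        d_over_a = components.sdptg_d / components.sdptg_a
    return {"t13": t13, "p2p1": p2p1, "ai": ai, "d_over_a": d_over_a}


def snr_gate(
    window: np.ndarray,
    sample_rate: float,
    settings: ExtractSettings = ExtractSettings(),
) -> tuple[float, bool]:
    """Spectral signal-to-noise figure of merit for a stream window.

    Ratio of the mean in-band (default 0.5-15 Hz) to mean out-of-band
    power spectral density in dB, capped at the configured ceiling; the
    window passes if the ratio meets the threshold.  A spectrally flat
    (white-noise) window scores 0 dB.  Requires >= 2 s of signal.
    """
    fs = sample_rate
    x = np.asarray(window, dtype=float)
    if x.size < 2 * fs:
        raise InvalidParameterError("S/N window must cover at least 2 s")
    nper = min(x.size, int(4 * fs))
    freqs, psd = signal.welch(x, fs=fs, nperseg=nper)
    lo, hi = settings.snr_band_hz
    inband = (freqs >= lo) & (freqs <= hi)
    if not inband.any() or inband.all():
        raise InvalidParameterError("S/N band degenerate at this sample rate")
    p_in = float(np.mean(psd[inband]))
    p_out = float(np.mean(psd[~inband]))
    if p_in <= 0:
        return -settings.snr_ceiling_db, False
    if p_out <= 0:
        return settings.snr_ceiling_db, True
    snr_db = min(10.0 * math.log10(p_in / p_out), settings.snr_ceiling_db)
    return snr_db, snr_db >= settings.snr_threshold_db


def _match_onsets(detected: np.ndarray, expected: np.ndarray, tol: int) -> int:
    """Count expected onsets matched by a detected onset within tol samples."""
    matched = 0
    j = 0
    for e in expected:
        while j < detected.size and detected[j] < e - tol:
            j += 1
        if j < detected.size and abs(int(detected[j]) - int(e)) <= tol:
            matched += 1
            j += 1
    return matched


def extract_session(
    stream: DerivativeStream,
    settings: ExtractSettings = ExtractSettings(),
    truth: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, QualityReport]:
    """Run the full per-beat analysis on a derivative stream.

    Returns a beat table (one :class:`BeatRecord` per row) and a
    :class:`QualityReport`.  Windows failing the S/N gate are excluded
    from beat analysis.  If ``truth`` (a synthesizer truth table) is
    given, detection efficiencies are computed against it.
    """
    fs = stream.sample_rate
    n = stream.samples.size
    win = max(int(settings.snr_window_s * fs), int(2 * fs))
    n_blocks = max(1, n // win)
    block_snr = np.empty(n_blocks)
    block_pass = np.empty(n_blocks, dtype=bool)
    for b in range(n_blocks):
        seg = stream.samples[b * win : (b + 1) * win if b < n_blocks - 1 else n]
        block_snr[b], block_pass[b] = snr_gate(seg, fs, settings)

    onsets = find_beats(stream, settings)
    integrated = integrate_stream(stream, settings)

    records: list[BeatRecord] = []
    max_seg = int(settings.max_ibi_ms * fs / 1e3)
    for k, onset in enumerate(onsets):
        block = min(int(onset) // win, n_blocks - 1)
        if not block_pass[block]:
            continue
        end = int(onsets[k + 1]) if k + 1 < onsets.size else min(n, int(onset) + max_seg)
        seg = integrated[onset:end]
        if seg.size < 0.4 * fs:
            continue
        cs = locate_components(seg, fs, settings)
        metrics = beat_metrics(cs)
        valid = cs.complete
        if valid:
            t12 = cs.p2_time - cs.p1_time
            t13 = metrics["t13"]
            w2, w3 = settings.p2_window_ms, settings.p3_window_ms
            # containment is guaranteed by the windowed search
            assert w2[0] - 1 <= t12 <= w2[1] + 1, t12
            assert w3[0] - 1 <= t13 <= w3[1] + 1, t13
        records.append(
            BeatRecord(
                onset_sample=int(onset),
                p1_time=cs.p1_time,
                p1_amp=cs.p1_amp,
                p2_time=cs.p2_time,
                p2_amp=cs.p2_amp,
                p3_time=cs.p3_time,
                p3_amp=cs.p3_amp,
                t13=metrics["t13"],
                p2p1=metrics["p2p1"],
                ai=metrics["ai"],
                d_over_a=metrics["d_over_a"],
                snr_db=float(block_snr[block]),
                valid=valid,
            )
        )

    beats = pd.DataFrame([r.__dict__ for r in records])
    if beats.empty:
        beats = pd.DataFrame(
            columns=[
                "onset_sample", "p1_time", "p1_amp", "p2_time", "p2_amp",
                "p3_time", "p3_amp", "t13", "p2p1", "ai", "d_over_a",
                "snr_db", "valid",
            ]
        )

    beats_expected = None
    beat_eff = None
    if truth is not None:
        expected = np.sort(truth["onset_sample"].to_numpy())
        beats_expected = int(expected.size)
        tol = int(0.1 * fs)  # 100 ms association window
        matched = _match_onsets(np.asarray(onsets), expected, tol)
        beat_eff = matched / beats_expected if beats_expected else 0.0
    comp_eff = float(beats["valid"].mean()) if len(beats) else 0.0
    report = QualityReport(
        beats_detected=int(len(beats)),
        beats_expected=beats_expected,
        beat_detection_efficiency=beat_eff,
        component_detection_efficiency=comp_eff,
        snr_db_median=float(np.median(block_snr)),
        no_beats_warning=len(beats) == 0,
    )
    if report.no_beats_warning:
        warnings.warn("no beats detected in stream", stacklevel=2)
    return beats, report
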