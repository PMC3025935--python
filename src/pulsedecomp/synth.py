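"""Ground-truthed synthetic sensor streams.

The emulated sensor reports the *time derivative* of the arterial pulse,
sampled at 512 Hz.  A session is a sequence of lower-body-negative-
pressure (LBNP) stages; each stage shifts diastolic pressure and heart
rate relative to the session baseline.  Every beat is a superposition of
five unimodal component kernels (primary ejection plus renal, iliac and
two higher-order reflections) whose delays can optionally be driven by
the forward model so that the synthesized ground truth and the model's
arrival times agree exactly.

The emitted stream is the first difference of the concatenated pressure
waveform scaled by the sample rate, plus additive white Gaussian noise;
cumulative summation (divided by the sample rate) recovers the pressure
waveform up to its initial value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .model import (
    ArrivalTimes,
    ArterialTree,
    PressureState,
    ReflectionCoefficients,
    arrival_times,
)

__all__ = [
    "ComponentSpec",
    "BeatSpec",
    "StageSpec",
    "SessionSpec",
    "Kernel",
    "component_kernel",
    "synthesize_beat",
    "synthesize_session",
    "default_components",
    "default_session_spec",
    "LBNP_STAGES",
]

#: Allowed chamber pressures, mmHg.
LBNP_STAGES = (0, -15, -30, -45, -60)

#: FWHM -> Gaussian sigma.
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Kernel support half-width in sigmas.
_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True)
class ComponentSpec:
    """One component pulse: peak delay from beat onset (ms), amplitude as a
    fraction of the primary amplitude, width (FWHM, ms) and skew (>= 0;
    0 gives a symmetric kernel)."""

    delay: float
    amplitude: float
    width: float
    skew: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude <= 1.5:
            raise InvalidParameterError("component amplitude must lie in (0, 1.5]")
        if not self.width > 0:
            raise InvalidParameterError("component width must be > 0")
        if self.skew < 0:
            raise InvalidParameterError("component skew must be >= 0")
        if self.delay < 0:
            raise InvalidParameterError("component delay must be >= 0 ms")


@dataclass(frozen=True)
class BeatSpec:
    """One beat: inter-beat period (ms), component set and the ground-truth
    pressure state."""

    period: float
    components: tuple[ComponentSpec, ...]
    pressure_state: PressureState

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise InvalidParameterError("beat period must be > 0 ms")
        delays = [c.delay for c in self.components]
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise InvalidParameterError("component delays must be strictly increasing")
        last = self.components[-1]
        if last.delay + 3.0 * last.width >= self.period:
            raise InvalidParameterError(
                f"last component (delay {last.delay:g} ms) spills into the next "
                f"beat at period {self.period:g} ms"
            )


@dataclass(frozen=True)
class StageSpec:
    """One LBNP stage: chamber pressure, duration and the hemodynamic
    shifts applied relative to the session baseline."""

    lbnp_mmhg: int
    duration_s: float
    diastole_shift_mmhg: float = 0.0
    hr_shift_bpm: float = 0.0

    def __post_init__(self) -> None:
        if self.lbnp_mmhg not in LBNP_STAGES:
            raise InvalidParameterError(
                f"lbnp_mmhg must be one of {LBNP_STAGES}, got {self.lbnp_mmhg}"
            )
        if not self.duration_s > 0:
            raise InvalidParameterError("stage duration must be > 0 s")


@dataclass(frozen=True)
class SessionSpec:
    """Full synthesis schedule for one recording session."""

    stages: tuple[StageSpec, ...]
    sample_rate: float = 512.0
    noise_sd: float = 0.02
    seed: int = 0
    base_state: PressureState = field(default_factory=lambda: PressureState(120.0, 75.0))
    base_hr_bpm: float = 60.0
    components: tuple[ComponentSpec, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise InvalidParameterError("sample_rate must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not self.base_hr_bpm > 0:
            raise InvalidParameterError("base_hr_bpm must be > 0")
        if self.components is None:
            object.__setattr__(self, "components", default_components())


class Kernel(NamedTuple):
    """A unit-peak component line shape and the sample index of its peak."""

    samples: np.ndarray
    peak_index: int


def component_kernel(width: float, skew: float, sample_rate: float) -> Kernel:
    """Unit-peak, single-maximum component kernel.

    A two-sided Gaussian: left standard deviation ``sigma = width * 0.4247``
    (width is FWHM in ms), right standard deviation ``sigma * (1 + skew)``.
    ``skew = 0`` yields a kernel equal to its mirror image about the peak.
    """
    if skew < 0:
        raise InvalidParameterError("skew must be >= 0")
    width_samples = width * sample_rate / 1e3
    if width_samples < 4.0:
        raise InvalidParameterError(
            f"width {width:g} ms is below resolution at {sample_rate:g} Hz "
            "(needs >= 4 samples)"
        )
    sigma_l = width * _FWHM_TO_SIGMA
    sigma_r = sigma_l * (1.0 + skew)
    peak = int(round(_SUPPORT_SIGMAS * sigma_l * sample_rate / 1e3))
    tail = int(round(_SUPPORT_SIGMAS * sigma_r * sample_rate / 1e3))
    t_ms = (np.arange(peak + tail + 1) - peak) * 1e3 / sample_rate
    sigma = np.where(t_ms < 0, sigma_l, sigma_r)
    k = np.exp(-0.5 * (t_ms / sigma) ** 2)
    return Kernel(samples=k, peak_index=peak)


def synthesize_beat(spec: BeatSpec, sample_rate: float) -> np.ndarray:
    """Sum of scaled, delayed component kernels over one beat period.

    The output is the dimensionless beat *shape* (primary amplitude 1,
    baseline 0); session synthesis scales it by pulse pressure and offsets
    it by diastolic pressure.  Component peaks are placed at fractional
    sample positions (the kernel is evaluated on the shifted time grid) so
    the recorded ground-truth delays carry no quantization error.  Kernels
    are clipped at the beat boundaries.
    """
    fs = sample_rate
    n = int(round(spec.period * fs / 1e3))
    x = np.zeros(n)
    prev_delay = None
    for comp in spec.components:
        if prev_delay is not None and (comp.delay - prev_delay) * fs / 1e3 < 1.0:
            raise InvalidParameterError(
                f"component delays {comp.delay:g} ms closer than one sample"
            )
        prev_delay = comp.delay
        # validates width resolution; support bounds mirror the kernel's
        component_kernel(comp.width, comp.skew, fs)
        sigma_l = comp.width * _FWHM_TO_SIGMA
        sigma_r = sigma_l * (1.0 + comp.skew)
        lo = max(0, int(math.ceil((comp.delay - _SUPPORT_SIGMAS * sigma_l) * fs / 1e3)))
        hi = min(n, int(math.floor((comp.delay + _SUPPORT_SIGMAS * sigma_r) * fs / 1e3)) + 1)
        if hi <= lo:
            continue
        t_ms = np.arange(lo, hi) * 1e3 / fs - comp.delay
        sigma = np.where(t_ms < 0, sigma_l, sigma_r)
        x[lo:hi] += comp.amplitude * np.exp(-0.5 * (t_ms / sigma) ** 2)
    return x


def _stage_beat_spec(
    session: SessionSpec,
    stage: StageSpec,
    model_link: Optional[tuple[ArterialTree, ReflectionCoefficients]],
) -> tuple[BeatSpec, Optional[ArrivalTimes]]:
    """Resolve the per-stage beat specification (delays possibly driven by
    the forward model)."""
    base = session.base_state
    state = PressureState(base.psyst, base.pdiast + stage.diastole_shift_mmhg)
    hr = session.base_hr_bpm + stage.hr_shift_bpm
    period = 60e3 / hr
    comps = session.components
    at: Optional[ArrivalTimes] = None
    if model_link is not None:
        tree, coeffs = model_link
        at = arrival_times(state, tree, coeffs)
        d1, d2, d3 = at.t1 * 1e3, at.t2 * 1e3, at.t3 * 1e3
        # higher-order re-reflections trail the iliac pulse at the
        # renal-iliac round-trip spacing
        gap = d3 - d2
        delays = (d1, d2, d3, d3 + gap, d3 + 2.0 * gap)
        comps = tuple(
            ComponentSpec(delay=d, amplitude=c.amplitude, width=c.width, skew=c.skew)
            for d, c in zip(delays, comps)
        )
    return BeatSpec(period=period, components=comps, pressure_state=state), at


def synthesize_session(
    spec: SessionSpec,
    model_link: Optional[tuple[ArterialTree, ReflectionCoefficients]] = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize a full session.

    Returns ``(stream, truth)`` where ``stream`` is the 512-Hz derivative
    signal (first difference of the pressure waveform scaled by the sample
    rate, plus Gaussian noise of standard deviation ``noise_sd`` times the
    peak noise-free derivative amplitude) and ``truth`` is a per-beat
    DataFrame with columns ``beat_index, onset_sample, t13_ms, t12_ms,
    p2p1, psyst, pdiast, lbnp_mmhg, period_ms``.

    When ``model_link`` (an ``(ArterialTree, ReflectionCoefficients)``
    pair) is given, per-stage component delays are set from the forward
    model's arrival times, so the recorded true T13 equals the model's
    T13 exactly.  Identical seeds produce bitwise-identical streams.
    """
    if len(spec.stages) == 0:
        raise InvalidParameterError("session must contain at least one stage")
    fs = spec.sample_rate
    rng = np.random.default_rng(spec.seed)

    chunks: list[np.ndarray] = []
    rows: list[dict] = []
    # flat diastolic lead-in keeps filter transients off the first beat
    first_state = PressureState(
        spec.base_state.psyst,
        spec.base_state.pdiast + spec.stages[0].diastole_shift_mmhg,
    )
    lead = np.full(int(round(0.25 * fs)), first_state.pdiast)
    chunks.append(lead)
    cursor = lead.size
    beat_index = 0
    for stage in spec.stages:
        beat_spec, at = _stage_beat_spec(spec, stage, model_link)
        shape = synthesize_beat(beat_spec, fs)
        state = beat_spec.pressure_state
        wave = state.pdiast + state.pulse_pressure * shape
        n_beats = max(1, int(stage.duration_s * 1e3 // beat_spec.period))
        comps = beat_spec.components
        if at is not None:
            t13_ms, t12_ms = at.t13_ms, at.t12_ms
        else:
            t13_ms = comps[2].delay - comps[0].delay if len(comps) >= 3 else math.nan
            t12_ms = comps[1].delay - comps[0].delay if len(comps) >= 2 else math.nan
        p2p1 = comps[1].amplitude / comps[0].amplitude if len(comps) >= 2 else math.nan
        # beat onset = start of the primary kernel's support
        sigma_l1 = comps[0].width * _FWHM_TO_SIGMA
        onset_off = max(
            0, int(round((comps[0].delay - _SUPPORT_SIGMAS * sigma_l1) * fs / 1e3))
        )
        for _ in range(n_beats):
            rows.append(
                {
                    "beat_index": beat_index,
                    "onset_sample": cursor + onset_off,
                    "t13_ms": t13_ms,
                    "t12_ms": t12_ms,
                    "p2p1": p2p1,
                    "psyst": state.psyst,
                    "pdiast": state.pdiast,
                    "lbnp_mmhg": stage.lbnp_mmhg,
                    "period_ms": beat_spec.period,
                }
            )
            chunks.append(wave)
            cursor += wave.size
            beat_index += 1

    pressure = np.concatenate(chunks)
    stream = np.diff(pressure, prepend=pressure[0]) * fs
    if spec.noise_sd > 0:
        sd = spec.noise_sd * np.max(np.abs(stream))
        stream = stream + rng.normal(0.0, sd, size=stream.size)
    truth = pd.DataFrame(rows)
    return stream, truth


def default_components() -> tuple[ComponentSpec, ...]:
    """Default five-component morphology.

    Delays follow the default forward-model arrival times at 120/80 mmHg;
    amplitudes are 1.0, 0.30, 0.40, 0.08, 0.02 of the primary (the iliac
    reflection carries ~40% of pulse pressure, higher orders diminish
    sharply).
    """
    width, skew = 50.0, 0.3
    return (
        ComponentSpec(delay=90.0, amplitude=1.00, width=width, skew=skew),
        ComponentSpec(delay=215.0, amplitude=0.30, width=width, skew=skew),
        ComponentSpec(delay=292.0, amplitude=0.40, width=width, skew=skew),
        ComponentSpec(delay=369.0, amplitude=0.08, width=width, skew=skew),
        ComponentSpec(delay=446.0, amplitude=0.02, width=width, skew=skew),
    )


def default_session_spec(seed: int = 0, stage_duration_s: float = 60.0) -> SessionSpec:
    """Default five-stage LBNP schedule.

    Chamber stages 0 to -60 mmHg raise diastole by 0/5/10/15/20 mmHg at
    fixed systole (pulse pressure falls, as under progressive central
    hypovolemia) and raise heart rate by 0/2/5/12/25 bpm.
    """
    lbnp = LBNP_STAGES
    dia = (0.0, 5.0, 10.0, 15.0, 20.0)
    hr = (0.0, 2.0, 5.0, 12.0, 25.0)
    stages = tuple(
        StageSpec(lbnp_mmhg=l, duration_s=stage_duration_s, diastole_shift_mmhg=d, hr_shift_bpm=h)
        for l, d, h in zip(lbnp, dia, hr)
    )
    return SessionSpec(stages=stages, seed=seed)
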