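"""Forward model of peripheral arterial pulse arrival times.

The peripheral pressure pulse is treated as a superposition of a primary
ejection pulse and two central reflections (renal and iliac).  Each
component travels its arterial path legs at a pressure-dependent wave
speed, so the arrival-time differences T12 = t2 - t1 and T13 = t3 - t1
respond to blood-pressure changes.  Wave speed follows a Moens-Korteweg
relation with an exponential pressure factor,

    v(P) = sqrt(h * E * exp(zeta * P) / (2 * rho * alpha)),

where ``h`` is wall thickness, ``E`` Young's modulus, ``rho`` fluid
density, ``alpha`` vessel diameter and ``zeta`` a compliance exponent in
1/mmHg.  Central (aortic) segments may instead use the first-order
linearization of this relation about a reference pressure, which is the
default calibration: an exponential arm response combined with an
essentially linear central response.

Units: pressures are mmHg throughout, lengths metres, times seconds
internally (millisecond accessors are provided for reporting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidParameterError, ModelInconsistencyError

__all__ = [
    "ArterialSegment",
    "ArterialTree",
    "ReflectionCoefficients",
    "PressureState",
    "ComponentPressures",
    "ArrivalTimes",
    "wave_speed",
    "renal_reflection_coefficient",
    "component_pressures",
    "arrival_times",
    "t13_pressure_curve",
    "reflection_attenuation",
    "default_tree",
    "default_coefficients",
]

#: Valid pressure range for wave-speed evaluation, mmHg.
PRESSURE_RANGE = (20.0, 250.0)

_RESPONSE_KINDS = ("exponential", "linear")
_SEGMENT_NAMES = ("arm_x1", "thoracic_x2", "abdominal_x3")


@dataclass(frozen=True)
class ArterialSegment:
    """Geometry and elasticity of one arterial path.

    Parameters
    ----------
    name
        One of ``arm_x1``, ``thoracic_x2``, ``abdominal_x3``.
    length
        Path length in metres.
    youngs_modulus
        Wall Young's modulus in pascals.
    wall_thickness
        Wall thickness in metres.
    diameter
        Vessel diameter in metres.
    fluid_density
        Blood density in kg/m^3.
    compliance_exponent
        Pressure sensitivity ``zeta`` of the wave speed, 1/mmHg.
    response_kind
        ``"exponential"`` for the full Moens-Korteweg pressure factor,
        ``"linear"`` for its first-order expansion about
        ``linearization_pressure`` (used for the central segments).
    linearization_pressure
        Expansion point for the linear response, mmHg.
    """

    name: str
    length: float
    youngs_modulus: float
    wall_thickness: float
    diameter: float
    fluid_density: float = 1050.0
    compliance_exponent: float = 0.0
    response_kind: str = "exponential"
    linearization_pressure: float = 90.0

    def __post_init__(self) -> None:
        if self.name not in _SEGMENT_NAMES:
            raise InvalidParameterError(
                f"unknown segment name {self.name!r}; expected one of {_SEGMENT_NAMES}"
            )
        for field_name in ("length", "youngs_modulus", "wall_thickness", "diameter", "fluid_density"):
            if not getattr(self, field_name) > 0:
                raise InvalidParameterError(f"{self.name}: {field_name} must be > 0")
        if self.compliance_exponent < 0:
            raise InvalidParameterError(f"{self.name}: compliance_exponent must be >= 0")
        if self.response_kind not in _RESPONSE_KINDS:
            raise InvalidParameterError(
                f"{self.name}: response_kind must be one of {_RESPONSE_KINDS}"
            )

    @property
    def base_speed(self) -> float:
        """Wave speed at zero pressure factor, m/s."""
        return math.sqrt(
            self.wall_thickness
            * self.youngs_modulus
            / (2.0 * self.fluid_density * self.diameter)
        )


@dataclass(frozen=True)
class ArterialTree:
    """The three analyzed arterial paths: arm (x1), thoracic aorta (x2),
    abdominal aorta (x3)."""

    arm: ArterialSegment
    thoracic: ArterialSegment
    abdominal: ArterialSegment

    def __post_init__(self) -> None:
        expected = {"arm": "arm_x1", "thoracic": "thoracic_x2", "abdominal": "abdominal_x3"}
        for attr, name in expected.items():
            seg = getattr(self, attr)
            if seg.name != name:
                raise InvalidParameterError(
                    f"tree.{attr} must be the {name} segment, got {seg.name!r}"
                )


@dataclass(frozen=True)
class ReflectionCoefficients:
    """Reflection/transmission coefficients of the two central sites and
    the arm-entry junction.

    ``r2`` (renal) is pressure dependent; it is evaluated at systole via
    :func:`renal_reflection_coefficient` as an affine function of systolic
    pressure clamped to (0, 1).
    """

    r1: float = 0.10
    r2_at_ref: float = 0.17
    r2_slope: float = 0.002  # 1/mmHg
    r2_ref_systole: float = 120.0
    r3: float = 0.40

    def __post_init__(self) -> None:
        if not 0.0 <= self.r1 < 1.0:
            raise InvalidParameterError("r1 must lie in [0, 1)")
        if not 0.0 < self.r2_at_ref < 1.0:
            raise InvalidParameterError("r2_at_ref must lie in (0, 1)")
        if not 0.0 < self.r3 < 1.0:
            raise InvalidParameterError("r3 must lie in (0, 1)")


@dataclass(frozen=True)
class PressureState:
    """Systolic/diastolic pressure pair, mmHg."""

    psyst: float
    pdiast: float

    def __post_init__(self) -> None:
        if not self.pdiast > 0:
            raise InvalidParameterError("pdiast must be > 0")
        if self.psyst < self.pdiast:
            raise InvalidParameterError("psyst must be >= pdiast")

    @property
    def pulse_pressure(self) -> float:
        return self.psyst - self.pdiast


@dataclass(frozen=True)
class ComponentPressures:
    """The pressures loading each leg of the three component-pulse paths."""

    p11: float
    p21: float
    p22: float
    p23: float
    p31: float
    p32: float
    p33: float
    p34: float
    p35: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("p11", "p21", "p22", "p23", "p31", "p32", "p33", "p34", "p35")}


@dataclass(frozen=True)
class ArrivalTimes:
    """Arrival times of the three component pulses at the periphery, seconds."""

    t1: float
    t2: float
    t3: float

    @property
    def t12(self) -> float:
        return self.t2 - self.t1

    @property
    def t13(self) -> float:
        return self.t3 - self.t1

    @property
    def t12_ms(self) -> float:
        return 1e3 * self.t12

    @property
    def t13_ms(self) -> float:
        return 1e3 * self.t13


def wave_speed(segment: ArterialSegment, pressure: float) -> float:
    """Pressure-dependent pulse wave speed of ``segment``, m/s.

    Exponential segments evaluate the Moens-Korteweg relation directly;
    linear segments use its first-order expansion about the segment's
    linearization pressure.  Strictly increasing in pressure whenever the
    compliance exponent is positive.
    """
    lo, hi = PRESSURE_RANGE
    if not lo <= pressure <= hi:
        raise InvalidParameterError(
            f"pressure {pressure:.6g} mmHg outside [{lo:g}, {hi:g}]"
        )
    zeta = segment.compliance_exponent
    if segment.response_kind == "exponential":
        return segment.base_speed * math.exp(0.5 * zeta * pressure)
    p0 = segment.linearization_pressure
    v0 = segment.base_speed * math.exp(0.5 * zeta * p0)
    v = v0 * (1.0 + 0.5 * zeta * (pressure - p0))
    if v <= 0:
        raise ModelInconsistencyError(
            f"{segment.name}: linearized wave speed non-positive at {pressure:g} mmHg"
        )
    return v


def renal_reflection_coefficient(
    psyst: float, coeffs: ReflectionCoefficients, *, eps: float = 1e-6
) -> float:
    """Evaluate the systole-dependent renal reflection coefficient R2.

    Affine in systolic pressure about the reference systole, clamped to
    (0, 1): ``R2 = clamp(r2_at_ref + r2_slope * (psyst - ref), eps, 1-eps)``.
    """
    if not 60.0 <= psyst <= 250.0:
        raise InvalidParameterError(f"psyst {psyst:.6g} mmHg outside [60, 250]")
    r2 = coeffs.r2_at_ref + coeffs.r2_slope * (psyst - coeffs.r2_ref_systole)
    return min(max(r2, eps), 1.0 - eps)


def component_pressures(
    state: PressureState, coeffs: ReflectionCoefficients
) -> ComponentPressures:
    """Pressures loading the path legs of the three component pulses.

    The renal coefficient is evaluated at ``state.psyst``.  Every output
    must lie in [diastole, systole]; a violation raises
    :class:`ModelInconsistencyError` naming the offending term.
    """
    pp = state.pulse_pressure
    r1 = coeffs.r1
    r2 = renal_reflection_coefficient(state.psyst, coeffs)
    r3 = coeffs.r3
    cp = ComponentPressures(
        p11=state.psyst - r1 * pp,
        p21=state.psyst,
        p22=state.pdiast + r2 * pp,
        p23=state.pdiast + r2 * (1.0 - r1) * pp,
        p31=state.psyst,
        p32=state.psyst - r2 * pp,
        p33=state.pdiast + r3 * (1.0 - r2) * pp,
        p34=state.pdiast + r3 * (1.0 - r2) * (1.0 - r2) * pp,
        p35=state.pdiast + r3 * (1.0 - r2) * (1.0 - r2) * (1.0 - r1) * pp,
    )
    slack = 1e-9 * max(1.0, state.psyst)
    for term, value in cp.as_dict().items():
        if not (state.pdiast - slack <= value <= state.psyst + slack):
            raise ModelInconsistencyError(
                f"component pressure {term.upper()} = {value:.6g} mmHg outside "
                f"[{state.pdiast:g}, {state.psyst:g}]"
            )
    return cp


def arrival_times(
    state: PressureState,
    tree: ArterialTree,
    coeffs: ReflectionCoefficients,
) -> ArrivalTimes:
    """Arrival times of the primary, renal and iliac component pulses.

    Each leg contributes path-length / wave-speed at the pressure loading
    that leg.  The final leg of the renal path runs through the arm
    arteries and uses the arm segment's velocity function.  Raises
    :class:`ModelInconsistencyError` if the ordering t1 < t2 < t3 fails.
    """
    cp = component_pressures(state, coeffs)
    arm, tho, abd = tree.arm, tree.thoracic, tree.abdominal
    x1, x2, x3 = arm.length, tho.length, abd.length

    t1 = x1 / wave_speed(arm, cp.p11)
    t2 = (
        x2 / wave_speed(tho, cp.p21)
        + x2 / wave_speed(tho, cp.p22)
        + x1 / wave_speed(arm, cp.p23)
    )
    t3 = (
        x2 / wave_speed(tho, cp.p31)
        + x3 / wave_speed(abd, cp.p32)
        + x3 / wave_speed(abd, cp.p33)
        + x2 / wave_speed(tho, cp.p34)
        + x1 / wave_speed(arm, cp.p35)
    )
    if not t1 < t2 < t3:
        raise ModelInconsistencyError(
            f"arrival times not ordered: t1={t1:.6g}, t2={t2:.6g}, t3={t3:.6g} s"
        )
    return ArrivalTimes(t1=t1, t2=t2, t3=t3)


def t13_pressure_curve(
    diastole_grid: Sequence[float],
    systole: float,
    tree: ArterialTree,
    coeffs: ReflectionCoefficients,
) -> np.ndarray:
    """T13 (ms) as a function of diastolic pressure at fixed systole.

    Returns an array of shape (n, 2): columns (diastole mmHg, T13 ms).
    The grid must lie within [40, systole - 10] mmHg.  Under the default
    calibration (exponential arm, linear central segments) T13 decreases
    as diastole rises toward systole.
    """
    grid = np.asarray(list(diastole_grid), dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("diastole grid is empty")
    if grid.min() < 40.0 or grid.max() > systole - 10.0:
        raise InvalidParameterError(
            f"diastole grid must lie within [40, {systole - 10:g}] mmHg"
        )
    out = np.empty((grid.size, 2))
    for i, pd in enumerate(grid):
        at = arrival_times(PressureState(psyst=systole, pdiast=float(pd)), tree, coeffs)
        out[i] = (pd, at.t13_ms)
    return out


def reflection_attenuation(coefficients: Iterable[float]) -> float:
    """Relative amplitude of a pulse after sequential reflections.

    Each reflection multiplies the amplitude by its coefficient, so a
    twice-reflected pulse with coefficient r retains r**2 of the primary
    amplitude.
    """
    amp = 1.0
    for r in coefficients:
        if not 0.0 <= r <= 1.0:
            raise InvalidParameterError(f"reflection coefficient {r!r} outside [0, 1]")
        amp *= r
    return amp


# --- default calibration -------------------------------------------------
#
# Segment lengths approximate an average-height adult (arm path 0.80 m,
# thoracic aorta 0.28 m, abdominal aorta 0.25 m).  Elastic moduli are
# chosen so that the thoracic aorta propagates at 4.5 m/s at 80 mmHg (the
# softest, slowest artery), the abdominal aorta at 6 m/s at 90 mmHg, and
# the arm complex at 9 m/s at 120 mmHg.  The arm responds exponentially
# to pressure while the central segments use the linearized response;
# this contrast is what gives T13 its pressure sensitivity in the
# examined regime.

def default_tree() -> ArterialTree:
    """Shipped default arterial calibration."""
    return ArterialTree(
        arm=ArterialSegment(
            name="arm_x1",
            length=0.80,
            youngs_modulus=2.8947e5,
            wall_thickness=0.9e-3,
            diameter=4.0e-3,
            compliance_exponent=0.008,
            response_kind="exponential",
        ),
        thoracic=ArterialSegment(
            name="thoracic_x2",
            length=0.28,
            youngs_modulus=3.7433e5,
            wall_thickness=1.2e-3,
            diameter=2.0e-2,
            compliance_exponent=0.008,
            response_kind="linear",
            linearization_pressure=90.0,
        ),
        abdominal=ArterialSegment(
            name="abdominal_x3",
            length=0.25,
            youngs_modulus=5.0180e5,
            wall_thickness=1.1e-3,
            diameter=1.5e-2,
            compliance_exponent=0.008,
            response_kind="linear",
            linearization_pressure=90.0,
        ),
    )


def default_coefficients() -> ReflectionCoefficients:
    """Shipped default reflection coefficients (R2 = 0.17 at 120 mmHg,
    R3 = 0.40)."""
    return ReflectionCoefficients()


def with_constant_speeds(tree: ArterialTree, speed: float) -> ArterialTree:
    """Return a copy of ``tree`` whose segments all propagate at a fixed,
    pressure-independent ``speed`` (m/s).  Useful as a closed-form oracle."""
    if speed <= 0:
        raise InvalidParameterError("speed must be > 0")

    def flat(seg: ArterialSegment) -> ArterialSegment:
        # pick E so that base_speed == speed, zero compliance exponent
        e = speed**2 * 2.0 * seg.fluid_density * seg.diameter / seg.wall_thickness
        return replace(
            seg, youngs_modulus=e, compliance_exponent=0.0, response_kind="exponential"
        )

    return ArterialTree(arm=flat(tree.arm), thoracic=flat(tree.thoracic), abdominal=flat(tree.abdominal))
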