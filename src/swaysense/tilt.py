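"""Tilt estimation from 3-axis acceleration.

A chest-worn accelerometer at rest measures only gravity, so the direction
of the measured acceleration vector encodes the device's inclination.  Two
families of formulas are implemented:

* the *triple-axis* forms — an X–Y plane angle ``theta = arctan(ax/ay)``
  and the angle from gravity ``phi = arccos(az/|a|)``; and
* *independent inclination sensing* — per-axis angles computed from each
  component against the quadrature sum of the other two,

      theta = arctan( ax / sqrt(ay² + az²) )   # X-axis inclination
      psi   = arctan( ay / sqrt(ax² + az²) )   # Y-axis inclination
      phi   = arctan( sqrt(ax² + ay²) / az )   # angle from the Z axis

The plain arctangent confines these angles to (−90°, 90°]; combining them
with the signs of the acceleration components (two-argument arctangent
semantics) extends the range to a full 360° so that inverted orientations
are distinguishable.  The pipeline computes tilt at 25 Hz by decimating the
50 Hz acceleration stream and applying the independent-inclination formulas
with quadrant resolution to each retained sample.

All angles are in degrees.  An exactly zero acceleration vector has no
defined orientation (free fall) and raises
:class:`~swaysense.errors.UndefinedOrientationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    SamplingError,
    UndefinedOrientationError,
    ValidationError,
)

#: Accelerometer full scale in G (±8 G sensor configuration).
FULL_SCALE_G = 8.0

#: Nominal sampling rate of the acceleration stream (Hz).
DEFAULT_SAMPLE_RATE_HZ = 50.0

#: Rate at which tilt angles are computed (Hz).
DEFAULT_TILT_RATE_HZ = 25.0

#: Relative tolerance on timestamp spacing before a series is rejected.
DEFAULT_TIMING_RTOL = 0.01


@dataclass(frozen=True)
class AccelerationSample:
    """One 3-axis acceleration measurement in G."""

    ax: float
    ay: float
    az: float
    t: float = 0.0

    def __post_init__(self) -> None:
        comps = (self.ax, self.ay, self.az)
        if not all(np.isfinite(comps)):
            raise ValidationError(f"non-finite acceleration sample {comps}")
        if any(abs(c) > FULL_SCALE_G for c in comps):
            raise ValidationError(
                f"acceleration {comps} exceeds the ±{FULL_SCALE_G:g} G full scale"
            )

    @property
    def norm(self) -> float:
        return float(np.sqrt(self.ax**2 + self.ay**2 + self.az**2))


@dataclass(frozen=True)
class TiltAngles:
    """Inclination angles (degrees) of the X, Y and Z axes.

    ``theta`` and ``psi`` are the inclinations of the device X and Y axes;
    ``phi`` is the angle between the device Z axis and gravity.  When
    ``quadrant_resolved`` is False the angles come straight from the plain
    arctangent forms (theta, psi in [−90, 90], phi in [0, 180]); when True
    they have been extended to (−180, 180] using the component signs.
    """

    theta: float
    psi: float
    phi: float
    quadrant_resolved: bool = False


@dataclass
class AccelSeries:
    """A regularly sampled 3-axis acceleration time series (G)."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = self.t.size
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise ValidationError("acceleration series columns differ in length")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def components(self) -> np.ndarray:
        """(n, 3) array of [ax, ay, az]."""
        return np.column_stack([self.ax, self.ay, self.az])

    @property
    def duration(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    def sample_rate(self) -> float:
        """Median sampling rate inferred from the timestamps."""
        if len(self) < 2:
            raise ValidationError("cannot infer a rate from fewer than 2 samples")
        dt = float(np.median(np.diff(self.t)))
        if dt <= 0:
            raise SamplingError("non-increasing timestamps")
        return 1.0 / dt


@dataclass
class TiltSeries:
    """Per-sample tilt angles in degrees, quadrant-resolved."""

    t: np.ndarray
    theta: np.ndarray
    psi: np.ndarray
    phi: np.ndarray
    rate: float = field(default=DEFAULT_TILT_RATE_HZ)

    def __len__(self) -> int:
        return int(np.asarray(self.t).size)


def _require_nonzero(ax: float, ay: float, az: float) -> None:
    if ax == 0.0 and ay == 0.0 and az == 0.0:
        raise UndefinedOrientationError(
            "zero acceleration vector: orientation undefined (free fall)"
        )


def _atan_deg(num: float, den: float) -> float:
    """arctan(num/den) in degrees with the signed ±90° limit at den = 0.

    Written via arctan2 on (num·sign(den), |den|) so a subnormal
    denominator cannot overflow the quotient; the branch is the plain
    arctan's (−90°, 90°).
    """
    if den == 0.0:
        return float(np.sign(num)) * 90.0
    return float(np.degrees(np.arctan2(num * np.sign(den), abs(den))))


def triple_axis_theta(sample: AccelerationSample) -> float:
    """X–Y plane tilt, ``arctan(ax / ay)`` in degrees.

    This is the printed triple-axis form; note its denominator is the Y
    component alone, not the conventional quadrature sum (for which see
    :func:`independent_inclination`).  The pipeline does not use it.
    """
    _require_nonzero(sample.ax, sample.ay, sample.az)
    return _atan_deg(sample.ax, sample.ay)


def triple_axis_phi(sample: AccelerationSample) -> float:
    """Angle between gravity and the Z axis, ``arccos(az/|a|)`` in [0°, 180°]."""
    _require_nonzero(sample.ax, sample.ay, sample.az)
    return float(np.degrees(np.arccos(np.clip(sample.az / sample.norm, -1.0, 1.0))))


def independent_inclination(sample: AccelerationSample) -> TiltAngles:
    """Per-axis inclination angles from the independent-sensing formulas.

    Returns plain-arctangent angles (``quadrant_resolved=False``); zero
    denominators yield the signed ±90° limit.
    """
    ax, ay, az = sample.ax, sample.ay, sample.az
    _require_nonzero(ax, ay, az)
    theta = _atan_deg(ax, float(np.hypot(ay, az)))
    psi = _atan_deg(ay, float(np.hypot(ax, az)))
    phi = _atan_deg(float(np.hypot(ax, ay)), az)
    return TiltAngles(theta=theta, psi=psi, phi=phi, quadrant_resolved=False)


def resolve_quadrant(angles: TiltAngles, sample: AccelerationSample) -> TiltAngles:
    """Extend tilt angles to the full (−180°, 180°] range.

    The plain arctangent cannot distinguish an orientation from its mirror
    through the X–Y plane.  Using two-argument arctangent semantics on each
    plane projection — the numerator keeps its sign, the quadrature-sum
    denominator takes the sign of ``az`` — places each angle in the quadrant
    dictated by the component signs.  ``phi`` becomes ``atan2(hypot(ax, ay),
    az)`` in [0°, 180°], so an inverted device reads phi = 180°.

    Idempotent: the result depends only on ``sample``.
    """
    ax, ay, az = sample.ax, sample.ay, sample.az
    _require_nonzero(ax, ay, az)
    hemi = 1.0 if az >= 0 else -1.0
    theta = float(np.degrees(np.arctan2(ax, hemi * np.hypot(ay, az))))
    psi = float(np.degrees(np.arctan2(ay, hemi * np.hypot(ax, az))))
    phi = float(np.degrees(np.arctan2(np.hypot(ax, ay), az)))
    # atan2(-0.0, x<0) yields exactly −180°; fold onto the +180° branch
    theta = 180.0 if theta == -180.0 else theta
    psi = 180.0 if psi == -180.0 else psi
    return TiltAngles(theta=theta, psi=psi, phi=phi, quadrant_resolved=True)


def _resolved_angles_vec(
    ax: np.ndarray, ay: np.ndarray, az: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized independent inclination + quadrant resolution (degrees)."""
    if np.any((ax == 0) & (ay == 0) & (az == 0)):
        raise UndefinedOrientationError(
            "series contains an exactly zero acceleration vector"
        )
    hemi = np.where(az >= 0, 1.0, -1.0)
    theta = np.degrees(np.arctan2(ax, hemi * np.hypot(ay, az)))
    psi = np.degrees(np.arctan2(ay, hemi * np.hypot(ax, az)))
    phi = np.degrees(np.arctan2(np.hypot(ax, ay), az))
    theta[theta == -180.0] = 180.0
    psi[psi == -180.0] = 180.0
    return theta, psi, phi


def check_regular_sampling(
    t: np.ndarray, rate: float, rtol: float = DEFAULT_TIMING_RTOL
) -> None:
    """Raise :class:`SamplingError` unless timestamps are evenly spaced at ``rate``."""
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        return
    dt = np.diff(t)
    expected = 1.0 / rate
    if np.any(dt <= 0):
        raise SamplingError("timestamps are not strictly increasing")
    worst = float(np.max(np.abs(dt - expected)))
    if worst > rtol * expected:
        raise SamplingError(
            f"irregular sampling: max interval deviation {worst:.3g} s exceeds "
            f"{rtol:.0%} of the nominal {expected:.3g} s step"
        )


def tilt_series(
    series: AccelSeries,
    tilt_rate: float = DEFAULT_TILT_RATE_HZ,
    sample_rate: float | None = None,
    timing_rtol: float = DEFAULT_TIMING_RTOL,
) -> TiltSeries:
    """Compute quadrant-resolved tilt angles at ``tilt_rate`` from a 50 Hz stream.

    The acceleration stream is decimated by keeping every ``rate/tilt_rate``-th
    sample (no anti-alias filtering) and the independent-inclination formulas
    plus quadrant resolution are applied to each retained sample.

    Parameters
    ----------
    series
        Regularly sampled acceleration series.
    tilt_rate
        Output rate in Hz; must divide the sampling rate.
    sample_rate
        Nominal input rate; inferred from timestamps when omitted.
    timing_rtol
        Allowed relative deviation of timestamp spacing.
    """
    if len(series) < 2:
        raise ValidationError("tilt_series needs at least 2 samples")
    rate = sample_rate if sample_rate is not None else series.sample_rate()
    check_regular_sampling(series.t, rate, rtol=timing_rtol)
    if tilt_rate <= 0:
        raise ConfigError("tilt_rate must be positive")
    factor = rate / tilt_rate
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ConfigError(
            f"tilt rate {tilt_rate:g} Hz does not divide the sampling rate {rate:g} Hz"
        )
    step = int(round(factor))
    t = series.t[::step]
    theta, psi, phi = _resolved_angles_vec(
        series.ax[::step], series.ay[::step], series.az[::step]
    )
    return TiltSeries(t=t, theta=theta, psi=psi, phi=phi, rate=tilt_rate)
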