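"""Standardised-kinematics bench: oscillating-bar simulation.

Emulates an industrial robot joint rotating a bar of accelerometers in
the vertical plane.  The joint sweeps between two angles following a
minimum-jerk 7th-order polynomial (zero velocity, acceleration and jerk
at both sweep ends, suppressing structural vibration), oscillating
continuously at a set frequency.  For a sensor at radius ``r`` from the
rotation axis, the movement-related acceleration is the vector sum of
the tangential component ``r * theta_dotdot`` and the centripetal
component ``r * theta_dot**2``; its magnitude is the forward-kinematics
reference every metric is judged against.

The simulated sensor signal adds the gravity projection to the two
in-plane axes.  With the bar angle ``theta`` measured from horizontal
(90 deg = bar pointing up):

* axis 1 (perpendicular to the bar, in the rotation plane) carries the
  tangential acceleration plus ``cos(theta)`` of gravity;
* axis 2 (parallel to the bar, pointing away from the axis) carries the
  centripetal acceleration opposing ``sin(theta)`` of gravity;
* axis 3 (along the rotation axis) carries nothing but noise.

Signs are fixed so a static sensor reads a unit-magnitude gravity
vector.  A whole-axis flip is invisible to every norm-based metric, but
the relative sign of the centripetal term and the gravity projection on
the parallel axis is not: the proof mass is flung outward while gravity
(for a bar above horizontal) pulls the reading positive, so the terms
oppose, which is what pulls LFEN below 1 g during vertical-plane
rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .recording import TriaxialRecording

__all__ = [
    "GRAVITY_M_S2",
    "SENSOR_NOISE_SD_G",
    "OscillationCondition",
    "TrajectoryKinematics",
    "SimulatedSensor",
    "minimum_jerk_sweep",
    "generate_trajectory",
    "static_trajectory",
    "reference_acceleration",
    "simulate_sensor",
    "condition_grid",
    "long_bar_radii",
    "short_bar_radii",
]

GRAVITY_M_S2 = 9.81
#: sensor noise floor of the device being emulated (2.6 mg per axis)
SENSOR_NOISE_SD_G = 0.0026

DEFAULT_FS = 80.0
DEFAULT_DURATION_S = 180.0

# Minimum-jerk unit sweep: the unique degree-7 polynomial s on [0, 1]
# with s(0)=0, s(1)=1 and zero 1st-3rd derivatives at both ends.
_SWEEP_COEF = np.array([35.0, -84.0, 70.0, -20.0])  # tau^4 .. tau^7


def minimum_jerk_sweep(tau: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized sweep position, velocity and acceleration on tau in [0, 1].

    Returns ``(s, ds, d2s)`` where ``s(tau) = 35 tau^4 - 84 tau^5 +
    70 tau^6 - 20 tau^7`` and the derivatives are analytic.
    """
    tau = np.asarray(tau, dtype=float)
    s = tau**4 * (35.0 + tau * (-84.0 + tau * (70.0 - 20.0 * tau)))
    ds = tau**3 * (140.0 + tau * (-420.0 + tau * (420.0 - 140.0 * tau)))
    d2s = tau**2 * (420.0 + tau * (-1680.0 + tau * (2100.0 - 840.0 * tau)))
    return s, ds, d2s


@dataclass(frozen=True)
class OscillationCondition:
    """One bench condition: frequency, angular range, sensor radii."""

    frequency_hz: float
    angle_min_deg: float
    angle_max_deg: float
    radii_m: Tuple[float, ...]
    duration_s: float = DEFAULT_DURATION_S
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if self.frequency_hz < 0:
            raise ValueError("frequency must be >= 0 (0 = static)")
        if self.frequency_hz > 0 and not self.angle_min_deg < self.angle_max_deg:
            raise ValueError("moving condition needs angle_min < angle_max")
        radii = tuple(float(r) for r in self.radii_m)
        if not radii or any(not 0 < r <= 1 for r in radii):
            raise ValueError("radii must lie in (0, 1] m")
        object.__setattr__(self, "radii_m", radii)
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")

    @property
    def is_static(self) -> bool:
        return self.frequency_hz == 0


@dataclass(frozen=True)
class TrajectoryKinematics:
    """Joint angle and its exact analytic derivatives on a sample grid."""

    t: np.ndarray
    theta: np.ndarray  # rad
    omega: np.ndarray  # rad/s
    alpha: np.ndarray  # rad/s^2
    fs: float


@dataclass(frozen=True)
class SimulatedSensor:
    """One simulated accelerometer on the bar."""

    radius_m: float
    recording: TriaxialRecording
    noise_sd_g: float = 0.0


def generate_trajectory(cond: OscillationCondition) -> TrajectoryKinematics:
    """Continuous oscillation between the condition's angle bounds.

    One full period (up sweep + down sweep) lasts ``1 / frequency_hz``;
    each half-period is a minimum-jerk polynomial sweep, so angle,
    velocity, acceleration and jerk are continuous across sweep
    boundaries.
    """
    if cond.is_static:
        raise ValueError("use static_trajectory for a 0 Hz condition")
    f = cond.frequency_hz
    n = int(round(cond.duration_s * cond.fs))
    t = np.arange(n) / cond.fs
    lo = np.deg2rad(cond.angle_min_deg)
    hi = np.deg2rad(cond.angle_max_deg)
    span = hi - lo
    half = 0.5 / f  # duration of one sweep

    phase = np.mod(t * f, 1.0)
    going_up = phase < 0.5
    tau = np.where(going_up, phase * 2.0, (phase - 0.5) * 2.0)
    s, ds, d2s = minimum_jerk_sweep(tau)
    sign = np.where(going_up, 1.0, -1.0)

    theta = np.where(going_up, lo + span * s, hi - span * s)
    omega = sign * span * ds / half
    alpha = sign * span * d2s / half**2
    return TrajectoryKinematics(t=t, theta=theta, omega=omega, alpha=alpha, fs=cond.fs)


def static_trajectory(
    angle_deg: float, duration_s: float = DEFAULT_DURATION_S, fs: float = DEFAULT_FS
) -> TrajectoryKinematics:
    """Bar held at a constant angle; zero velocity and acceleration."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    theta = np.full(n, np.deg2rad(angle_deg))
    zeros = np.zeros(n)
    return TrajectoryKinematics(t=t, theta=theta, omega=zeros, alpha=zeros.copy(), fs=fs)


def reference_acceleration(traj: TrajectoryKinematics, radius_m: float) -> np.ndarray:
    """Movement acceleration magnitude at radius ``radius_m``, in g.

    Vector magnitude of the tangential (``r * alpha``) and centripetal
    (``r * omega**2``) components.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    return np.hypot(radius_m * traj.alpha, radius_m * traj.omega**2) / GRAVITY_M_S2


def simulate_sensor(
    traj: TrajectoryKinematics,
    radius_m: float,
    noise_sd_g: float = 0.0,
    seed: Optional[object] = None,
) -> SimulatedSensor:
    """Synthesize the tri-axial signal of a sensor at ``radius_m``.

    ``seed`` (any ``numpy`` seed-like, e.g. int or SeedSequence) is
    mandatory whenever ``noise_sd_g > 0`` so that noisy simulations are
    reproducible by construction.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    # Specific force measured by the sensor: gravity reaction plus movement.
    # The centripetal acceleration points toward the axis while the outward
    # parallel axis reads +sin(theta) of gravity when the bar is above
    # horizontal, so the two in-plane terms on that axis oppose each other;
    # this relative sign is observable in every norm-based metric (only a
    # whole-axis flip is not) and drives LFEN below 1 g during rotation.
    perp = radius_m * traj.alpha / GRAVITY_M_S2 + np.cos(traj.theta)
    para = np.sin(traj.theta) - radius_m * traj.omega**2 / GRAVITY_M_S2
    axial = np.zeros_like(perp)
    data = np.column_stack([perp, para, axial])
    if noise_sd_g > 0:
        if seed is None:
            raise ValueError("a seed is required for noisy simulation")
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd_g, size=data.shape)
    rec = TriaxialRecording(fs=traj.fs, data=data)
    return SimulatedSensor(radius_m=radius_m, recording=rec, noise_sd_g=noise_sd_g)


def long_bar_radii(n: int = 18, lo: float = 0.13, hi: float = 0.78) -> Tuple[float, ...]:
    """Evenly spaced sensor positions on the 70 cm bar (default 18)."""
    return tuple(np.linspace(lo, hi, n))


def short_bar_radii(n: int = 5, lo: float = 0.13, hi: float = 0.29) -> Tuple[float, ...]:
    """Evenly spaced sensor positions on the 20 cm bar (default 5)."""
    return tuple(np.linspace(lo, hi, n))


def condition_grid(
    duration_s: float = DEFAULT_DURATION_S, fs: float = DEFAULT_FS, include_static: bool = True
) -> list[OscillationCondition]:
    """The full bench grid: 37 moving frequencies plus two static holds.

    Moving rows: 0.05-0.55 Hz in 0.05 steps over 0-90 deg (long bar);
    0.6/0.7/0.8 Hz over 0-45 deg (long bar); 0.9/1.0/1.1 Hz over
    0-20 deg (long bar); 1.2/1.3 Hz over 0-45 deg (short bar);
    1.4-2.6 Hz in 0.1 steps plus 2.8, 3.0, 3.2, 3.6, 4.0 Hz over
    0-20 deg (short bar).  Static rows: 0 deg and 22.5 deg holds with
    the long bar.
    """
    long_r = long_bar_radii()
    short_r = short_bar_radii()
    conds: list[OscillationCondition] = []

    def add(freqs, a_min, a_max, radii):
        for f in freqs:
            conds.append(
                OscillationCondition(
                    frequency_hz=float(round(f, 10)),
                    angle_min_deg=a_min,
                    angle_max_deg=a_max,
                    radii_m=radii,
                    duration_s=duration_s,
                    fs=fs,
                )
            )

    if include_static:
        for angle in (0.0, 22.5):
            conds.append(
                OscillationCondition(
                    frequency_hz=0.0,
                    angle_min_deg=angle,
                    angle_max_deg=angle,
                    radii_m=long_r,
                    duration_s=duration_s,
                    fs=fs,
                )
            )
    add(np.round(np.arange(0.05, 0.551, 0.05), 10), 0.0, 90.0, long_r)
    add((0.6, 0.7, 0.8), 0.0, 45.0, long_r)
    add((0.9, 1.0, 1.1), 0.0, 20.0, long_r)
    add((1.2, 1.3), 0.0, 45.0, short_r)
    add(
        tuple(np.round(np.arange(1.4, 2.601, 0.1), 10)) + (2.8, 3.0, 3.2, 3.6, 4.0),
        0.0,
        20.0,
        short_r,
    )
    return conds


def mini_condition_grid(
    duration_s: float = DEFAULT_DURATION_S, fs: float = DEFAULT_FS
) -> list[OscillationCondition]:
    """A reduced grid for smoke tests: one condition per regime, 3 radii."""
    r3_long = tuple(np.linspace(0.13, 0.78, 3))
    r3_short = tuple(np.linspace(0.13, 0.29, 3))
    return [
        OscillationCondition(0.0, 22.5, 22.5, r3_long, duration_s, fs),
        OscillationCondition(0.1, 0.0, 90.0, r3_long, duration_s, fs),
        OscillationCondition(0.7, 0.0, 45.0, r3_long, duration_s, fs),
        OscillationCondition(1.0, 0.0, 20.0, r3_long, duration_s, fs),
        OscillationCondition(2.0, 0.0, 20.0, r3_short, duration_s, fs),
    ]
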