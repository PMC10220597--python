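"""Eye-movement trajectory generation and motion-platform telemetry.

Movements are programmed as ordered segments — a signed angular jump
executed over a fixed duration, followed by a fixation pause — exactly as
the rotation stage is driven. Three classes of human eye movement are
shipped as presets: smooth pursuit (slow 20° tracking legs), scene
saccades (fast 4° jumps with ~330 ms fixations) and fixational
micro-saccades (~0.55° in 14 ms repeating every 1.25 s).

The within-segment velocity profile is configurable because the stage
controller's internal profile is not part of the motion program:

* ``rectangular`` — constant velocity, peak/mean = 1;
* ``triangular``  — linear ramp up then down, peak/mean = 2;
* ``minimum_jerk`` — the classic smooth point-to-point profile
  θ(τ) = Δ(10τ³ − 15τ⁴ + 6τ⁵), peak/mean = 1.875.

All profiles integrate exactly to the programmed displacement, so net
travel is profile-independent. The module also synthesises accelerometer
telemetry (tangential acceleration at the mount radius, resampled to the
acquisition chain's 6.4 kHz) and probe temperature traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import constants as c
from .errors import InvalidParameterError, ResolutionError
from .telemetry_io import child_rng

Profile = Literal["rectangular", "triangular", "minimum_jerk"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class MotionSegment:
    """One programmed move: signed angle over a duration, then a hold."""

    delta_angle: float    # degrees, signed
    move_duration: float  # s
    pause_after: float = 0.0  # s

    def __post_init__(self):
        if self.delta_angle != 0 and not self.move_duration > 0:
            raise InvalidParameterError(
                "move_duration must be > 0 for a non-zero move"
            )
        if self.pause_after < 0:
            raise InvalidParameterError("pause_after must be >= 0")


@dataclass(frozen=True)
class MotionProgram:
    """A named sequence of segments with a velocity profile."""

    name: str
    segments: tuple[MotionSegment, ...]
    profile: Profile = "triangular"
    repeat_count: int = 1
    sample_rate: float = 2000.0  # Hz

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.repeat_count < 1:
            raise InvalidParameterError("repeat_count must be >= 1")
        moves = [s.move_duration for s in self.segments if s.delta_angle != 0]
        if moves and self.sample_rate < 2.0 / min(moves):
            raise ResolutionError(
                f"sample rate {self.sample_rate} Hz cannot resolve the "
                f"shortest move ({min(moves) * 1e3:.3g} ms)"
            )

    @property
    def duration(self) -> float:
        once = sum(s.move_duration + s.pause_after for s in self.segments)
        return once * self.repeat_count

    def net_displacement(self) -> float:
        """Arithmetic sum of programmed deltas over all repeats, degrees."""
        return sum(s.delta_angle for s in self.segments) * self.repeat_count


@dataclass
class Trajectory:
    """Sampled angle/velocity/acceleration series."""

    time: np.ndarray       # s
    angle: np.ndarray      # degrees
    velocity: np.ndarray   # degrees/s
    acceleration: np.ndarray  # degrees/s²
    program: MotionProgram | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "angle_deg": self.angle,
                "velocity_deg_s": self.velocity,
                "acceleration_deg_s2": self.acceleration,
            }
        )


@dataclass(frozen=True)
class TelemetryChannelSpec:
    """Accelerometer or temperature channel configuration."""

    kind: Literal["accelerometer", "temperature"]
    sample_rate: float = 0.0   # 0 -> platform default for the kind
    noise_sigma: float = 0.0
    mount_radius: float = c.DEFAULT_MOUNT_RADIUS_M  # m, accelerometer
    setpoint: float = 37.0                          # °C, temperature

    def __post_init__(self):
        if self.sample_rate == 0.0:
            default = (c.ACCELEROMETER_RATE_HZ if self.kind == "accelerometer"
                       else c.TEMPERATURE_RATE_HZ)
            object.__setattr__(self, "sample_rate", default)
        if self.kind == "accelerometer" and not self.mount_radius > 0:
            raise InvalidParameterError("mount_radius must be > 0")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise sigma must be >= 0")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------
def _load_presets() -> dict:
    with resources.files("pkeye.data").joinpath("motion_presets.json").open() as fh:
        return json.load(fh)


def load_preset(name: str, profile: Profile | None = None,
                sample_rate: float | None = None) -> MotionProgram:
    """Load a shipped motion preset by name.

    Available: ``smooth_pursuit``, ``scene_saccades``, ``micro_saccades``
    (as executed on the stage) and their ``*_programmed`` variants (as
    originally commanded; the two differ slightly and both are preserved).
    """
    presets = _load_presets()
    spec = presets[name]
    segments = tuple(
        MotionSegment(s["delta_deg"], s["duration_s"], s["pause_s"])
        for s in spec["segments"]
    )
    return MotionProgram(
        name=name,
        segments=segments,
        profile=profile or spec["profile"],
        sample_rate=sample_rate or spec["sample_rate_hz"],
    )


def preset_names() -> list[str]:
    return sorted(_load_presets())


SMOOTH_PURSUIT = "smooth_pursuit"
SCENE_SACCADES = "scene_saccades"
MICRO_SACCADES = "micro_saccades"


# ---------------------------------------------------------------------------
# Velocity profiles (closed forms on normalised time tau in [0, 1])
# ---------------------------------------------------------------------------
def _profile_eval(profile: Profile, delta: float, T: float, tau: np.ndarray):
    """Angle offset, velocity and acceleration within one move."""
    if profile == "rectangular":
        theta = delta * tau
        vel = np.full_like(tau, delta / T)
        acc = np.zeros_like(tau)
    elif profile == "triangular":
        half = tau < 0.5
        theta = np.where(half, 2 * delta * tau**2,
                         delta - 2 * delta * (1 - tau) ** 2)
        vel = np.where(half, 4 * delta * tau / T, 4 * delta * (1 - tau) / T)
        acc = np.where(half, 4 * delta / T**2, -4 * delta / T**2)
    elif profile == "minimum_jerk":
        theta = delta * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
        vel = delta / T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
        acc = delta / T**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    else:
        raise InvalidParameterError(f"unknown profile {profile!r}")
    return theta, vel, acc


# ---------------------------------------------------------------------------
# Trajectory construction
# ---------------------------------------------------------------------------
def build_trajectory(program: MotionProgram) -> Trajectory:
    """Sample the program at its sample rate.

    The angle is continuous, pauses hold it constant, and within each move
    the profile integrates exactly to the programmed delta. An empty
    program yields a single sample at zero.
    """
    if not program.segments:
        z = np.zeros(1)
        return Trajectory(z, z.copy(), z.copy(), z.copy(), program)

    dt = 1.0 / program.sample_rate
    total = program.duration
    n = int(round(total / dt)) + 1
    time = np.arange(n) * dt
    angle = np.zeros(n)
    vel = np.zeros(n)
    acc = np.zeros(n)

    theta0 = 0.0
    t0 = 0.0
    for _ in range(program.repeat_count):
        for seg in program.segments:
            T = seg.move_duration
            if seg.delta_angle != 0 and T > 0:
                in_move = (time >= t0) & (time < t0 + T)
                tau = (time[in_move] - t0) / T
                th, v, a = _profile_eval(program.profile, seg.delta_angle, T, tau)
                angle[in_move] = theta0 + th
                vel[in_move] = v
                acc[in_move] = a
            theta0 += seg.delta_angle
            t0 += T
            if seg.pause_after > 0:
                in_pause = (time >= t0) & (time < t0 + seg.pause_after)
                angle[in_pause] = theta0
                t0 += seg.pause_after
    # samples at/after the program end hold the final angle
    angle[time >= t0 - 0.5 * dt] = theta0
    return Trajectory(time, angle, vel, acc, program)


def peak_velocity(trajectory: Trajectory) -> float:
    """Maximum |angular velocity| over the series, degrees/s."""
    if trajectory.time.size == 0:
        raise InvalidParameterError("empty trajectory")
    return float(np.max(np.abs(trajectory.velocity)))


def kinematic_summary(trajectory: Trajectory) -> dict:
    """Peak velocity, net displacement and displacement-consistency check."""
    net = float(trajectory.angle[-1] - trajectory.angle[0])
    integ = float(np.trapezoid(trajectory.velocity, trajectory.time))
    return {
        "peak_velocity_deg_s": peak_velocity(trajectory),
        "net_displacement_deg": net,
        "velocity_integral_deg": integ,
        "duration_s": float(trajectory.time[-1]),
    }


# ---------------------------------------------------------------------------
# Telemetry synthesis
# ---------------------------------------------------------------------------
def synth_accelerometer(
    trajectory: Trajectory,
    spec: TelemetryChannelSpec | None = None,
    seed: int = 0,
    include_centripetal: bool = False,
) -> pd.DataFrame:
    """Tangential accelerometer trace at the mount radius, m/s².

    The single-axis sensor reads a = r·α (α in rad/s²); the optional
    centripetal term r·ω² can be added for a radially oriented sensor.
    Output is resampled onto the accelerometer clock (6.4 kHz by default)
    with seeded Gaussian noise; the trace is identically zero during
    pauses (before noise).
    """
    spec = spec or TelemetryChannelSpec("accelerometer")
    if spec.kind != "accelerometer":
        raise InvalidParameterError("spec must be an accelerometer channel")
    duration = float(trajectory.time[-1]) if trajectory.time.size > 1 else 1.0
    n = int(round(duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    alpha = np.interp(t, trajectory.time, trajectory.acceleration)  # deg/s²
    a = spec.mount_radius * np.deg2rad(alpha)
    if include_centripetal:
        omega = np.interp(t, trajectory.time, trajectory.velocity)
        a = a + spec.mount_radius * np.deg2rad(omega) ** 2
    if spec.noise_sigma:
        a = a + child_rng(seed, "motion.accel").normal(0, spec.noise_sigma, n)
    return pd.DataFrame({"time_s": t, "acceleration_m_s2": a})


def synth_temperature(
    specs: Sequence[TelemetryChannelSpec] | None = None,
    duration: float = 3600.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-probe temperature traces at 1 Hz, Gaussian about the setpoint.

    Defaults emulate the two platform probes (35.3 ± 0.6 °C and
    34.0 ± 0.3 °C) heated by lamps around the models.
    """
    if duration < 1.0:
        raise InvalidParameterError("duration must be >= 1 s")
    if specs is None:
        specs = [
            TelemetryChannelSpec("temperature", setpoint=sp, noise_sigma=sg)
            for sp, sg in c.DEFAULT_TEMPERATURE_PROBES
        ]
    frames = []
    for i, spec in enumerate(specs):
        if spec.kind != "temperature":
            raise InvalidParameterError("specs must be temperature channels")
        n = int(round(duration * spec.sample_rate))
        t = np.arange(n) / spec.sample_rate
        rng = child_rng(seed, f"motion.temp.{i}")
        vals = spec.setpoint + (
            rng.normal(0, spec.noise_sigma, n) if spec.noise_sigma else 0.0
        )
        frames.append(
            pd.DataFrame(
                {"time_s": t, "probe": f"probe_{i + 1}", "temperature_degC": vals}
            )
        )
    return pd.concat(frames, ignore_index=True)
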