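"""Protocol-driven synthetic gait and cardiorespiratory data.

The generator emulates a field test on a level track: a subject rests,
then walks at two speeds and runs at two speeds (3 min per stage, standing
recovery in between, ~20 min total).  It produces

* a torso motion trace (speed, vertical position, vertical acceleration)
  at a configurable rate, with one vertical oscillation per step;
* breath-by-breath oxygen uptake sampled every 5 s and heart rate sampled
  at ~1 Hz, both driven by first-order on/off kinetics toward
  speed-dependent steady states;
* ground truth (true step boundaries, noiseless latent series, true
  inter-stream clock offsets) so every downstream stage can be tested
  without any real recording.

All randomness flows through explicit integer seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SubjectProfile",
    "ProtocolSegment",
    "ExerciseProtocol",
    "MotionTrace",
    "PhysioSeries",
    "SimulatedPhysiology",
    "SyncedStreams",
    "generate_protocol",
    "sample_subject",
    "simulate_steps",
    "vo2_steady_state",
    "simulate_physiology",
    "inject_sync_artifacts",
    "write_simulation",
    "read_motion_csv",
    "read_physio_csv",
]

#: speed (m/s) above which the generator treats locomotion as running
GAIT_TRANSITION_SPEED = 2.2

#: admissible locomotion speed range of the field protocol, m/s
SPEED_RANGE = (1.3, 3.5)


class ValidationError(ValueError):
    """A domain object violated one of its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    """Physiological parameters governing one simulated individual.

    Units: mass kg; V̇O2 values mL/min/kg; heart rates bpm; time constants s.
    ``cadence_base`` and ``preferred_cadence_slope`` define the linear
    cadence model ``step_frequency = base + slope * speed`` (steps/s).
    """

    body_mass: float = 78.3
    vo2_rest: float = 3.5
    vo2_peak: float = 52.0
    hr_rest: float = 58.0
    hr_max: float = 192.0
    tau_vo2_on: float = 35.0
    tau_vo2_off: float = 45.0
    tau_hr: float = 25.0
    cadence_base: float = 1.4
    preferred_cadence_slope: float = 0.45
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.body_mass > 0:
            raise ValidationError("body_mass must be positive")
        if not self.vo2_rest < self.vo2_peak:
            raise ValidationError("vo2_rest must be below vo2_peak")
        if not self.hr_rest < self.hr_max:
            raise ValidationError("hr_rest must be below hr_max")
        for name in ("tau_vo2_on", "tau_vo2_off", "tau_hr"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.step_frequency(SPEED_RANGE[0]) <= 0:
            raise ValidationError("cadence model must be positive over the protocol speeds")

    def step_frequency(self, speed: float) -> float:
        """Preferred cadence (steps/s) at a given locomotion speed."""
        return self.cadence_base + self.preferred_cadence_slope * speed


@dataclass(frozen=True)
class ProtocolSegment:
    label: Literal["rest", "walk", "run"]
    target_speed: float  # m/s, 0 for rest
    duration: float  # s

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValidationError(f"segment {self.label!r}: duration must be > 0")
        if self.label == "rest":
            if self.target_speed != 0:
                raise ValidationError("rest segment must have target_speed 0")
        else:
            lo, hi = SPEED_RANGE
            if not lo <= self.target_speed <= hi:
                raise ValidationError(
                    f"segment {self.label!r}: speed {self.target_speed} m/s outside "
                    f"[{lo}, {hi}] m/s"
                )


@dataclass(frozen=True)
class ExerciseProtocol:
    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("protocol needs at least one segment")
        if self.segments[0].label != "rest":
            raise ValidationError("protocol must start from rest")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def segment_bounds(self) -> list[tuple[float, float, ProtocolSegment]]:
        """(start, end, segment) triples in session time."""
        out, t = [], 0.0
        for seg in self.segments:
            out.append((t, t + seg.duration, seg))
            t += seg.duration
        return out

    def speed_at(self, t: float) -> tuple[float, str]:
        """Target speed and label at session time ``t`` (last segment wins at ties)."""
        for start, end, seg in self.segment_bounds():
            if start <= t < end:
                return seg.target_speed, seg.label
        last = self.segments[-1]
        return last.target_speed, last.label


def _check_monotone(time: np.ndarray, what: str) -> None:
    if time.ndim != 1 or time.size == 0:
        raise ValidationError(f"{what}: time must be a non-empty 1-d array")
    if not np.all(np.diff(time) > 0):
        raise ValidationError(f"{what}: time must be strictly increasing")


@dataclass
class MotionTrace:
    """Regularly sampled torso motion stream."""

    sample_rate: float  # Hz
    time: np.ndarray  # s
    speed: np.ndarray  # m/s
    vertical_position: np.ndarray  # m
    vertical_acceleration: np.ndarray  # m/s^2

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.vertical_position = np.asarray(self.vertical_position, dtype=float)
        self.vertical_acceleration = np.asarray(self.vertical_acceleration, dtype=float)
        _check_monotone(self.time, "MotionTrace")
        n = self.time.size
        for name in ("speed", "vertical_position", "vertical_acceleration"):
            if getattr(self, name).shape != (n,):
                raise ValidationError(f"MotionTrace: {name} must match time length {n}")
        if self.sample_rate <= 0:
            raise ValidationError("MotionTrace: sample_rate must be positive")

    def shifted(self, offset: float) -> "MotionTrace":
        return MotionTrace(
            sample_rate=self.sample_rate,
            time=self.time + offset,
            speed=self.speed.copy(),
            vertical_position=self.vertical_position.copy(),
            vertical_acceleration=self.vertical_acceleration.copy(),
        )


@dataclass
class PhysioSeries:
    """A sampled physiological time series (V̇O2 in mL/min/kg or HR in bpm).

    ``bookmark_time`` carries a device-clock event marker (the
    synchronization bookmark) when one was recorded.
    """

    quantity: Literal["vo2", "hr"]
    time: np.ndarray  # s
    values: np.ndarray
    nominal_rate: float  # Hz
    bookmark_time: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_monotone(self.time, f"PhysioSeries[{self.quantity}]")
        if self.values.shape != self.time.shape:
            raise ValidationError("PhysioSeries: values must match time length")
        if self.quantity == "vo2" and not np.all(self.values > 0):
            raise ValidationError("PhysioSeries[vo2]: values must be positive")
        if self.quantity == "hr" and not (
            np.all(self.values >= 20) and np.all(self.values <= 230)
        ):
            raise ValidationError("PhysioSeries[hr]: values must lie in [20, 230] bpm")

    def shifted(self, offset: float) -> "PhysioSeries":
        return PhysioSeries(
            quantity=self.quantity,
            time=self.time + offset,
            values=self.values.copy(),
            nominal_rate=self.nominal_rate,
            bookmark_time=None if self.bookmark_time is None else self.bookmark_time + offset,
        )


@dataclass
class SimulatedPhysiology:
    """Noisy sampled series plus the noiseless latent truth."""

    vo2: PhysioSeries
    hr: PhysioSeries
    latent_vo2: PhysioSeries
    latent_hr: PhysioSeries


@dataclass
class SyncedStreams:
    """Streams on desynchronized device clocks, with ground truth retained."""

    motion: MotionTrace
    vo2: PhysioSeries
    hr: PhysioSeries
    true_offsets: tuple[float, float, float]  # motion, vo2, hr
    jump_time: float  # true session time of the synchronization jump


# ---------------------------------------------------------------------------
# protocol and subject sampling
# ---------------------------------------------------------------------------


def generate_protocol(
    walk_speeds: Sequence[float] = (1.3, 1.8),
    run_speeds: Sequence[float] = (2.5, 3.5),
    stage_duration: float = 180.0,
    rest_duration: float = 120.0,
) -> ExerciseProtocol:
    """Rest / walk1 / rest / walk2 / rest / run1 / rest / run2 / rest.

    Raises :class:`ValidationError` when a speed falls outside the protocol
    range, walking is not slower than running, or a duration is not positive.
    """
    if len(walk_speeds) != 2 or len(run_speeds) != 2:
        raise ValidationError("exactly two walking and two running speeds are required")
    if max(walk_speeds) >= min(run_speeds):
        raise ValidationError("walking speeds must be below running speeds")
    if stage_duration <= 0 or rest_duration <= 0:
        raise ValidationError("stage_duration and rest_duration must be positive")
    rest = ProtocolSegment("rest", 0.0, rest_duration)
    segments: list[ProtocolSegment] = [rest]
    for label, speeds in (("walk", walk_speeds), ("run", run_speeds)):
        for v in speeds:
            segments.append(ProtocolSegment(label, float(v), stage_duration))
            segments.append(rest)
    return ExerciseProtocol(tuple(segments))


def sample_subject(seed: int) -> SubjectProfile:
    """Draw one subject from the cohort distribution.

    Body mass ~ Normal(78.3, 13.0) kg truncated to [45, 120]; the other
    parameters get modest physiological scatter around the defaults.
    """
    rng = np.random.default_rng(seed)
    mass = float(np.clip(rng.normal(78.3, 13.0), 45.0, 120.0))
    return SubjectProfile(
        body_mass=mass,
        vo2_rest=float(rng.normal(3.5, 0.3)),
        vo2_peak=float(rng.normal(52.0, 4.0)),
        hr_rest=float(rng.normal(58.0, 5.0)),
        hr_max=float(rng.normal(192.0, 6.0)),
        tau_vo2_on=float(rng.normal(35.0, 4.0)),
        tau_vo2_off=float(rng.normal(45.0, 4.0)),
        tau_hr=float(rng.normal(25.0, 3.0)),
        cadence_base=float(rng.normal(1.4, 0.08)),
        preferred_cadence_slope=float(rng.normal(0.45, 0.03)),
        rng_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# steady-state metabolic model
# ---------------------------------------------------------------------------

#: net metabolic cost slopes, mL O2 per kg per minute per (m/s)
WALK_VO2_SLOPE = 6.0
RUN_VO2_SLOPE = 12.0


def vo2_steady_state(
    speed: float,
    gait: Literal["walk", "run", "rest"],
    subject: SubjectProfile,
    walk_slope: float = WALK_VO2_SLOPE,
    run_slope: float = RUN_VO2_SLOPE,
) -> float:
    """Steady-state oxygen uptake (mL/min/kg) at a constant speed.

    Linear metabolic cost models in the spirit of the ACSM walking/running
    equations: ``vo2_rest + slope * speed`` with a gait-specific slope.
    """
    if speed < 0:
        raise ValidationError("speed must be non-negative")
    if speed == 0 or gait == "rest":
        return subject.vo2_rest
    slope = walk_slope if gait == "walk" else run_slope
    return subject.vo2_rest + slope * speed


# ---------------------------------------------------------------------------
# gait synthesis
# ---------------------------------------------------------------------------


def _oscillation_amplitude(label: str) -> float:
    # half-range of the vertical excursion, m (peak-to-peak is twice this)
    return 0.025 if label == "walk" else 0.045


def _speed_oscillation(label: str) -> float:
    # within-step speed oscillation half-range, m/s
    return 0.05 if label == "walk" else 0.125


def _pace_wander(rng: np.random.Generator, n: int, dt: float,
                 sd: float = 0.1, tau: float = 15.0) -> np.ndarray:
    """Ornstein-Uhlenbeck pace deviation: subjective pacing drifts smoothly."""
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    q = sd * np.sqrt(1.0 - a * a)
    w = q * rng.normal(0.0, 1.0, size=n)
    w[0] = rng.normal(0.0, sd)
    x, _ = lfilter([1.0], [1.0, -a], w, zi=np.zeros(1))
    return x


#: gait settling: fractional cadence reduction per unit V̇O2 deficit
CADENCE_SETTLING_GAIN = 0.05
#: gait settling: fractional vertical-oscillation increase per unit deficit
AMPLITUDE_SETTLING_GAIN = 0.10


def simulate_steps(
    protocol: ExerciseProtocol,
    subject: SubjectProfile,
    seed: int,
    sample_rate: float = 100.0,
    speed_noise_sd: float = 0.05,
    position_noise_sd: float = 0.005,
    accel_noise_sd: float = 0.5,
    duration_jitter: float = 0.02,
    cadence_settling: float = CADENCE_SETTLING_GAIN,
    amplitude_settling: float = AMPLITUDE_SETTLING_GAIN,
) -> tuple[MotionTrace, np.ndarray]:
    """Synthesize the torso motion trace and the true step boundary times.

    During locomotion the vertical position completes one oscillation per
    step (peaking mid-step) and the measured speed wanders around the stage
    target; at rest both are flat up to sensor noise.  Step durations follow
    the subject's cadence model with multiplicative jitter.

    Gait is coupled to the metabolic transient: while the oxygen deficit
    d(t) = (V_ss − V̇O2(t))/(V_ss − V̇O2_rest) decays at stage onset, the
    runner's gait is not yet settled — cadence sits ``cadence_settling``
    fraction lower and vertical oscillation ``amplitude_settling`` fraction
    higher per unit deficit, relaxing to the preferred gait as V̇O2
    approaches steady state.

    Returns the trace and the array of true step start times (ground truth
    for segmentation tests).  Noise defaults mirror the stated device
    accuracies: speed 0.05 m/s, per-step vertical displacement ~0.01 m
    (applied as a slowly varying position error so it moves the whole
    step, not individual samples).
    """
    rng = np.random.default_rng(seed)
    total = protocol.total_duration
    n = int(round(total * sample_rate))
    t = np.arange(n) / sample_rate
    dt = 1.0 / sample_rate

    speed = np.zeros(n)
    vpos = np.zeros(n)
    vacc = np.zeros(n)

    # smooth pace deviation shared across the whole session
    wander = _pace_wander(rng, n, dt)

    # noiseless metabolic state for the gait-settling coupling
    kt, kv, _ = _integrate_kinetics(protocol, subject, dt=0.1)

    boundaries: list[float] = []
    for start, end, seg in protocol.segment_bounds():
        i0, i1 = int(round(start * sample_rate)), min(int(round(end * sample_rate)), n)
        if seg.label == "rest":
            continue
        base_amp = _oscillation_amplitude(seg.label)
        s_amp = _speed_oscillation(seg.label)
        vss = vo2_steady_state(seg.target_speed, seg.label, subject)
        reserve = max(vss - subject.vo2_rest, 1e-9)
        tcur = start
        while True:
            deficit = (vss - np.interp(tcur, kt, kv)) / reserve
            deficit = float(np.clip(deficit, 0.0, 1.0))
            f = subject.step_frequency(seg.target_speed) * (
                1.0 - cadence_settling * deficit
            )
            amp = base_amp * (1.0 + amplitude_settling * deficit)
            d = (1.0 / f) * (1.0 + duration_jitter * rng.normal())
            if tcur + d > end:
                break
            boundaries.append(tcur)
            j0 = max(int(np.ceil(tcur * sample_rate)), i0)
            j1 = min(int(np.ceil((tcur + d) * sample_rate)), i1)
            if j1 > j0:
                u = (t[j0:j1] - tcur) / d  # local phase in [0, 1)
                vpos[j0:j1] = amp * (1.0 - np.cos(2.0 * np.pi * u))
                omega = 2.0 * np.pi / d
                vacc[j0:j1] = amp * omega * omega * np.cos(2.0 * np.pi * u)
                speed[j0:j1] = (
                    seg.target_speed + wander[j0:j1] + s_amp * np.sin(2.0 * np.pi * u)
                )
            tcur += d

    speed = np.clip(speed + rng.normal(0.0, speed_noise_sd, n), 0.0, None)
    # slowly varying vertical position error (INS drift), ~2 s correlation,
    # kept well below the step oscillation so rest periods stay step-free
    k = max(int(2 * sample_rate), 1)
    drift = np.convolve(rng.normal(0.0, position_noise_sd * np.sqrt(k), n),
                        np.ones(k) / k, mode="same")
    vpos = vpos + drift
    vacc = vacc + rng.normal(0.0, accel_noise_sd, n)

    trace = MotionTrace(
        sample_rate=sample_rate,
        time=t,
        speed=speed,
        vertical_position=vpos,
        vertical_acceleration=vacc,
    )
    return trace, np.asarray(boundaries)


# ---------------------------------------------------------------------------
# cardiorespiratory kinetics
# ---------------------------------------------------------------------------


def _integrate_kinetics(
    protocol: ExerciseProtocol, subject: SubjectProfile, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent V̇O2 and HR on a dt grid.

    First-order kinetics toward the speed-dependent steady state,
    dV/dt = (V_ss − V)/τ with the onset time constant when V_ss > V and the
    recovery constant otherwise.  HR relaxes toward the heart rate implied
    by the fractional V̇O2 reserve with its own time constant.  Because the
    forcing is piecewise constant on each dt interval, the exact
    exponential update is used, so on a constant-speed segment the latent
    trace equals the closed-form solution to machine precision.
    """
    n = int(round(protocol.total_duration / dt)) + 1
    t = np.arange(n) * dt
    v = np.empty(n)
    h = np.empty(n)
    v[0] = subject.vo2_rest
    h[0] = subject.hr_rest
    bounds = protocol.segment_bounds()
    bi = 0
    for i in range(1, n):
        tprev = t[i - 1]
        while bi + 1 < len(bounds) and tprev >= bounds[bi][1]:
            bi += 1
        seg = bounds[bi][2]
        vss = vo2_steady_state(seg.target_speed, seg.label, subject)
        tau = subject.tau_vo2_on if vss > v[i - 1] else subject.tau_vo2_off
        v[i] = vss + (v[i - 1] - vss) * np.exp(-dt / tau)
        frac = (v[i - 1] - subject.vo2_rest) / (subject.vo2_peak - subject.vo2_rest)
        hss = subject.hr_rest + frac * (subject.hr_max - subject.hr_rest)
        h[i] = hss + (h[i - 1] - hss) * np.exp(-dt / subject.tau_hr)
    return t, v, h


def simulate_physiology(
    protocol: ExerciseProtocol,
    subject: SubjectProfile,
    seed: int,
    vo2_rate: float = 0.2,
    hr_rate: float = 1.0,
    vo2_noise_sd_abs: float = 125.0,
    hr_noise_sd: float = 2.0,
    dt: float = 0.1,
) -> SimulatedPhysiology:
    """Sampled V̇O2 (every 1/vo2_rate s) and HR (1/hr_rate s) with noise.

    ``vo2_noise_sd_abs`` is the spirometer noise in absolute mL/min (the
    Oxycon-like figure); it is divided by body mass to give the per-sample
    SD in mL/min/kg.  The noiseless latent series are returned alongside
    for oracle tests.
    """
    rng = np.random.default_rng(seed)
    t, v, h = _integrate_kinetics(protocol, subject, dt)
    total = protocol.total_duration

    tv = np.arange(1.0 / vo2_rate, total + 1e-9, 1.0 / vo2_rate)
    th = np.arange(1.0 / hr_rate, total + 1e-9, 1.0 / hr_rate)
    vo2_sd = vo2_noise_sd_abs / subject.body_mass
    vo2_vals = np.interp(tv, t, v) + rng.normal(0.0, vo2_sd, tv.size)
    hr_vals = np.interp(th, t, h) + rng.normal(0.0, hr_noise_sd, th.size)
    vo2_vals = np.clip(vo2_vals, 0.1, None)
    hr_vals = np.clip(hr_vals, 20.0, 230.0)

    return SimulatedPhysiology(
        vo2=PhysioSeries("vo2", tv, vo2_vals, vo2_rate),
        hr=PhysioSeries("hr", th, hr_vals, hr_rate),
        latent_vo2=PhysioSeries("vo2", t, np.clip(v, 1e-9, None), 1.0 / dt),
        latent_hr=PhysioSeries("hr", t, np.clip(h, 20.0, 230.0), 1.0 / dt),
    )


# ---------------------------------------------------------------------------
# synchronization artifacts
# ---------------------------------------------------------------------------


def inject_sync_artifacts(
    motion: MotionTrace,
    vo2: PhysioSeries,
    hr: PhysioSeries,
    offsets: Sequence[float],
    jump_time: float,
    seed: int = 0,
    spike_amplitude: float | None = None,
    marker_jitter_sd: float = 0.04,
) -> SyncedStreams:
    """Desynchronize the streams and plant the jump bookmark.

    Each stream's clock is shifted by its offset (device clock = session
    time + offset).  A sharp vertical-acceleration spike is inserted in the
    motion trace at the jump, and the V̇O2 and HR devices record bookmark
    markers with a small timing jitter (manual bookmark precision).  True
    offsets are retained as ground truth.
    """
    offsets = tuple(float(o) for o in offsets)
    if len(offsets) != 3:
        raise ValidationError("offsets must be (motion, vo2, hr)")
    if any(abs(o) >= 30.0 for o in offsets):
        raise ValidationError("stream offsets must satisfy |offset| < 30 s")
    if not (motion.time[0] <= jump_time <= motion.time[-1]):
        raise ValidationError("jump_time must fall inside the motion recording")

    rng = np.random.default_rng(seed)
    m = motion.shifted(offsets[0])
    idx = int(np.argmin(np.abs(motion.time - jump_time)))
    if spike_amplitude is None:
        spike_amplitude = max(3.0 * float(np.max(np.abs(m.vertical_acceleration))), 50.0)
    # short triangular landing spike; strict global maximum of |accel|
    m.vertical_acceleration[idx] = spike_amplitude
    if idx > 0:
        m.vertical_acceleration[idx - 1] = 0.6 * spike_amplitude
    if idx + 1 < m.time.size:
        m.vertical_acceleration[idx + 1] = 0.6 * spike_amplitude

    v = vo2.shifted(offsets[1])
    v.bookmark_time = jump_time + offsets[1] + rng.normal(0.0, marker_jitter_sd)
    h = hr.shifted(offsets[2])
    h.bookmark_time = jump_time + offsets[2] + rng.normal(0.0, marker_jitter_sd)
    return SyncedStreams(motion=m, vo2=v, hr=h, true_offsets=offsets, jump_time=jump_time)


# ---------------------------------------------------------------------------
# plain-text writers / readers
# ---------------------------------------------------------------------------


def write_simulation(
    out_dir: str | Path,
    motion: MotionTrace,
    physio: SimulatedPhysiology,
    step_times: np.ndarray,
    subject: SubjectProfile,
    protocol: ExerciseProtocol,
    seeds: dict[str, int],
    true_offsets: Sequence[float] | None = None,
) -> dict[str, Path]:
    """Write CSV streams plus a JSON sidecar; returns the file map."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def _csv(name: str, frame: "pd.DataFrame") -> None:
        p = out / name
        frame.to_csv(p, index=False, float_format="%.6f")
        files[name] = p

    _csv("motion.csv", pd.DataFrame({
        "time_s": motion.time,
        "speed_mps": motion.speed,
        "vertical_position_m": motion.vertical_position,
        "vertical_acceleration_mps2": motion.vertical_acceleration,
    }))
    _csv("vo2.csv", pd.DataFrame({"time_s": physio.vo2.time, "vo2_mlkgmin": physio.vo2.values}))
    _csv("hr.csv", pd.DataFrame({"time_s": physio.hr.time, "hr_bpm": physio.hr.values}))
    _csv("vo2_latent.csv", pd.DataFrame({
        "time_s": physio.latent_vo2.time, "vo2_mlkgmin": physio.latent_vo2.values,
    }))
    _csv("steps_true.csv", pd.DataFrame({"time_s": step_times}))

    sidecar = {
        "subject": dataclasses.asdict(subject),
        "protocol": [dataclasses.asdict(s) for s in protocol.segments],
        "seeds": seeds,
        "true_offsets": list(true_offsets) if true_offsets is not None else None,
        "motion_sample_rate_hz": motion.sample_rate,
        "vo2_rate_hz": physio.vo2.nominal_rate,
        "hr_rate_hz": physio.hr.nominal_rate,
        "vo2_bookmark_time_s": physio.vo2.bookmark_time,
        "hr_bookmark_time_s": physio.hr.bookmark_time,
    }
    p = out / "sidecar.json"
    p.write_text(json.dumps(sidecar, indent=2))
    files["sidecar.json"] = p
    return files


def read_motion_csv(path: str | Path, sample_rate: float | None = None) -> MotionTrace:
    import pandas as pd

    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return MotionTrace(
        sample_rate=sample_rate,
        time=t,
        speed=df["speed_mps"].to_numpy(),
        vertical_position=df["vertical_position_m"].to_numpy(),
        vertical_acceleration=df["vertical_acceleration_mps2"].to_numpy(),
    )


def read_physio_csv(
    path: str | Path,
    quantity: Literal["vo2", "hr"],
    nominal_rate: float,
    bookmark_time: float | None = None,
) -> PhysioSeries:
    import pandas as pd

    df = pd.read_csv(path)
    col = "vo2_mlkgmin" if quantity == "vo2" else "hr_bpm"
    return PhysioSeries(
        quantity=quantity,
        time=df["time_s"].to_numpy(),
        values=df[col].to_numpy(),
        nominal_rate=nominal_rate,
        bookmark_time=bookmark_time,
    )
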