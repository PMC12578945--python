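"""Synthetic multichannel sEMG+IMU gait-trial generator.

Emulates the statistical structure of lower-limb recordings during five
functional motions (walking forwards/backwards, 90-degree turns left/right,
and a squat / pick-up movement): class- and muscle-specific EMG burst
timing, stride-periodic kinematics, turn yaw-rate signatures, and
per-subject variability (muscle gains, activation latency, cadence, noise
floors) large enough that naive cross-subject transfer degrades.

Signals are generated at the native sensor rates — EMG as 12-bit ADC counts
at 1000 Hz, 9-axis IMU values at 25 Hz — and only later aligned into the
5000x35 trial matrix (see :mod:`gaitmotion.trial_io`).

EMG model: baseline offset + noise floor + Gaussian-envelope-modulated
band-limited noise bursts (carrier band 20-150 Hz, inside the 0.2-400 Hz
preprocessing passband).  IMU model: gravity baseline on the vertical
accelerometer (+1 g in quiet standing), class-specific low-frequency
kinematic templates, slow magnetometer heading ramps during turns, plus
white noise.  Units: accelerometer in g, gyroscope in deg/s, magnetometer
in arbitrary normalised units.

Sign conventions (fixed, used by tests and documentation): accelerometer z
points up (+1 g at rest), x points anteroposterior (+ = forwards); the yaw
gyroscope (gyr_z) is positive for counterclockwise rotation, i.e. positive
sustained yaw rate during a left turn and negative during a right turn.

Everything is a pure function of its seed and arguments.  Sub-streams are
derived with ``numpy.random.SeedSequence([seed, stream_key])``: stream key
1000 carries the trial plan shared by all channels of one trial (burst
onsets, stride phase, amplitude jitters), keys 0-7 the per-EMG-channel
noise, and keys 100-102 the per-IMU-unit noise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .channels import EMG_CHANNELS, IMU_PLACEMENTS

__all__ = [
    "MotionClass",
    "SubjectProfile",
    "GeneratorConfig",
    "RawTrialBundle",
    "SyntheticDataset",
    "gen_emg_channel",
    "gen_emg_envelope",
    "gen_imu_unit",
    "gen_imu_template",
    "gen_trial",
    "gen_dataset",
    "sample_profile",
]


class MotionClass(str, enum.Enum):
    """The five motion classes; the label set is closed."""

    walk_forward = "walk_forward"
    walk_backward = "walk_backward"
    turn_left = "turn_left"
    turn_right = "turn_right"
    squat = "squat"

    @classmethod
    def from_label(cls, label: "str | MotionClass") -> "MotionClass":
        if isinstance(label, cls):
            return label
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown motion label {label!r}; valid labels: {valid}"
            ) from None


MOTION_CLASSES: tuple[MotionClass, ...] = tuple(MotionClass)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters.

    muscle_gains maps each EMG channel name to a positive scale factor;
    burst_latency_shift (s) offsets every activation onset;
    imu_amplitude_scale multiplies kinematic template amplitudes;
    noise floors are standard deviations (ADC counts for EMG, g for IMU);
    cadence is strides per second for the gait classes.
    """

    subject_id: str
    muscle_gains: dict[str, float]
    burst_latency_shift: float = 0.0
    imu_amplitude_scale: float = 1.0
    noise_floor_emg: float = 8.0
    noise_floor_imu: float = 0.04
    cadence: float = 1.0

    def __post_init__(self) -> None:
        for name, g in self.muscle_gains.items():
            if g < 0:
                raise ValueError(f"muscle gain for {name!r} must be >= 0, got {g}")
        for fname in ("imu_amplitude_scale", "noise_floor_emg",
                      "noise_floor_imu", "cadence"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling rates, ADC characteristics and dataset sizing."""

    fs_emg: float = 1000.0
    fs_imu: float = 25.0
    duration: float = 5.0
    adc_bits: int = 12
    adc_vref: float = 1.1
    n_per_class: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.fs_emg <= 0 or self.fs_imu <= 0:
            raise ValueError("sampling rates must be positive")
        ratio = self.fs_emg / self.fs_imu
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"fs_emg/fs_imu must be an integer upsampling factor, got {ratio}"
            )
        n = self.duration * self.fs_emg
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x fs_emg must be an integer sample count")

    @property
    def upsample_factor(self) -> int:
        return int(round(self.fs_emg / self.fs_imu))

    @property
    def n_emg(self) -> int:
        return int(round(self.duration * self.fs_emg))

    @property
    def n_imu(self) -> int:
        return int(round(self.duration * self.fs_imu))

    @property
    def adc_max(self) -> int:
        return 2 ** self.adc_bits - 1


@dataclass
class RawTrialBundle:
    """Per-sensor native-rate series of one trial, before alignment."""

    emg: np.ndarray          # (8, n_emg) integer ADC counts
    imu: np.ndarray          # (3, 9, n_imu) float
    label: MotionClass
    subject_id: str
    seed: int

    def validate(self, config: GeneratorConfig) -> None:
        if self.emg.shape != (len(EMG_CHANNELS), config.n_emg):
            raise ValueError(f"EMG shape {self.emg.shape} invalid")
        if self.imu.shape != (len(IMU_PLACEMENTS), 9, config.n_imu):
            raise ValueError(f"IMU shape {self.imu.shape} invalid")
        if self.emg.min() < 0 or self.emg.max() > config.adc_max:
            raise ValueError("EMG counts outside ADC range")


# ---------------------------------------------------------------------------
# Activation schedule: which muscles fire in which class.
#
# Editable module constant.  Walking entries give (stride phase in [0,1),
# burst sigma in s, relative amplitude) per muscle role; the left leg is a
# half stride out of phase with the right.  Event entries give absolute
# (onset s, sigma s, amplitude) tuples, before subject latency shift and
# trial onset jitter.  Plantarflexors (soleus, both gastrocnemius heads)
# burst at push-off, the tibialis anterior in swing; walking backwards
# reverses the roles; turns load the outer leg; the squat opens with a large
# tibialis-anterior burst (dorsiflexion driving the knees forwards) that
# leads the IMU excursion, then sustained low-level plantarflexor activity.
# ---------------------------------------------------------------------------

_WALK_FORWARD_PHASES = {
    "ta": (0.85, 0.05, 0.55),
    "gm": (0.38, 0.05, 0.90),
    "gl": (0.40, 0.05, 0.80),
    "sol": (0.35, 0.05, 1.00),
}
_WALK_BACKWARD_PHASES = {
    "ta": (0.35, 0.05, 1.00),
    "gm": (0.80, 0.05, 0.50),
    "gl": (0.82, 0.05, 0.45),
    "sol": (0.78, 0.05, 0.55),
}
# Outer-leg amplitude factor for turns: a left turn pivots on the left leg
# while the right (outer) leg pushes, and vice versa.
_TURN_OUTER_GAIN = 1.0
_TURN_INNER_GAIN = 0.35

_EMG_BURST_SCALE_COUNTS = 420.0   # envelope amplitude 1.0 in ADC counts
_EMG_BASELINE_COUNTS = 2048.0     # mid-scale ADC offset
_TURN_DURATION_S = 3.0
_TURN_YAW_RATE = 30.0             # deg/s, 90 degrees over 3 s


def _muscle_role(channel: str) -> tuple[str, str]:
    """Return (side, role) for an EMG channel name, e.g. ('l', 'sol')."""
    if channel not in EMG_CHANNELS:
        valid = ", ".join(EMG_CHANNELS)
        raise ValueError(
            f"unknown EMG channel {channel!r}; valid channels: {valid}"
        )
    _, side, role = channel.split("_")
    return side, role


@dataclass(frozen=True)
class _TrialPlan:
    """Trial-level random draws shared by every channel of one trial."""

    stride_phase: float        # [0,1) stride offset for gait classes
    event_onset: float         # s, turn start / squat onset
    amp_jitter: float          # shared kinematic amplitude jitter
    burst_time_jitter: float   # s, small common onset jitter
    burst_amp_jitters: np.ndarray  # per-burst EMG amplitude factors


def _trial_plan(label: MotionClass, config: GeneratorConfig, seed: int) -> _TrialPlan:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000]))
    stride_phase = float(rng.uniform(0.0, 1.0))
    if label in (MotionClass.turn_left, MotionClass.turn_right):
        event_onset = float(rng.uniform(0.3, 1.0))
    else:
        event_onset = float(rng.uniform(0.6, 1.2))   # squat onset
    amp_jitter = float(rng.uniform(0.9, 1.1))
    burst_time_jitter = float(rng.uniform(-0.03, 0.03))
    burst_amp_jitters = rng.uniform(0.85, 1.15, size=16)
    return _TrialPlan(stride_phase, event_onset, amp_jitter,
                      burst_time_jitter, burst_amp_jitters)


def _burst_times_walking(phase: float, side: str, plan: _TrialPlan,
                         profile: SubjectProfile, duration: float) -> np.ndarray:
    """Onset times of one muscle's per-stride bursts over the trial."""
    cadence = max(profile.cadence, 1e-6)
    leg_shift = 0.5 if side == "l" else 0.0
    period = 1.0 / cadence
    # enough strides to cover the window regardless of phase
    k = np.arange(-1, int(np.ceil(duration * cadence)) + 2)
    times = (k + phase + leg_shift + plan.stride_phase) * period
    times = times + profile.burst_latency_shift + plan.burst_time_jitter
    return times[(times > -0.2) & (times < duration + 0.2)]


def gen_emg_envelope(label: MotionClass | str, channel: str,
                     profile: SubjectProfile, config: GeneratorConfig,
                     seed: int) -> np.ndarray:
    """Noiseless activation envelope (unit amplitude scale) for one channel.

    Exposed separately so tests can check burst timing against the envelope
    the EMG synthesis actually used.
    """
    label = MotionClass.from_label(label)
    side, role = _muscle_role(channel)
    plan = _trial_plan(label, config, seed)
    t = np.arange(config.n_emg) / config.fs_emg
    env = np.zeros_like(t)

    def add_burst(onset: float, sigma: float, amp: float, j: int) -> None:
        a = amp * plan.burst_amp_jitters[j % len(plan.burst_amp_jitters)]
        env_local = a * np.exp(-0.5 * ((t - onset) / sigma) ** 2)
        np.maximum(env, env_local, out=env)

    if label in (MotionClass.walk_forward, MotionClass.walk_backward):
        table = (_WALK_FORWARD_PHASES if label is MotionClass.walk_forward
                 else _WALK_BACKWARD_PHASES)
        phase, sigma, amp = table[role]
        for j, onset in enumerate(
                _burst_times_walking(phase, side, plan, profile, config.duration)):
            add_burst(onset, sigma, amp, j)
    elif label in (MotionClass.turn_left, MotionClass.turn_right):
        outer = "r" if label is MotionClass.turn_left else "l"
        gain = _TURN_OUTER_GAIN if side == outer else _TURN_INNER_GAIN
        t0 = plan.event_onset + profile.burst_latency_shift
        offsets = (0.2, 1.2, 2.2) if role != "ta" else (0.7, 1.7, 2.7)
        amp = gain if role != "ta" else 0.45 * gain
        for j, off in enumerate(offsets):
            add_burst(t0 + off, 0.09, amp, j + 8)
    else:  # squat
        t0 = plan.event_onset + profile.burst_latency_shift
        if role == "ta":
            add_burst(t0, 0.25, 1.0, 0)
        else:
            # sustained low-level plantarflexor activity through the rise
            add_burst(t0 + 1.2, 0.7, 0.30, 1)
    return env


def gen_emg_channel(label: MotionClass | str, channel: str,
                    profile: SubjectProfile, config: GeneratorConfig,
                    seed: int) -> np.ndarray:
    """One EMG channel of one trial, as integer ADC counts.

    Deterministic given (label, channel, profile, config, seed).
    """
    label = MotionClass.from_label(label)
    env = gen_emg_envelope(label, channel, profile, config, seed)
    ch_idx = EMG_CHANNELS.index(channel)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), ch_idx]))
    n = config.n_emg
    # band-limited carrier, 20-150 Hz, unit std
    white = rng.standard_normal(n)
    sos = sps.butter(4, [20.0, 150.0], btype="bandpass", fs=config.fs_emg,
                     output="sos")
    carrier = sps.sosfilt(sos, white)
    std = carrier.std()
    if std > 0:
        carrier = carrier / std
    gain = profile.muscle_gains.get(channel, 1.0)
    counts = (
        _EMG_BASELINE_COUNTS
        + gain * _EMG_BURST_SCALE_COUNTS * env * carrier
        + profile.noise_floor_emg * rng.standard_normal(n)
    )
    counts = np.clip(np.rint(counts), 0, config.adc_max)
    return counts.astype(np.int32)


# ---------------------------------------------------------------------------
# IMU synthesis
# ---------------------------------------------------------------------------

def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _smooth_box(t: np.ndarray, t0: float, t1: float, edge: float = 0.25) -> np.ndarray:
    """Unit plateau on [t0, t1] with logistic edges (differentiable)."""
    return 1.0 / (1.0 + np.exp(-(t - t0) / edge)) / (1.0 + np.exp((t - t1) / edge))


def gen_imu_template(label: MotionClass | str, placement: str,
                     profile: SubjectProfile, config: GeneratorConfig,
                     seed: int) -> np.ndarray:
    """Noise-free 9-channel kinematic template (accel xyz, gyro xyz, mag xyz).

    The template is what :func:`gen_imu_unit` adds sensor noise to; it is
    public so structural tests (step peaks, squat excursion, yaw sign) can
    run on the deterministic part.
    """
    label = MotionClass.from_label(label)
    if placement not in IMU_PLACEMENTS:
        valid = ", ".join(IMU_PLACEMENTS)
        raise ValueError(
            f"unknown IMU placement {placement!r}; valid placements: {valid}"
        )
    plan = _trial_plan(label, config, seed)
    n = config.n_imu
    t = np.arange(n) / config.fs_imu
    scale = profile.imu_amplitude_scale * plan.amp_jitter
    foot = placement == "right_foot"
    left = placement == "left_shank"
    out = np.zeros((9, n))
    acc_x, acc_y, acc_z = out[0], out[1], out[2]
    gyr_x, gyr_y, gyr_z = out[3], out[4], out[5]
    mag_x, mag_y, mag_z = out[6], out[7], out[8]

    acc_z += 1.0                       # gravity baseline, g
    mag_x += 0.40
    mag_y += 0.25
    mag_z += 0.50

    if label in (MotionClass.walk_forward, MotionClass.walk_backward):
        cadence = max(profile.cadence, 1e-6)
        direction = 1.0 if label is MotionClass.walk_forward else -1.0
        leg_shift = 0.5 if left else 0.0
        period = 1.0 / cadence
        k = np.arange(-1, int(np.ceil(config.duration * cadence)) + 2)
        steps = (k + 0.15 + leg_shift + plan.stride_phase) * period
        steps = steps[(steps > -0.3) & (steps < config.duration + 0.3)]
        az_amp = (0.50 if foot else 0.35) * scale
        ax_amp = (0.30 if foot else 0.18) * scale
        for s in steps:
            acc_z += az_amp * _gauss(t, s, 0.07)
            acc_x += direction * ax_amp * _gauss(t, s + 0.1, 0.09)
        w = 2 * np.pi * cadence
        ph = 2 * np.pi * (plan.stride_phase + leg_shift)
        acc_x += direction * 0.08 * scale * np.sin(w * t + ph)
        acc_y += 0.05 * scale * np.sin(0.5 * w * t + ph)
        gyr_y += (90.0 if foot else 55.0) * scale * np.sin(w * t + ph)
        gyr_x += 12.0 * scale * np.sin(w * t + ph + 0.8)
        gyr_z += 6.0 * scale * np.sin(w * t + ph + 1.9)
    elif label in (MotionClass.turn_left, MotionClass.turn_right):
        sign = 1.0 if label is MotionClass.turn_left else -1.0
        t0 = plan.event_onset
        box = _smooth_box(t, t0, t0 + _TURN_DURATION_S)
        yaw_rate = sign * _TURN_YAW_RATE * box            # deg/s
        gyr_z += yaw_rate
        heading = np.cumsum(yaw_rate) / config.fs_imu     # deg
        hr = np.deg2rad(heading)
        mag_x[:] = 0.40 * np.cos(hr)
        mag_y[:] = 0.40 * np.sin(hr) + 0.25
        # pivot steps during the turn
        for j, s in enumerate((0.4, 1.4, 2.4)):
            acc_z += 0.15 * scale * _gauss(t, t0 + s, 0.08)
        gyr_y += 18.0 * scale * np.sin(2 * np.pi * 1.0 * (t - t0)) * box
        acc_x += sign * 0.05 * scale * box
    else:  # squat
        t_c = plan.event_onset + 0.6   # centre of the descent
        amp = scale * (0.35 if not foot else 0.12)
        acc_z += -0.8 * amp * _gauss(t, t_c, 0.28)            # descent dip
        acc_z += 0.65 * amp * _gauss(t, t_c + 1.3, 0.30)      # rise
        # single smooth anteroposterior bump as the knees travel forwards
        acc_x += amp * _gauss(t, t_c + 0.15, 0.38)
        gyr_y += -110.0 * amp * _gauss(t, t_c - 0.25, 0.30)
        gyr_y += 95.0 * amp * _gauss(t, t_c + 1.15, 0.32)
        gyr_x += 20.0 * amp * _gauss(t, t_c, 0.5)
    return out


def gen_imu_unit(label: MotionClass | str, placement: str,
                 profile: SubjectProfile, config: GeneratorConfig,
                 seed: int) -> np.ndarray:
    """One 9-axis IMU unit of one trial (template + sensor noise)."""
    template = gen_imu_template(label, placement, profile, config, seed)
    unit_idx = IMU_PLACEMENTS.index(placement)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 100 + unit_idx]))
    noise = rng.standard_normal(template.shape)
    sigma = np.full((9, 1), profile.noise_floor_imu)
    sigma[3:6] *= 15.0    # gyro noise in deg/s
    sigma[6:9] *= 0.3     # magnetometer is quiet
    return template + sigma * noise


def gen_trial(label: MotionClass | str, profile: SubjectProfile,
              config: GeneratorConfig, seed: int) -> RawTrialBundle:
    """Assemble the 8 EMG + 3x9 IMU series of one trial from one seed."""
    label = MotionClass.from_label(label)
    emg = np.stack([
        gen_emg_channel(label, ch, profile, config, seed) for ch in EMG_CHANNELS
    ])
    imu = np.stack([
        gen_imu_unit(label, placement, profile, config, seed)
        for placement in IMU_PLACEMENTS
    ])
    bundle = RawTrialBundle(emg=emg, imu=imu, label=label,
                            subject_id=profile.subject_id, seed=int(seed))
    bundle.validate(config)
    return bundle


# ---------------------------------------------------------------------------
# Subject sampling and dataset assembly
# ---------------------------------------------------------------------------

def sample_profile(subject_id: str, seed_seq: np.random.SeedSequence) -> SubjectProfile:
    """Draw a subject profile from the documented variability ranges.

    Gains log-uniform in [0.5, 2.0]; activation latency uniform in
    [-0.15, +0.15] s; cadence uniform in [0.8, 1.2] strides/s; kinematic
    amplitude log-uniform in [0.6, 1.6]; EMG noise floor uniform in
    [5, 15] counts and IMU noise floor uniform in [0.02, 0.08] g.
    """
    rng = np.random.default_rng(seed_seq)
    gains = {ch: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
             for ch in EMG_CHANNELS}
    return SubjectProfile(
        subject_id=subject_id,
        muscle_gains=gains,
        burst_latency_shift=float(rng.uniform(-0.15, 0.15)),
        imu_amplitude_scale=float(np.exp(rng.uniform(np.log(0.6), np.log(1.6)))),
        noise_floor_emg=float(rng.uniform(5.0, 15.0)),
        noise_floor_imu=float(rng.uniform(0.02, 0.08)),
        cadence=float(rng.uniform(0.8, 1.2)),
    )


@dataclass
class SyntheticDataset:
    """In-memory collection of raw trial bundles with subject profiles."""

    bundles: list[RawTrialBundle]
    profiles: dict[str, SubjectProfile]
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __len__(self) -> int:
        return len(self.bundles)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.profiles)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.bundles:
            counts[b.label.value] = counts.get(b.label.value, 0) + 1
        return counts


def gen_dataset(n_subjects: int, config: GeneratorConfig | None = None,
                out_dir: "str | None" = None) -> SyntheticDataset:
    """Generate a balanced multi-subject dataset, reproducible from
    ``config.master_seed``.

    Each subject gets an independently drawn profile and exactly
    ``config.n_per_class`` trials per motion class.  If ``out_dir`` is given
    the aligned trials are additionally written as CSV files plus a manifest
    (see :func:`gaitmotion.trial_io.write_dataset`).
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    config = config or GeneratorConfig()
    bundles: list[RawTrialBundle] = []
    profiles: dict[str, SubjectProfile] = {}
    for si in range(n_subjects):
        subject_id = f"S{si + 1:02d}"
        profile = sample_profile(
            subject_id, np.random.SeedSequence([config.master_seed, 7, si]))
        profiles[subject_id] = profile
        for ci, label in enumerate(MOTION_CLASSES):
            for ti in range(config.n_per_class):
                ss = np.random.SeedSequence([config.master_seed, 11, si, ci, ti])
                trial_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
                bundles.append(gen_trial(label, profile, config, trial_seed))
    dataset = SyntheticDataset(bundles=bundles, profiles=profiles, config=config)
    if out_dir is not None:
        from .trial_io import write_dataset
        write_dataset(dataset, out_dir)
    return dataset
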