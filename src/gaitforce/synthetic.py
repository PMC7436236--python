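"""Synthetic treadmill-walking generator: paired IMU + reference vGRF trials.

The generator emulates a cohort of healthy adults walking on an instrumented
treadmill at fixed belt speeds while wearing 6-axis inertial sensors (3-axis
accelerometer in m/s^2, 3-axis gyroscope in deg/s) on four lower-limb
segments.  Each trial carries a reference vertical ground reaction force
(vGRF) channel expressed in body weights (BW).

Design goals, in order of importance:

1. the stance-phase force has the classic double-bump morphology — a passive
   (weight-acceptance) peak near 25% of stance, an active (push-off) peak
   near 75%, zero force in swing — plus a short, exponentially damped
   heel-strike transient whose energy sits above 10 Hz;
2. the IMU channels are *deterministic* functions of gait phase and of the
   force itself, so that with sensor noise switched off an 11-sample IMU
   window identifies the force at the window centre exactly (the regression
   problem downstream is well-posed);
3. subjects differ in body mass, cadence, peak magnitudes, heel-strike
   sharpness and sensor mounting, so that leave-one-subject-out evaluation
   is genuinely harder than within-subject evaluation.

The reference force channel is always noise-free: it plays the role of the
gold-standard force plate.  Only the IMU channels carry white measurement
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "LOCATIONS",
    "CHANNELS",
    "DEFAULT_SPEEDS",
    "GRAVITY",
    "GeneratorConfig",
    "SubjectProfile",
    "Trial",
    "make_subject",
    "vgrf_template",
    "simulate_trial",
    "simulate_cohort",
]

#: IMU mounting locations, proximal ordering as worn on the limb.
LOCATIONS = ("foot", "shank", "distal_thigh", "proximal_thigh")

#: Channel order within each location's 6 x n array.
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")

#: Treadmill belt speeds of the emulated protocol, m/s.
DEFAULT_SPEEDS = (0.4, 0.7, 1.0, 1.3, 1.6)

GRAVITY = 9.81  # m/s^2, used for BW <-> newton conversions throughout

# Gaussian bump centres/width of the stance-force template, fractions of stance.
_PP_CENTER = 0.25
_AP_CENTER = 0.75
_BUMP_WIDTH = 0.11
_MIDSTANCE_AMP = 0.55

# Heel-strike transient: damped sinusoid, 15 Hz, 80 ms support, 20 ms decay.
_IMPACT_FREQ_HZ = 15.0
_IMPACT_SUPPORT_S = 0.08
_IMPACT_DECAY_S = 0.02
_IMPACT_REL_AMP = 0.08  # fraction of the passive-peak amplitude

# Per-location signal morphology.  theta_amp: segment sway amplitude (rad);
# psi: phase offset distinguishing segments; grf_c: fraction of the vGRF that
# shows up as axial acceleration; imp: impact transmissibility (foot > shank >
# thighs); gyro_amp: sagittal angular-velocity scale (deg/s).  Magnitudes are
# in the range reported for walking at comfortable speeds.
_LOC_PARAMS = {
    "foot": dict(theta_amp=0.80, psi=0.0, grf_c=0.35, imp=1.00, gyro_amp=250.0),
    "shank": dict(theta_amp=0.50, psi=0.8, grf_c=0.25, imp=0.60, gyro_amp=150.0),
    "distal_thigh": dict(theta_amp=0.35, psi=1.6, grf_c=0.18, imp=0.30, gyro_amp=80.0),
    "proximal_thigh": dict(theta_amp=0.25, psi=2.4, grf_c=0.12, imp=0.20, gyro_amp=60.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Population parameters from which subjects are drawn.

    Means and SDs follow the emulated cohort (body mass 72 +/- 9 kg); the
    remaining spreads are the between-subject variability the
    leave-one-subject-out protocol assumes.  Setting every SD to zero yields
    identical subjects equal to the population mean.
    """

    mass_mean: float = 72.0            # kg
    mass_sd: float = 9.0               # kg
    mass_min: float = 45.0             # kg, truncation floor
    stance_mean: float = 0.62          # fraction of the gait cycle in stance
    stance_sd: float = 0.02
    stance_bounds: tuple = (0.5, 0.7)  # hard truncation, matches invariants
    gain_sd: float = 0.05              # SD of pp_gain and ap_gain around 1
    impact_gain_sd: float = 0.10       # SD of the heel-strike scale around 1
    cycle_scale_sd: float = 0.03       # per-subject cadence multiplier SD
    mount_rot_sd_deg: float = 3.0      # per-axis sensor misalignment SD
    noise_sd_accel: float = 0.05       # m/s^2, accelerometer white noise
    noise_sd_gyro: float = 0.5         # deg/s, gyroscope white noise
    fs: float = 100.0                  # Hz

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorConfig":
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown generator parameters: {sorted(unknown)}")
        if "stance_bounds" in doc:
            doc = {**doc, "stance_bounds": tuple(doc["stance_bounds"])}
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}

    def validate(self) -> None:
        sds = (self.mass_sd, self.stance_sd, self.gain_sd, self.impact_gain_sd,
               self.cycle_scale_sd, self.mount_rot_sd_deg,
               self.noise_sd_accel, self.noise_sd_gyro)
        if any(s < 0 for s in sds):
            raise ValueError("population SDs must be >= 0")
        lo, hi = self.stance_bounds
        if not (lo <= self.stance_mean <= hi):
            raise ValueError(
                f"stance_mean {self.stance_mean} outside bounds {self.stance_bounds}")
        if self.mass_mean <= 0 or self.mass_min <= 0:
            raise ValueError("mass parameters must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated participant.

    ``cycle_time(speed)`` maps belt speed to gait-cycle duration; the shared
    shape T(s) = clip(1.9 - 0.5 s, 0.8, 1.8) s is scaled by the subject's
    ``cycle_scale`` so cadence varies across the cohort.
    """

    subject_id: str
    mass: float                        # kg
    stance_fraction: float             # fraction of the cycle in stance
    pp_gain: float                     # passive-peak scale, ~1
    ap_gain: float                     # active-peak scale, ~1
    impact_gain: float                 # heel-strike transient scale, ~1
    cycle_scale: float                 # cadence multiplier, ~1
    mount_rotation: Dict[str, np.ndarray]  # location -> xyz Euler angles, deg
    noise_sd_accel: float              # m/s^2
    noise_sd_gyro: float               # deg/s
    rng_seed: int

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if not (0.5 <= self.stance_fraction <= 0.7):
            raise ValueError("stance_fraction outside [0.5, 0.7]")
        if min(self.pp_gain, self.ap_gain, self.impact_gain) <= 0:
            raise ValueError("gains must be positive")

    def cycle_time(self, speed: float) -> float:
        """Gait-cycle duration (s) at a belt speed (m/s); decreasing in speed."""
        return self.cycle_scale * float(np.clip(1.9 - 0.5 * speed, 0.8, 1.8))


@dataclass
class Trial:
    """One subject/speed recording: per-location IMU streams + reference vGRF."""

    subject_id: str
    speed: float                       # m/s
    fs: float                          # Hz
    duration: float                    # s
    mass: float                        # kg
    imu: Dict[str, np.ndarray]         # location -> (6, n) array, CHANNELS order
    vgrf: np.ndarray                   # (n,) BW, noise-free reference
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.vgrf.shape[0]

    def validate(self) -> None:
        n = self.n_samples
        for loc, arr in self.imu.items():
            if arr.shape != (6, n):
                raise ValueError(f"{loc}: IMU shape {arr.shape} != (6, {n})")
        if np.any(self.vgrf < 0):
            raise ValueError("reference vGRF must be non-negative")
        if abs(self.fs * self.duration - n) > 1:
            raise ValueError("fs * duration inconsistent with sample count")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float = -np.inf, hi: float = np.inf) -> float:
    """Rejection-sampled truncated normal; degenerates to `mean` when sd=0."""
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate draw outside truncation bounds")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def make_subject(seed: int, config: GeneratorConfig | None = None,
                 subject_id: str | None = None) -> SubjectProfile:
    """Draw one subject from the population; deterministic given (seed, config)."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    mass = _truncnorm(rng, config.mass_mean, config.mass_sd, lo=config.mass_min)
    stance = _truncnorm(rng, config.stance_mean, config.stance_sd,
                        lo=config.stance_bounds[0], hi=config.stance_bounds[1])
    pp_gain = _truncnorm(rng, 1.0, config.gain_sd, lo=1e-6)
    ap_gain = _truncnorm(rng, 1.0, config.gain_sd, lo=1e-6)
    impact_gain = _truncnorm(rng, 1.0, config.impact_gain_sd, lo=1e-6)
    cycle_scale = _truncnorm(rng, 1.0, config.cycle_scale_sd, lo=0.5, hi=1.5)
    mount = {
        loc: rng.normal(0.0, config.mount_rot_sd_deg, size=3)
        if config.mount_rot_sd_deg > 0 else np.zeros(3)
        for loc in LOCATIONS
    }
    return SubjectProfile(
        subject_id=subject_id or f"S{seed}",
        mass=mass,
        stance_fraction=stance,
        pp_gain=pp_gain,
        ap_gain=ap_gain,
        impact_gain=impact_gain,
        cycle_scale=cycle_scale,
        mount_rotation=mount,
        noise_sd_accel=config.noise_sd_accel,
        noise_sd_gyro=config.noise_sd_gyro,
        rng_seed=int(seed),
    )


def _peak_amplitudes(speed: float, profile: SubjectProfile) -> tuple:
    """Gaussian-bump amplitudes of the passive and active peaks (BW)."""
    a_pp = profile.pp_gain * (1.05 + 0.12 * speed)
    a_ap = profile.ap_gain * (1.02 + 0.10 * speed)
    return a_pp, a_ap


def vgrf_template(tau, speed: float, profile: SubjectProfile):
    """Stance-phase vGRF (BW) at stance fraction ``tau`` in [0, 1].

    Two Gaussian bumps (passive peak at 25%, active peak at 75% of stance,
    width 0.11) ride on a mid-stance support term 0.55*sin(pi*tau).  The line
    interpolating the raw curve's endpoint values is subtracted so the force
    is exactly zero at initial contact and toe-off, and the result is clipped
    at zero.  Peak amplitudes grow with belt speed and are scaled by the
    subject's pp/ap gains.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0) or np.any(tau_arr > 1):
        raise ValueError("tau must lie in [0, 1]")
    a_pp, a_ap = _peak_amplitudes(speed, profile)

    def bumps(x):
        return (a_pp * np.exp(-0.5 * ((x - _PP_CENTER) / _BUMP_WIDTH) ** 2)
                + a_ap * np.exp(-0.5 * ((x - _AP_CENTER) / _BUMP_WIDTH) ** 2))

    raw = bumps(tau_arr) + _MIDSTANCE_AMP * np.sin(np.pi * tau_arr)
    edge0, edge1 = bumps(0.0), bumps(1.0)
    corrected = raw - ((1.0 - tau_arr) * edge0 + tau_arr * edge1)
    out = np.clip(corrected, 0.0, None)
    return out if out.ndim else float(out)


def _impact_transient(t_since_ic: np.ndarray) -> np.ndarray:
    """Unit-amplitude damped 15 Hz sinusoid on [0, 80 ms) after contact."""
    active = t_since_ic < _IMPACT_SUPPORT_S
    tr = np.zeros_like(t_since_ic)
    ts = t_since_ic[active]
    tr[active] = np.exp(-ts / _IMPACT_DECAY_S) * np.sin(
        2 * np.pi * _IMPACT_FREQ_HZ * ts)
    return tr


def simulate_trial(profile: SubjectProfile, speed: float,
                   duration: float = 60.0, fs: float = 100.0) -> Trial:
    """Render one treadmill trial for a subject at a fixed belt speed.

    Gait cycles of duration ``profile.cycle_time(speed)`` are tiled over the
    trial; the first ``stance_fraction`` of each cycle is stance.  The
    reference vGRF is the stance template plus the heel-strike transient
    (clipped at zero), exactly zero in swing, and carries no noise.  IMU
    channels are smooth functions of the gait phase plus a term proportional
    to the local vGRF and the location-scaled impact transient; each triad is
    rotated by the subject's mounting misalignment and then corrupted with
    white noise.
    """
    n = int(round(duration * fs))
    T = profile.cycle_time(speed)
    if n < T * fs:
        raise ValueError("trial shorter than one gait cycle")
    t = np.arange(n) / fs
    phase = (t % T) / T                      # gait-cycle phase in [0, 1)
    sf = profile.stance_fraction
    in_stance = phase < sf
    tau = np.where(in_stance, phase / sf, 0.0)

    a_pp, _ = _peak_amplitudes(speed, profile)
    vgrf = np.zeros(n)
    vgrf[in_stance] = vgrf_template(tau[in_stance], speed, profile)
    transient = _impact_transient(phase * T)  # time since initial contact
    vgrf = np.clip(
        vgrf + _IMPACT_REL_AMP * profile.impact_gain * a_pp * transient, 0.0, None)

    rng = np.random.default_rng([profile.rng_seed, int(round(speed * 1000))])
    two_pi = 2 * np.pi * phase
    imu: Dict[str, np.ndarray] = {}
    for loc in LOCATIONS:
        p = _LOC_PARAMS[loc]
        sway = p["theta_amp"] * (0.5 + 0.5 * speed)
        theta = (sway * np.sin(two_pi + p["psi"])
                 + 0.25 * p["theta_amp"] * np.sin(2 * two_pi + 0.5 * p["psi"]))
        imp = p["imp"] * profile.impact_gain * transient
        ax = (GRAVITY * np.sin(theta)
              + 1.5 * speed * np.sin(two_pi + p["psi"] + 1.1)
              + 4.0 * imp)
        ay = (0.6 * speed * np.sin(two_pi + p["psi"] + 2.3)
              + 0.3 * GRAVITY * np.sin(0.5 * theta))
        az = (GRAVITY * np.cos(theta)
              + p["grf_c"] * GRAVITY * vgrf
              + 6.0 * imp)
        gscale = p["gyro_amp"] * (0.4 + 0.6 * speed)
        gx = gscale * np.sin(two_pi + p["psi"] + 0.4)
        gy = 0.5 * gscale * np.sin(2 * two_pi + p["psi"] + 1.0)
        gz = 0.25 * p["gyro_amp"] * speed * np.sin(two_pi + p["psi"] + 2.0)

        R = Rotation.from_euler(
            "xyz", profile.mount_rotation[loc], degrees=True).as_matrix()
        acc = R @ np.vstack([ax, ay, az])
        gyr = R @ np.vstack([gx, gy, gz])
        if profile.noise_sd_accel > 0:
            acc = acc + rng.normal(0.0, profile.noise_sd_accel, acc.shape)
        if profile.noise_sd_gyro > 0:
            gyr = gyr + rng.normal(0.0, profile.noise_sd_gyro, gyr.shape)
        imu[loc] = np.vstack([acc, gyr])

    trial = Trial(subject_id=profile.subject_id, speed=speed, fs=fs,
                  duration=duration, mass=profile.mass, imu=imu, vgrf=vgrf,
                  seed=profile.rng_seed)
    trial.validate()
    return trial


def simulate_cohort(n_subjects: int = 9,
                    speeds: Sequence[float] = DEFAULT_SPEEDS,
                    duration: float = 60.0,
                    seed: int = 0,
                    config: GeneratorConfig | None = None,
                    fs: float | None = None) -> List[Trial]:
    """Simulate ``n_subjects`` x ``len(speeds)`` trials, one list entry each.

    Per-subject seeds derive deterministically from the master ``seed``, so
    the cohort is bitwise reproducible.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    config = config or GeneratorConfig()
    fs = fs if fs is not None else config.fs
    subject_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    subject_seeds = (subject_seeds % (2 ** 31)).astype(int)
    trials: List[Trial] = []
    for i, s_seed in enumerate(subject_seeds):
        profile = make_subject(int(s_seed), config, subject_id=f"S{i + 1:02d}")
        for speed in speeds:
            trials.append(simulate_trial(profile, float(speed), duration, fs))
    return trials
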