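"""Synthetic treadmill-running generator.

Emulates the study protocol — a cohort of runners, each recorded at
several treadmill speeds with a shoe-mounted 3-axis accelerometer while
sagittal hip/knee/ankle angles and heel height are tracked — so the whole
estimation pipeline can be exercised without motion-capture data.

Design
------
Each participant owns smooth stride-periodic joint-angle waveforms (a
fundamental harmonic plus von-Mises-style bumps) whose per-stride extrema
are calibrated *exactly* to that participant's six discrete gait-event
values (peak hip flexion/extension, peak knee flexion during stance, peak
ankle dorsi/plantarflexion, ankle angle at initial contact).  Event values
are drawn per participant from a normal population whose means and SDs
default to reference running-gait statistics, so population event means
converge to the calibration targets.

The accelerometer signal is produced by a forward model rather than drawn
from noise: a planar thigh–shank–foot chain is planted under the angle
trajectories together with a vertical pelvis trajectory chosen so the
chain's heel point follows a prescribed heel-height curve with its minimum
exactly at initial contact.  The shoe-mounted sensor point is rigidly
attached to the foot segment; its world position is differentiated twice
(high-order central differences on the closed-form trajectory), gravity is
added, and the specific force is rotated into the foot-fixed sensor frame.
Accelerometer output is therefore specific force in m/s^2, gravity
included, as a real shoe-mounted accelerometer measures.

The stride period is quantised to an integer number of samples so that a
noiseless trial is exactly stride-periodic sample-for-sample; initial
contacts fall on exact sample indices, which the record stores as ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Six discrete gait events, in canonical order.  Extension / plantarflexion
# events are magnitudes of negative angles (flexion / dorsiflexion positive);
# the ankle angle at initial contact is signed.
EVENT_NAMES = (
    "hip_peak_flexion",
    "hip_peak_extension",
    "knee_peak_flexion_stance",
    "ankle_peak_dorsiflexion",
    "ankle_peak_plantarflexion",
    "ankle_angle_at_ic",
)

# Population event statistics (deg): mean, between-participant SD.
DEFAULT_CALIBRATION_TARGETS: dict[str, tuple[float, float]] = {
    "hip_peak_flexion": (27.6, 7.3),
    "hip_peak_extension": (15.3, 3.9),
    "knee_peak_flexion_stance": (30.1, 6.4),
    "ankle_peak_dorsiflexion": (12.8, 3.6),
    "ankle_peak_plantarflexion": (21.4, 5.0),
    "ankle_angle_at_ic": (2.2, 3.1),
}

SUPPORTED_SPEEDS = (6.0, 16.0)   # km/h range the waveform model covers
REFERENCE_SPEED = 10.0           # km/h at which cadence_base applies
CADENCE_SLOPE = 0.025            # relative stride-rate increase per km/h
GRAVITY = 9.80665                # m/s^2

# Foot-frame geometry of the shoe-mounted sensor and the heel point (m).
_SENSOR_FWD, _SENSOR_UP = 0.08, 0.04
_HEEL_BACK, _HEEL_DOWN = 0.06, 0.07
_PELVIS_SWAY = 0.02              # horizontal pelvis oscillation amplitude (m)

_GRID = np.linspace(0.0, 1.0, 100_001, endpoint=False)  # calibration grid
_IC_KAPPA = 80.0                 # concentration of the at-IC adjustment bump


def _bump(phi: np.ndarray, center: float, kappa: float) -> np.ndarray:
    """Smooth periodic bump, peak 1 at ``center``, width ~1/(2*pi*sqrt(kappa))."""
    return np.exp(kappa * (np.cos(2.0 * np.pi * (phi - center)) - 1.0))


# ---------------------------------------------------------------------------
# Waveforms.  Each takes stride phase phi in [0, 1) (phi = 0 at initial
# contact) and the calibrated parameter dict stored on the profile.
# ---------------------------------------------------------------------------

def _hip_raw(phi, p):
    return np.cos(2 * np.pi * (phi - p["phase"])) + p["h2_amp"] * np.cos(
        4 * np.pi * (phi - p["h2_phase"]))


def _hip_angle(phi, p):
    return p["scale"] * _hip_raw(phi, p) + p["offset"]


def _knee_raw(phi, p, a_st):
    return (p["baseline"]
            + a_st * _bump(phi, p["stance_center"], p["stance_kappa"])
            + p["swing_amp"] * _bump(phi, p["swing_center"], p["swing_kappa"]))


def _knee_angle(phi, p):
    return _knee_raw(phi, p, p["a_st"])


def _ankle_raw(phi, p):
    return (_bump(phi, p["df_center"], p["df_kappa"])
            - p["pf_weight"] * _bump(phi, p["pf_center"], p["pf_kappa"]))


def _ankle_angle(phi, p):
    base = p["scale"] * _ankle_raw(phi, p) + p["offset"]
    return base + p["ic_delta"] * _bump(phi, 0.0, _IC_KAPPA)


def _heel_height_mm(phi, p):
    # Minimum exactly at phi = 0 (initial contact).
    return p["heel_min"] + p["heel_amp"] * 0.5 * (1.0 - np.cos(2 * np.pi * phi))


@dataclass
class ParticipantProfile:
    """One synthetic runner: anthropometry, gait-waveform shape, event values.

    ``events`` holds the six discrete gait-event values this participant's
    angle waveforms are calibrated to reproduce exactly every stride
    (extension/plantarflexion as magnitudes, ankle angle at IC signed).
    """

    participant_id: str
    segment_lengths: dict[str, float]          # thigh/shank/foot (m)
    angle_waveform_params: dict[str, dict]     # per-joint calibrated params
    events: dict[str, float]
    cadence_base: float                        # strides/s at 10 km/h
    noise_sd: float                            # accelerometer noise (m/s^2)
    rng_seed: int

    def __post_init__(self):
        for name, length in self.segment_lengths.items():
            if not (np.isfinite(length) and length > 0):
                raise ValueError(f"segment length {name!r} must be positive")
        if not np.isfinite(self.cadence_base) or self.cadence_base <= 0:
            raise ValueError("cadence_base must be positive and finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def stride_frequency(self, speed: float) -> float:
        """Strides per second at a treadmill speed (km/h); increases with speed."""
        return self.cadence_base * (1.0 + CADENCE_SLOPE * (speed - REFERENCE_SPEED))

    def angle_curves(self, phi: np.ndarray) -> np.ndarray:
        """Hip/knee/ankle angles (deg) at stride phases ``phi`` -> (T, 3)."""
        p = self.angle_waveform_params
        return np.stack([
            _hip_angle(phi, p["hip"]),
            _knee_angle(phi, p["knee"]),
            _ankle_angle(phi, p["ankle"]),
        ], axis=-1)


@dataclass
class SynthConfig:
    """Cohort-level protocol settings (defaults mirror the study protocol)."""

    n_participants: int = 10
    speeds: tuple[float, ...] = (8.0, 9.0, 10.0, 11.0, 12.0)
    trials_per_speed: int = 3
    trial_duration: float = 60.0       # s
    sample_rate: float = 100.0         # Hz
    population_seed: int = 0
    noise_sd: float = 0.8              # accelerometer noise SD (m/s^2)
    stance_fraction: float = 0.4       # fraction of stride in stance
    calibration_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION_TARGETS))

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_speed < 1:
            raise ValueError("trials_per_speed must be >= 1")
        if self.trial_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("trial_duration and sample_rate must be positive")
        if not (0 < self.stance_fraction < 1):
            raise ValueError("stance_fraction must lie in (0, 1)")
        missing = set(EVENT_NAMES) - set(self.calibration_targets)
        if missing:
            raise ValueError(f"calibration_targets missing events: {sorted(missing)}")
        for s in self.speeds:
            if not SUPPORTED_SPEEDS[0] <= s <= SUPPORTED_SPEEDS[1]:
                raise ValueError(
                    f"speed {s} km/h outside supported range {SUPPORTED_SPEEDS}")


@dataclass
class TrialRecord:
    """One recording: sensor acceleration, reference angles, heel height.

    ``accel`` is specific force in the foot-fixed sensor frame (m/s^2,
    gravity included), columns (ax, ay, az) = (foot-forward, foot-normal,
    mediolateral).  ``angles`` columns are hip/knee/ankle in degrees with
    flexion / dorsiflexion positive.  ``true_ic_indices`` and
    ``true_events`` are simulator ground truth (absent for real data).
    """

    participant_id: str
    speed: float
    sample_rate: float
    t: np.ndarray
    accel: np.ndarray          # (T, 3)
    angles: np.ndarray         # (T, 3)
    heel_height: np.ndarray    # (T,) mm
    true_ic_indices: np.ndarray | None = None
    true_events: dict[str, float] | None = None
    trial_id: str = ""
    stride_samples: int | None = None
    noise_sd: float | None = None
    preprocessing: dict | None = None   # set by filter_trial

    def __post_init__(self):
        T = len(self.t)
        if not (self.accel.shape == (T, 3) and self.angles.shape == (T, 3)
                and self.heel_height.shape == (T,)):
            raise ValueError("accel/angles/heel_height lengths must match t")
        dt = np.diff(self.t)
        if T > 1 and not (np.all(dt > 0)
                          and np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-9, atol=1e-9)):
            raise ValueError("time vector must increase uniformly at 1/sample_rate")
        if not self.trial_id:
            self.trial_id = f"{self.participant_id}_v{self.speed:g}"

    @property
    def n_samples(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _draw_events(rng: np.random.Generator,
                 targets: dict[str, tuple[float, float]]) -> dict[str, float]:
    ev = {name: rng.normal(m, s) for name, (m, s) in targets.items()}
    # Physiologic guards.  Clipping probabilities are small at the default
    # targets, so population means stay within a fraction of a degree.
    ev["hip_peak_flexion"] = max(ev["hip_peak_flexion"], 8.0)
    ev["hip_peak_extension"] = max(ev["hip_peak_extension"], 3.0)
    ev["knee_peak_flexion_stance"] = max(ev["knee_peak_flexion_stance"], 12.0)
    ev["ankle_peak_dorsiflexion"] = max(ev["ankle_peak_dorsiflexion"], 3.0)
    ev["ankle_peak_plantarflexion"] = max(ev["ankle_peak_plantarflexion"], 6.0)
    ev["ankle_angle_at_ic"] = float(np.clip(
        ev["ankle_angle_at_ic"],
        -ev["ankle_peak_plantarflexion"] + 2.0,
        ev["ankle_peak_dorsiflexion"] - 1.0))
    return {k: float(v) for k, v in ev.items()}


def _calibrate_hip(p: dict, events: dict) -> None:
    raw = _hip_raw(_GRID, p)
    lo, hi = float(raw.min()), float(raw.max())
    p["scale"] = (events["hip_peak_flexion"] + events["hip_peak_extension"]) / (hi - lo)
    p["offset"] = events["hip_peak_flexion"] - p["scale"] * hi


def _calibrate_knee(p: dict, events: dict, stance_fraction: float) -> None:
    stance = _GRID[_GRID < stance_fraction]
    target = events["knee_peak_flexion_stance"]
    a = max(target - p["baseline"], 1.0)
    for _ in range(30):
        cur = float(_knee_raw(stance, p, a).max())
        if abs(cur - target) < 1e-10:
            break
        a += target - cur
    p["a_st"] = a


def _calibrate_ankle(p: dict, events: dict) -> None:
    raw = _ankle_raw(_GRID, p)
    lo, hi = float(raw.min()), float(raw.max())
    p["scale"] = (events["ankle_peak_dorsiflexion"]
                  + events["ankle_peak_plantarflexion"]) / (hi - lo)
    p["offset"] = events["ankle_peak_dorsiflexion"] - p["scale"] * hi
    at_ic = p["scale"] * float(_ankle_raw(np.array([0.0]), p)[0]) + p["offset"]
    # Localised correction so the angle at phi = 0 equals the configured
    # at-IC value; the bump is ~1e-10 at the DF/PF extrema so they move by
    # far less than the 1e-6 deg guarantee.
    p["ic_delta"] = events["ankle_angle_at_ic"] - at_ic


def generate_population(config: SynthConfig) -> list[ParticipantProfile]:
    """Draw a deterministic cohort of participant profiles.

    Event values are drawn per participant from the configured calibration
    targets (independent normals); waveform shape parameters are jittered
    around canonical running-gait timings and each profile's waveforms are
    then calibrated so its per-stride extrema equal its event values.
    """
    rng = np.random.default_rng(config.population_seed)
    profiles = []
    for i in range(config.n_participants):
        events = _draw_events(rng, config.calibration_targets)
        hip = {
            "phase": rng.normal(0.88, 0.02) % 1.0,
            "h2_amp": rng.uniform(0.05, 0.20),
            "h2_phase": rng.uniform(0.0, 1.0),
        }
        knee = {
            "baseline": rng.normal(10.0, 1.5),
            "stance_center": rng.normal(0.15, 0.015),
            "stance_kappa": rng.normal(5.0, 0.4),
            "swing_center": rng.normal(0.70, 0.02),
            "swing_kappa": rng.normal(4.0, 0.4),
            "swing_amp": rng.normal(50.0, 8.0),
        }
        knee["baseline"] = float(np.clip(knee["baseline"], 5.0, 15.0))
        knee["swing_amp"] = float(np.clip(knee["swing_amp"], 25.0, 80.0))
        ankle = {
            "df_center": float(np.clip(rng.normal(0.20, 0.02), 0.15, 0.26)),
            "df_kappa": rng.normal(5.0, 0.4),
            "pf_center": float(np.clip(rng.normal(0.40, 0.02), 0.33, 0.48)),
            "pf_kappa": rng.normal(6.0, 0.4),
            "pf_weight": rng.uniform(0.8, 1.2),
        }
        heel = {
            "heel_min": rng.uniform(20.0, 40.0),     # mm
            "heel_amp": rng.uniform(200.0, 300.0),   # mm
        }
        misc = {
            "pelvis_phase": rng.uniform(0.0, 1.0),
            "ml_amp": rng.uniform(1.0, 3.0),         # mediolateral accel (m/s^2)
            "ml_phase": rng.uniform(0.0, 1.0),
        }
        _calibrate_hip(hip, events)
        _calibrate_knee(knee, events, config.stance_fraction)
        _calibrate_ankle(ankle, events)
        profiles.append(ParticipantProfile(
            participant_id=f"P{i + 1:02d}",
            segment_lengths={
                "thigh": float(np.clip(rng.normal(0.42, 0.02), 0.35, 0.50)),
                "shank": float(np.clip(rng.normal(0.42, 0.02), 0.35, 0.50)),
                "foot": float(np.clip(rng.normal(0.25, 0.01), 0.20, 0.30)),
            },
            angle_waveform_params={
                "hip": hip, "knee": knee, "ankle": ankle,
                "heel": heel, "misc": misc,
            },
            events=events,
            cadence_base=float(np.clip(rng.normal(1.40, 0.06), 1.20, 1.60)),
            noise_sd=config.noise_sd,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _stride_samples(profile: ParticipantProfile, speed: float,
                    sample_rate: float) -> int:
    """Stride period quantised to whole samples (exact periodicity)."""
    P = int(round(sample_rate / profile.stride_frequency(speed)))
    if P < 8:
        raise ValueError("sample rate too low to resolve a stride")
    return P


def _chain_positions(profile: ParticipantProfile, phi: np.ndarray):
    """World positions of sensor and heel points for stride phases ``phi``.

    The pelvis vertical trajectory is chosen so that the heel point of the
    thigh–shank–foot chain follows the prescribed heel-height curve, whose
    minimum sits exactly at phi = 0 (initial contact).
    Returns (sensor_xy (T,2), heel_xy (T,2), foot_pitch (T,)).
    """
    p = profile.angle_waveform_params
    L = profile.segment_lengths
    ang = np.deg2rad(profile.angle_curves(phi))
    alpha_t = ang[:, 0]                    # thigh from vertical, forward +
    alpha_s = ang[:, 0] - ang[:, 1]        # shank
    pitch = alpha_s + ang[:, 2]            # foot pitch from horizontal, toes-up +

    cos_p, sin_p = np.cos(pitch), np.sin(pitch)
    pelvis_x = _PELVIS_SWAY * np.sin(2 * np.pi * (phi - p["misc"]["pelvis_phase"]))
    # Vertical drop pelvis -> heel with pelvis at height zero:
    knee_y0 = -L["thigh"] * np.cos(alpha_t)
    ankle_y0 = knee_y0 - L["shank"] * np.cos(alpha_s)
    heel_y0 = ankle_y0 + (-sin_p * (-_HEEL_BACK) + cos_p * (-_HEEL_DOWN))
    pelvis_y = _heel_height_mm(phi, p["heel"]) / 1000.0 - heel_y0

    knee_x = pelvis_x + L["thigh"] * np.sin(alpha_t)
    ankle_x = knee_x + L["shank"] * np.sin(alpha_s)
    ankle_y = pelvis_y + ankle_y0
    sensor = np.stack([
        ankle_x + cos_p * _SENSOR_FWD - sin_p * _SENSOR_UP,
        ankle_y + sin_p * _SENSOR_FWD + cos_p * _SENSOR_UP,
    ], axis=-1)
    heel = np.stack([
        ankle_x + cos_p * (-_HEEL_BACK) - sin_p * (-_HEEL_DOWN),
        ankle_y + sin_p * (-_HEEL_BACK) + cos_p * (-_HEEL_DOWN),
    ], axis=-1)
    return sensor, heel, pitch


def world_kinematics(profile: ParticipantProfile, speed: float,
                     duration: float, sample_rate: float):
    """Noise-free world-frame sensor kinematics for a trial.

    Returns ``(t, sensor_pos, sensor_acc, foot_pitch, phi)`` where
    ``sensor_pos`` (T, 2) is the sensor point's world position (m),
    ``sensor_acc`` its world acceleration (m/s^2, gravity NOT included)
    obtained by fourth-order central differencing of the closed-form
    trajectory, and ``foot_pitch`` (rad) the foot-segment orientation.
    """
    P = _stride_samples(profile, speed, sample_rate)
    T = int(round(duration * sample_rate))
    i0 = P // 2
    idx = np.arange(T)
    phi = ((idx - i0) % P) / P             # exact per-residue phases

    def pos_at(t_shift: float) -> np.ndarray:
        s = idx + t_shift * sample_rate
        ph = ((s - i0) % P) / P
        return _chain_positions(profile, ph)[0]

    h = 1e-3                               # stencil step (s)
    acc = (-pos_at(2 * h) + 16 * pos_at(h) - 30 * pos_at(0.0)
           + 16 * pos_at(-h) - pos_at(2 * -h)) / (12 * h * h)
    sensor, _, pitch = _chain_positions(profile, phi)
    t = idx / sample_rate
    return t, sensor, acc, pitch, phi


def simulate_trial(profile: ParticipantProfile, speed: float,
                   duration: float = 60.0, sample_rate: float = 100.0,
                   trial_index: int = 0, seed: int | None = None) -> TrialRecord:
    """Simulate one treadmill trial for a participant.

    ``seed`` overrides the noise stream; by default it is derived
    deterministically from ``(profile.rng_seed, trial_index, speed)`` so the
    same call is bitwise reproducible while distinct trials get independent
    noise.
    """
    if not (np.isfinite(duration) and duration > 0):
        raise ValueError("duration must be positive and finite")
    if not (np.isfinite(sample_rate) and sample_rate > 0):
        raise ValueError("sample_rate must be positive and finite")
    if not (SUPPORTED_SPEEDS[0] <= speed <= SUPPORTED_SPEEDS[1]):
        raise ValueError(f"speed {speed} km/h outside supported range {SUPPORTED_SPEEDS}")
    for joint, prm in profile.angle_waveform_params.items():
        for key, val in prm.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite waveform parameter {joint}.{key}")

    t, _, acc_w, pitch, phi = world_kinematics(profile, speed, duration, sample_rate)
    P = _stride_samples(profile, speed, sample_rate)
    T = len(t)
    i0 = P // 2

    angles = profile.angle_curves(phi)
    heel_mm = _heel_height_mm(phi, profile.angle_waveform_params["heel"])

    # Specific force in the foot-fixed sensor frame (gravity included).
    f_w = acc_w - np.array([0.0, -GRAVITY])
    cos_p, sin_p = np.cos(pitch), np.sin(pitch)
    ax = f_w[:, 0] * cos_p + f_w[:, 1] * sin_p       # foot-forward axis
    ay = -f_w[:, 0] * sin_p + f_w[:, 1] * cos_p      # foot-normal axis
    misc = profile.angle_waveform_params["misc"]
    az = misc["ml_amp"] * np.sin(4 * np.pi * (phi - misc["ml_phase"]))
    accel = np.stack([ax, ay, az], axis=-1)

    if profile.noise_sd > 0:
        if seed is None:
            ss = np.random.SeedSequence(
                [profile.rng_seed, trial_index, int(round(speed * 1000))])
        else:
            ss = np.random.SeedSequence(seed)
        accel = accel + np.random.default_rng(ss).normal(
            0.0, profile.noise_sd, size=accel.shape)

    return TrialRecord(
        participant_id=profile.participant_id,
        speed=float(speed),
        sample_rate=float(sample_rate),
        t=t,
        accel=accel,
        angles=angles,
        heel_height=heel_mm,
        true_ic_indices=np.arange(i0, T, P),
        true_events=dict(profile.events),
        trial_id=f"{profile.participant_id}_v{speed:g}_t{trial_index}",
        stride_samples=P,
        noise_sd=profile.noise_sd,
    )


def ground_truth_events(trial: TrialRecord):
    """Analytically known per-stride gait-event values of a synthetic trial.

    The generating waveforms are calibrated so every stride attains exactly
    the profile's configured event values; this returns those values, one
    per complete stride, as the oracle for event-detection code.
    """
    from .evaluation import GaitEvents

    if trial.true_events is None or trial.true_ic_indices is None:
        raise ValueError("trial carries no simulator ground truth")
    ics = np.asarray(trial.true_ic_indices)
    n_strides = len(ics) - 1
    if n_strides < 1:
        raise ValueError("trial too short: no complete stride")
    const = {name: np.full(n_strides, trial.true_events[name])
             for name in EVENT_NAMES}
    return GaitEvents(ic_index=ics[:-1], **const)


# ---------------------------------------------------------------------------
# Trial file I/O: CSV + key-value sidecar
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("t", "ax", "ay", "az", "hip", "knee", "ankle", "heel_height")


def write_trial(trial: TrialRecord, out_dir) -> tuple[str, str]:
    """Write a trial as ``<trial_id>.csv`` plus ``<trial_id>.meta.txt``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    csv_path = os.path.join(out_dir, f"{trial.trial_id}.csv")
    meta_path = os.path.join(out_dir, f"{trial.trial_id}.meta.txt")
    df = pd.DataFrame(
        np.column_stack([trial.t, trial.accel, trial.angles, trial.heel_height]),
        columns=_CSV_COLUMNS)
    df.to_csv(csv_path, index=False, float_format="%.6f")
    lines = [
        f"participant_id: {trial.participant_id}",
        f"speed: {trial.speed:g}",
        f"sample_rate: {trial.sample_rate:g}",
        f"trial_id: {trial.trial_id}",
    ]
    if trial.stride_samples is not None:
        lines.append(f"stride_samples: {trial.stride_samples}")
    if trial.noise_sd is not None:
        lines.append(f"noise_sd: {trial.noise_sd:g}")
    if trial.true_ic_indices is not None:
        lines.append("true_ic_indices: "
                     + ",".join(str(int(i)) for i in trial.true_ic_indices))
    if trial.true_events is not None:
        for name in EVENT_NAMES:
            lines.append(f"event.{name}: {trial.true_events[name]:.10g}")
    with open(meta_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return csv_path, meta_path


def read_trial(csv_path) -> TrialRecord:
    """Read a trial written by :func:`write_trial` (or any file in its schema)."""
    import os

    df = pd.read_csv(csv_path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file missing columns: {sorted(missing)}")
    meta_path = str(csv_path)[:-4] + ".meta.txt"
    meta: dict[str, str] = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            for line in fh:
                if ":" in line:
                    key, val = line.split(":", 1)
                    meta[key.strip()] = val.strip()
    t = df["t"].to_numpy()
    sample_rate = float(meta.get("sample_rate",
                                 1.0 / np.median(np.diff(t)) if len(t) > 1 else 100.0))
    events = {name: float(meta[f"event.{name}"])
              for name in EVENT_NAMES if f"event.{name}" in meta}
    ics = None
    if "true_ic_indices" in meta and meta["true_ic_indices"]:
        ics = np.array([int(s) for s in meta["true_ic_indices"].split(",")])
    return TrialRecord(
        participant_id=meta.get("participant_id", "unknown"),
        speed=float(meta.get("speed", float("nan"))),
        sample_rate=round(sample_rate, 6),
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(),
        angles=df[["hip", "knee", "ankle"]].to_numpy(),
        heel_height=df["heel_height"].to_numpy(),
        true_ic_indices=ics,
        true_events=events or None,
        trial_id=meta.get("trial_id", os.path.splitext(os.path.basename(csv_path))[0]),
        stride_samples=int(meta["stride_samples"]) if "stride_samples" in meta else None,
        noise_sd=float(meta["noise_sd"]) if "noise_sd" in meta else None,
    )
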