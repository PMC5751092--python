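"""Seeded simulator of multi-channel orthosis recordings.

The generator emulates a laboratory protocol in which instrumented subjects
wearing a knee-ankle-foot orthosis perform scripted 60 s trials: quiet
sitting in five different initial leg positions, standing, treadmill walking
at three speeds, and sit-to-stand (SiSt) / stand-to-sit (StSi) transitions.
Fourteen channels are produced at 500 Hz: a three-axis accelerometer and a
two-axis gyroscope on each of the thigh and shank, knee and ankle
potentiometers, and heel/toe insole force sensors.

Kinematics are deliberately simple: each body segment carries an
inclination-from-vertical angle; accelerometers output the gravity
projection on their axes (units of g) plus a small motion term, Gaussian
noise and slow baseline drift; gyroscopes output the segment angular
velocity plus noise; forces ramp between a seated baseline and a
body-weight-proportional standing load and oscillate during gait.  The knee
follows a logistic trajectory between the position-dependent seated angle
and the standing angle during every transition, so the 45-degree midpoint
annotation rule applies to every SiSt event.  Ground truth (transition
intervals and a per-sample posture code) is recorded exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

__all__ = [
    "CHANNELS",
    "KNEE_CHANNEL",
    "POSTURE_CODES",
    "SubjectParams",
    "SensorTrial",
    "knee_trajectory",
    "simulate_trial",
    "simulate_dataset",
    "default_subject",
    "write_trial",
    "read_trial",
]

CHANNELS = [
    "thigh_acc_x", "thigh_acc_y", "thigh_acc_z",
    "thigh_gyro_pitch", "thigh_gyro_roll",
    "shank_acc_x", "shank_acc_y", "shank_acc_z",
    "shank_gyro_pitch", "shank_gyro_roll",
    "knee_angle", "ankle_angle",
    "heel_force", "toe_force",
]
KNEE_CHANNEL = CHANNELS.index("knee_angle")
ANKLE_CHANNEL = CHANNELS.index("ankle_angle")

POSTURE_CODES = {"sit": 0, "stand": 1, "walk": 2, "transition": 3}
POSTURE_NAMES = {v: k for k, v in POSTURE_CODES.items()}

SAMPLE_RATE = 500
TRIAL_SECONDS = 60

#: standing knee flexion, degrees
STANDING_ANGLE = 5.0
#: seated knee angle used for the SiSt trajectory when the legs start fully
#: extended (position 0); keeps the 45-degree rule inside the transition
EXTENDED_TRANSITION_ANGLE = 50.0  # floor of any SiSt start angle (deg)
#: logistic steepness divisor: s = duration / LOGISTIC_STEEPNESS
LOGISTIC_STEEPNESS = 9.2

#: duration scale factors for normal-speed vs "fast transition" activities;
#: the 15:10 normal:fast SiSt trial mix per subject makes the dataset mean
#: equal the subject's transition_duration_mean exactly
NORMAL_DURATION_SCALE = 1.2
FAST_DURATION_SCALE = 0.7
#: symmetric half-width of the truncation interval around the subject mean
DURATION_TRUNC_HALFWIDTH = 0.58

#: fraction of standing foot load carried while seated
SEATED_LOAD_FRACTION = 0.15

#: activities whose script begins or ends seated (require a position id)
SEATED_ACTIVITIES = frozenset({1, 2, 3, 4, 6, 7, 8})
#: activities repeated once per initial seated position in the protocol
POSITIONAL_ACTIVITIES = (2, 3, 4, 6, 7, 8)
#: activities performed once per subject
SINGLE_ACTIVITIES = (1, 5, 9, 10)
FAST_ACTIVITIES = frozenset({6, 7})

DEFAULT_SEATED_ANGLES = {0: 50.0, 1: 110.0, 2: 90.0, 3: 90.0, 4: 90.0}
DEFAULT_CADENCE = {"slow": 95.0, "normal": 110.0, "fast": 125.0}
DEFAULT_NOISE = {
    "accel": 0.05,   # g
    "gyro": 5.0,     # deg/s
    "pot": 0.5,      # deg
    "force": 2.0,    # N
}


@dataclass
class SubjectParams:
    """Per-subject generative parameters."""

    subject_id: int
    body_mass: float = 65.77
    seated_knee_angle_by_position: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SEATED_ANGLES))
    transition_duration_mean: float = 1.30
    transition_duration_sd: float = 0.30
    gait_cadence_by_speed: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CADENCE))
    noise_sd_per_channel: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE))

    def __post_init__(self) -> None:
        if self.transition_duration_mean <= 0:
            raise ValueError("transition_duration_mean must be positive")
        if any(v < 0 for v in self.noise_sd_per_channel.values()):
            raise ValueError("noise SDs must be non-negative")
        if sorted(self.seated_knee_angle_by_position) != [0, 1, 2, 3, 4]:
            raise ValueError("exactly five seated positions (0-4) required")


@dataclass
class SensorTrial:
    """One 60 s, 14-channel recording with exact ground truth."""

    subject_id: int
    activity_id: int
    position_id: int | None
    sample_rate: int
    signal: np.ndarray                      # 14 x T
    truth_transitions: list[tuple[int, int, str]]  # (onset, offset, kind)
    truth_posture: np.ndarray               # per-sample int code

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def has_sist(self) -> bool:
        return any(kind == "SiSt" for _, _, kind in self.truth_transitions)

    def sist_intervals(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, kind in self.truth_transitions if kind == "SiSt"]


def default_subject(subject_id: int = 0) -> SubjectParams:
    """A subject at the population means, handy for examples and tests."""
    return SubjectParams(subject_id=subject_id)


def knee_trajectory(duration_s: float, seated_angle_deg: float,
                    standing_angle_deg: float, sample_rate: int) -> np.ndarray:
    """Logistic knee-angle trajectory of a single SiSt transition.

    Monotone non-increasing, crossing the midpoint angle
    ``(seated + standing) / 2`` exactly at ``duration / 2``.  The steepness
    is tied to the duration so the end points come within 1 degree of the
    seated and standing angles.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if seated_angle_deg <= standing_angle_deg:
        raise ValueError("seated angle must exceed standing angle")
    p = _logistic_progress(int(round(duration_s * sample_rate)), sample_rate)
    return standing_angle_deg + (seated_angle_deg - standing_angle_deg) * p


def _logistic_progress(n: int, sample_rate: int) -> np.ndarray:
    """Progress variable of a transition: exactly 1 at the seated end and 0
    at the standing end (the raw logistic is rescaled so segments join the
    neighbouring postures without a step)."""
    duration_s = n / sample_rate
    t = np.arange(n) / sample_rate
    s = duration_s / LOGISTIC_STEEPNESS
    p = 1.0 / (1.0 + np.exp((t - duration_s / 2.0) / s))
    return (p - p[-1]) / (p[0] - p[-1])


def _smoothstep(n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    return u * u * (3.0 - 2.0 * u)


def _draw_duration(subject: SubjectParams, scale: float,
                   rng: np.random.Generator) -> float:
    """Transition duration: truncated normal around the subject mean, scaled
    by the activity speed class."""
    mu = subject.transition_duration_mean
    sd = subject.transition_duration_sd
    lo, hi = mu - DURATION_TRUNC_HALFWIDTH, mu + DURATION_TRUNC_HALFWIDTH
    a, b = (lo - mu) / sd, (hi - mu) / sd
    base = truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
    return float(base * scale)


def _walking_speed(activity_id: int) -> str:
    if activity_id == 9:
        return "slow"
    if activity_id in (7, 10):
        return "fast"
    return "normal"


# ---------------------------------------------------------------------------
# activity scripts


def _build_segments(activity_id: int, d_sist: float,
                    d_stsi: float) -> list[tuple[str, float]]:
    """Return the (kind, duration) script of one trial.

    Kinds: sit, stand, walk, sist, stsi.  SiSt events start at t = 20 s and
    StSi events at t = 40 s for every scripted activity that contains them.
    """

    def sit_then_sist() -> list[tuple[str, float]]:
        return [("sit", 20.0), ("sist", d_sist)]

    def stsi_then_sit() -> list[tuple[str, float]]:
        return [("stsi", d_stsi), ("sit", 20.0 - d_stsi)]

    if activity_id == 1:
        return [("sit", 60.0)]
    if activity_id in (5, 9, 10):
        return [("walk", 60.0)]
    if activity_id in (2, 6):
        return (sit_then_sist()
                + [("stand", 20.0 - d_sist)]
                + stsi_then_sit())
    if activity_id in (3, 7):
        return (sit_then_sist()
                + [("stand", 4.0 - d_sist), ("walk", 12.0), ("stand", 4.0)]
                + stsi_then_sit())
    if activity_id == 4:
        return (sit_then_sist()
                + [("stand", 12.0 - d_sist), ("walk", 6.0), ("stand", 2.0)]
                + stsi_then_sit())
    if activity_id == 8:
        return ([("stand", 20.0), ("walk", 18.0), ("stand", 2.0)]
                + stsi_then_sit())
    raise ValueError(f"unknown activity_id {activity_id}")


def simulate_trial(subject: SubjectParams, activity_id: int,
                   position_id: int | None = None, seed: int = 0,
                   sample_rate: int = SAMPLE_RATE) -> SensorTrial:
    """Simulate one 60 s trial of the scripted protocol.

    ``position_id`` selects the initial seated leg position (0-4) and is
    required for every activity that begins or ends seated.
    """
    if activity_id not in range(1, 11):
        raise ValueError(f"unknown activity_id {activity_id}")
    seated_activity = activity_id in SEATED_ACTIVITIES
    if seated_activity and position_id is None:
        raise ValueError(
            f"activity {activity_id} begins or ends seated; position_id required")
    if position_id is not None and position_id not in range(5):
        raise ValueError(f"position_id must be in 0..4, got {position_id}")

    rng = np.random.default_rng(seed)
    T = sample_rate * TRIAL_SECONDS

    scale = FAST_DURATION_SCALE if activity_id in FAST_ACTIVITIES \
        else NORMAL_DURATION_SCALE
    d_sist = _draw_duration(subject, scale, rng)
    d_stsi = _draw_duration(subject, scale, rng)

    if seated_activity:
        seated_angle = subject.seated_knee_angle_by_position[position_id]
    else:
        seated_angle = STANDING_ANGLE  # unused
    transition_angle = max(seated_angle, EXTENDED_TRANSITION_ANGLE)

    segments = _build_segments(activity_id, d_sist, d_stsi)

    cadence = subject.gait_cadence_by_speed[_walking_speed(activity_id)]
    stride_hz = cadence / 60.0 / 2.0  # two steps per stride

    knee = np.empty(T)
    thigh = np.empty(T)     # thigh inclination from vertical, deg
    load = np.empty(T)      # foot load fraction of standing weight
    env = np.zeros(T)       # gait oscillation envelope
    phase = np.zeros(T)     # gait phase, rad
    posture = np.empty(T, dtype=np.int8)
    transitions: list[tuple[int, int, str]] = []

    t_axis = np.arange(T) / sample_rate
    pos = 0
    for kind, dur in segments:
        n = int(round(dur * sample_rate))
        n = min(n, T - pos)
        if n <= 0:
            continue
        sl = slice(pos, pos + n)
        tt = t_axis[sl]
        if kind == "sit":
            knee[sl] = seated_angle + 0.3 * np.sin(2 * np.pi * 0.1 * tt)
            thigh[sl] = 90.0 + 0.5 * np.sin(2 * np.pi * 0.08 * tt)
            load[sl] = SEATED_LOAD_FRACTION
            posture[sl] = POSTURE_CODES["sit"]
        elif kind == "sist":
            p = _logistic_progress(n, sample_rate)
            knee[sl] = STANDING_ANGLE + (transition_angle - STANDING_ANGLE) * p
            thigh[sl] = 5.0 + 85.0 * p
            load[sl] = SEATED_LOAD_FRACTION + (1.0 - SEATED_LOAD_FRACTION) * (1.0 - p)
            posture[sl] = POSTURE_CODES["transition"]
            transitions.append((pos, pos + n, "SiSt"))
        elif kind == "stsi":
            q = 1.0 - _logistic_progress(n, sample_rate)  # rises 0 -> 1
            knee[sl] = STANDING_ANGLE + (transition_angle - STANDING_ANGLE) * q
            thigh[sl] = 5.0 + 85.0 * q
            load[sl] = 1.0 - (1.0 - SEATED_LOAD_FRACTION) * q
            posture[sl] = POSTURE_CODES["transition"]
            transitions.append((pos, pos + n, "StSi"))
        elif kind == "stand":
            knee[sl] = STANDING_ANGLE + 0.3 * np.sin(2 * np.pi * 0.12 * tt)
            thigh[sl] = 5.0 + 0.5 * np.sin(2 * np.pi * 0.1 * tt)
            load[sl] = 1.0
            posture[sl] = POSTURE_CODES["stand"]
        elif kind == "walk":
            ramp = int(round(0.5 * sample_rate))
            e = np.ones(n)
            r = min(ramp, n // 2)
            if r > 0:
                e[:r] = _smoothstep(r)
                e[-r:] = _smoothstep(r)[::-1]
            ph = 2 * np.pi * stride_hz * (tt - tt[0])
            swing = 0.5 - 0.5 * np.cos(ph)
            knee[sl] = STANDING_ANGLE + 30.0 * e * swing
            thigh[sl] = 5.0 + 12.0 * e * swing
            load[sl] = 1.0 - 0.8 * e * swing
            env[sl] = e
            phase[sl] = ph
            posture[sl] = POSTURE_CODES["walk"]
        else:  # pragma: no cover
            raise RuntimeError(f"unhandled segment kind {kind}")
        pos += n
    if pos < T:  # numerical remainder: extend the final posture
        knee[pos:] = knee[pos - 1]
        thigh[pos:] = thigh[pos - 1]
        load[pos:] = load[pos - 1]
        posture[pos:] = posture[pos - 1]

    signal = _render_channels(subject, knee, thigh, load, env, phase,
                              sample_rate, rng)
    return SensorTrial(
        subject_id=subject.subject_id,
        activity_id=activity_id,
        position_id=position_id if seated_activity else None,
        sample_rate=sample_rate,
        signal=signal,
        truth_transitions=transitions,
        truth_posture=posture,
    )


def _render_channels(subject: SubjectParams, knee: np.ndarray,
                     thigh: np.ndarray, load: np.ndarray, env: np.ndarray,
                     phase: np.ndarray, sample_rate: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Turn the kinematic timeline into the 14 sensor channels."""
    T = knee.size
    t = np.arange(T) / sample_rate
    noise = subject.noise_sd_per_channel
    d2r = np.pi / 180.0

    shank = knee - thigh                      # shank inclination from vertical
    gyro_thigh = np.gradient(thigh) * sample_rate   # deg/s
    gyro_shank = np.gradient(shank) * sample_rate

    def accel_triplet(incl_deg: np.ndarray, gyro: np.ndarray,
                      phase_off: float) -> list[np.ndarray]:
        drift = 0.01 * np.sin(2 * np.pi * 0.07 * t + phase_off)
        gait_x = 0.12 * env * np.sin(2 * phase + phase_off)
        gait_y = 0.05 * env * np.sin(phase + phase_off)
        ax = np.sin(incl_deg * d2r) + 0.001 * gyro + gait_x + drift
        ay = gait_y + drift
        az = np.cos(incl_deg * d2r) + 0.5 * gait_x + drift
        return [a + rng.normal(0.0, noise["accel"], T) for a in (ax, ay, az)]

    leg_weight_n = 0.5 * subject.body_mass * 9.81   # per instrumented leg
    heel = leg_weight_n * 0.6 * (load + 0.35 * env * np.cos(phase))
    toe = leg_weight_n * 0.4 * (load + 0.35 * env * np.cos(phase + 2.5))

    channels = (
        accel_triplet(thigh, gyro_thigh, 0.0)
        + [gyro_thigh + rng.normal(0.0, noise["gyro"], T),
           3.0 * env * np.sin(phase + 0.7) + rng.normal(0.0, noise["gyro"], T)]
        + accel_triplet(shank, gyro_shank, 1.9)
        + [gyro_shank + rng.normal(0.0, noise["gyro"], T),
           3.0 * env * np.sin(phase + 2.3) + rng.normal(0.0, noise["gyro"], T)]
        + [np.clip(knee + rng.normal(0.0, noise["pot"], T), -5.0, 130.0),
           90.0 + 3.0 * env * np.sin(phase + 1.2) + rng.normal(0.0, noise["pot"], T),
           np.clip(heel + rng.normal(0.0, noise["force"], T), 0.0, None),
           np.clip(toe + rng.normal(0.0, noise["force"], T), 0.0, None)]
    )
    return np.vstack(channels)


def simulate_dataset(n_subjects: int, seed: int = 0,
                     activities: list[int] | None = None,
                     positions: list[int] | None = None) -> list[SensorTrial]:
    """Simulate the full 34-trial protocol for ``n_subjects`` subjects.

    Per subject: activities 2, 3, 4, 6, 7 and 8 once per each of the five
    initial seated positions, plus activities 1, 5, 9 and 10 once each.
    ``activities``/``positions`` restrict the protocol to a subset (used for
    scaled-down runs); the default is the full protocol.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    act_filter = set(activities) if activities is not None else None
    pos_filter = set(positions) if positions is not None else None

    master = np.random.default_rng(seed)
    trials: list[SensorTrial] = []
    for sid in range(n_subjects):
        subject = _draw_subject(sid, master)
        plan: list[tuple[int, int | None]] = []
        for act in POSITIONAL_ACTIVITIES:
            for p in range(5):
                plan.append((act, p))
        for act in SINGLE_ACTIVITIES:
            # the pure-sitting trial still needs a leg position; the
            # protocol does not vary it, so the conventional 90-degree
            # position is used
            plan.append((act, 2 if act in SEATED_ACTIVITIES else None))
        for act, p in plan:
            trial_seed = int(master.integers(0, 2**31 - 1))
            if act_filter is not None and act not in act_filter:
                continue
            if pos_filter is not None and p is not None and p not in pos_filter:
                continue
            trials.append(simulate_trial(subject, act, p, seed=trial_seed))
    return trials


def _draw_subject(subject_id: int, rng: np.random.Generator) -> SubjectParams:
    """Subject parameters around the study population statistics."""
    angles = {
        p: float(np.clip(a + rng.normal(0.0, 2.0), None,
                         125.0))
        for p, a in DEFAULT_SEATED_ANGLES.items()
    }
    angles[0] = float(np.clip(angles[0], 50.0, 58.0))
    cadence = {k: float(v + rng.normal(0.0, 4.0))
               for k, v in DEFAULT_CADENCE.items()}
    return SubjectParams(
        subject_id=subject_id,
        body_mass=float(np.clip(rng.normal(65.77, 10.0), 45.0, 95.0)),
        seated_knee_angle_by_position=angles,
        transition_duration_mean=float(rng.normal(1.30, 0.05)),
        transition_duration_sd=0.30,
        gait_cadence_by_speed=cadence,
    )


# ---------------------------------------------------------------------------
# trial I/O: one CSV per trial plus a JSON sidecar with metadata and truth

def write_trial(trial: SensorTrial, directory: str | Path,
                stem: str | None = None) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stem is None:
        pos = "x" if trial.position_id is None else trial.position_id
        stem = f"s{trial.subject_id:02d}_a{trial.activity_id:02d}_p{pos}"
    csv_path = directory / f"{stem}.csv"
    json_path = directory / f"{stem}.json"
    pd.DataFrame(trial.signal.T, columns=CHANNELS).to_csv(csv_path, index=False)
    meta = {
        "subject_id": trial.subject_id,
        "activity_id": trial.activity_id,
        "position_id": trial.position_id,
        "sample_rate": trial.sample_rate,
        "truth_transitions": [[int(a), int(b), kind]
                              for a, b, kind in trial.truth_transitions],
        "truth_posture_rle": _rle_encode(trial.truth_posture),
    }
    json_path.write_text(json.dumps(meta))
    return csv_path, json_path


def read_trial(csv_path: str | Path) -> SensorTrial:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    frame = pd.read_csv(csv_path)
    if list(frame.columns) != CHANNELS:
        raise ValueError("channel header does not match the expected layout")
    return SensorTrial(
        subject_id=meta["subject_id"],
        activity_id=meta["activity_id"],
        position_id=meta["position_id"],
        sample_rate=meta["sample_rate"],
        signal=frame.to_numpy().T,
        truth_transitions=[(a, b, kind) for a, b, kind in meta["truth_transitions"]],
        truth_posture=_rle_decode(meta["truth_posture_rle"]),
    )


def _rle_encode(codes: np.ndarray) -> list[list[int]]:
    out: list[list[int]] = []
    start = 0
    for i in range(1, codes.size + 1):
        if i == codes.size or codes[i] != codes[start]:
            out.append([int(start), int(i), int(codes[start])])
            start = i
    return out


def _rle_decode(runs: list[list[int]]) -> np.ndarray:
    total = runs[-1][1]
    codes = np.empty(total, dtype=np.int8)
    for a, b, c in runs:
        codes[a:b] = c
    return codes
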