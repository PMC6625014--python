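"""Synthetic articulated gait over a non-steady-state locomotor circuit.

A purely kinematic 12-segment walker: the pelvis root follows a circuit
path (level ground, a 4-step stair with 0.15 m rise / 0.30 m run, a turn,
a 10 degree ramp), limbs are driven by phase-locked periodic joint
patterns, and every marker is rigidly attached to a segment frame, so the
emitted trajectories are exactly consistent with the ground-truth segment
poses. No ground-reaction forces or contact constraints are modeled; the
goal is realistic signal structure and bandwidth (dominant content well
below 6 Hz), not physiological fidelity.

All randomness flows from a single integer seed per trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .body_model import MarkerSeries

__all__ = [
    "AnthropometricProfile",
    "TaskSegment",
    "CircuitSpec",
    "GaitStyle",
    "SyntheticTrial",
    "default_circuit",
    "generate_trial",
    "make_cohort",
    "pd_surrogate",
]


@dataclass(frozen=True)
class AnthropometricProfile:
    """Subject stature and mass; segment lengths scale with height."""

    height: float = 1.75  # m
    mass: float = 66.8  # kg
    name: str = "subject"

    def segment_lengths(self) -> dict[str, float]:
        h = self.height
        return {
            "pelvis": 0.100 * h,
            "torso": 0.350 * h,
            "thigh_l": 0.245 * h,
            "thigh_r": 0.245 * h,
            "shank_l": 0.246 * h,
            "shank_r": 0.246 * h,
            "foot_l": 0.152 * h,
            "foot_r": 0.152 * h,
            "upper_arm_l": 0.186 * h,
            "upper_arm_r": 0.186 * h,
            "forearm_l": 0.160 * h,
            "forearm_r": 0.160 * h,
        }


@dataclass(frozen=True)
class TaskSegment:
    """One leg of the circuit, parameterized by arc length along the path."""

    kind: str  # "level" | "stair" | "ramp" | "turn"
    length: float  # m of path
    rise: float = 0.0  # total elevation change, m
    angle: float = 0.0  # total heading change, rad (turns)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("task segment length must be positive")
        if self.kind == "ramp":
            incline = math.degrees(math.atan2(abs(self.rise), self.length))
            if incline > 20.0:
                raise ValueError(f"ramp incline {incline:.1f} deg exceeds 20 deg")


def stair_task(n_steps: int = 4, step_rise: float = 0.15, step_run: float = 0.30) -> TaskSegment:
    if abs(step_rise) > 0.3:
        raise ValueError("stair step rise exceeds 0.3 m")
    return TaskSegment("stair", n_steps * step_run, rise=n_steps * step_rise)


@dataclass(frozen=True)
class CircuitSpec:
    """Circuit layout plus pacing and protocol parameters."""

    tasks: tuple[TaskSegment, ...]
    cadence: float = 105.0  # steps/min
    speed: float = 0.9  # m/s along path
    duration: float = 10.0  # s, used only when speed == 0 (standing)
    start: str = "A"  # "A" walks the circuit forward, "B" in reverse
    lead_leg: str = "l"
    rate: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if self.speed < 0 or self.cadence <= 0 or self.duration <= 0:
            raise ValueError("speed must be >= 0, cadence and duration positive")
        if self.start not in ("A", "B") or self.lead_leg not in ("l", "r"):
            raise ValueError("start must be A/B, lead_leg l/r")

    @property
    def path_length(self) -> float:
        return sum(t.length for t in self.tasks)

    def oriented_tasks(self) -> tuple[TaskSegment, ...]:
        """Task list as actually walked (reversed from point B)."""
        if self.start == "A":
            return self.tasks
        return tuple(
            replace(t, rise=-t.rise, angle=-t.angle) for t in reversed(self.tasks)
        )


def default_circuit(**kwargs) -> CircuitSpec:
    """Level approach, 4-step stair ascent, 180 degree turn, 10 degree ramp
    descent, level finish (walked in reverse when starting from point B)."""
    tasks = (
        TaskSegment("level", 2.5),
        stair_task(4, 0.15, 0.30),
        TaskSegment("turn", 1.6, angle=math.pi),
        TaskSegment("ramp", 2.5, rise=-2.5 * math.sin(math.radians(10.0))),
        TaskSegment("level", 2.0),
    )
    return CircuitSpec(tasks=tasks, **kwargs)


@dataclass(frozen=True)
class GaitStyle:
    """Joint-pattern amplitudes and trial-to-trial variability.

    Angles in rad, displacements in m. ``asym_l``/``asym_r`` scale the
    left/right limb amplitudes (1.0 = symmetric); ``variability`` is the
    relative SD of per-trial amplitude multipliers; tremor is an optional
    low-amplitude oscillation on the distal arm (off by default).
    """

    speed_factor: float = 1.0
    hip_amp: float = 0.30
    knee_amp: float = 0.30
    ankle_amp: float = 0.15
    arm_swing: float = 0.25
    elbow_amp: float = 0.15
    trunk_yaw: float = 0.06
    trunk_roll: float = 0.04
    pelvis_bounce: float = 0.018
    pelvis_sway: float = 0.030
    pelvis_yaw: float = 0.05
    pelvis_roll: float = 0.03
    asym_l: float = 1.0
    asym_r: float = 1.0
    tremor_amp: float = 0.0
    tremor_freq: float = 5.0  # Hz
    variability: float = 0.05

    def __post_init__(self) -> None:
        amps = (
            self.hip_amp, self.knee_amp, self.ankle_amp, self.arm_swing,
            self.elbow_amp, self.trunk_yaw, self.trunk_roll,
            self.pelvis_bounce, self.pelvis_sway, self.pelvis_yaw,
            self.pelvis_roll, self.tremor_amp,
        )
        if any(a < 0 for a in amps):
            raise ValueError("style amplitudes must be non-negative")
        if self.asym_l <= 0 or self.asym_r <= 0:
            raise ValueError("asymmetry factors must be positive")


def pd_surrogate(
    style: GaitStyle,
    arm_swing_factor: float = 0.6,
    asymmetry: float = 0.8,
    speed_factor: float = 0.85,
    tremor_amp: float = 0.0,
    tremor_freq: float = 5.0,
) -> GaitStyle:
    """Parkinsonian-style perturbation of a gait style.

    Reduced arm swing, one-sided amplitude reduction (``asymmetry`` applied
    to the right limbs), reduced walking speed, and optional 4-6 Hz distal
    tremor. With all factors at their identity values the style is
    returned unchanged.
    """
    return replace(
        style,
        arm_swing=style.arm_swing * arm_swing_factor,
        asym_r=style.asym_r * asymmetry,
        speed_factor=style.speed_factor * speed_factor,
        tremor_amp=tremor_amp,
        tremor_freq=tremor_freq,
    )


@dataclass
class SyntheticTrial:
    """Markers + ground-truth poses + metadata for one circuit traversal.

    Trials loaded from disk archives carry only markers, template, profile
    and task labels; the generator additionally attaches the ground-truth
    poses and the spec/style that produced the trial.
    """

    markers: MarkerSeries
    template: dict[str, dict[str, np.ndarray]]  # seg -> label -> local position
    profile: AnthropometricProfile
    labels: np.ndarray  # (n,) per-frame task kind
    poses: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
    spec: CircuitSpec | None = None
    style: GaitStyle | None = None
    seed: int = 0

    @property
    def rate(self) -> float:
        return self.markers.rate

    @property
    def n_frames(self) -> int:
        return self.markers.n_frames


# ---------------------------------------------------------------------------
# marker templates

def _tracking_markers(seg: str, length: float) -> dict[str, np.ndarray]:
    # four non-coplanar markers spread along the segment
    return {
        f"{seg}_m1": np.array([0.050, 0.000, 0.20 * length]),
        f"{seg}_m2": np.array([-0.030, 0.045, 0.45 * length]),
        f"{seg}_m3": np.array([0.000, -0.050, 0.65 * length]),
        f"{seg}_m4": np.array([0.040, 0.030, 0.85 * length]),
    }


def marker_template(lengths: dict[str, float]) -> dict[str, dict[str, np.ndarray]]:
    """Segment-local marker coordinates for the full documented marker set.

    Every tracked segment carries four tracking markers; named anatomical
    landmarks (styloids, malleoli, epicondyles, C7, PSIS, jugular notch,
    dorsal hand) are attached to the segment they move with. Leg and arm
    local frames have +x anterior and +z from the proximal toward the
    distal joint; medial is +y on the left side and -y on the right.
    """
    tpl = {seg: _tracking_markers(seg, L) for seg, L in lengths.items()}
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        Lf = lengths[f"forearm_{side}"]
        tpl[f"forearm_{side}"].update({
            f"wrist_rad_{side}": np.array([0.0, sgn * 0.035, Lf]),
            f"wrist_uln_{side}": np.array([0.0, -sgn * 0.035, Lf]),
            f"hand_dorsal_{side}": np.array([0.055, 0.0, Lf + 0.05]),
        })
        Lu = lengths[f"upper_arm_{side}"]
        tpl[f"upper_arm_{side}"].update({
            f"elbow_med_{side}": np.array([0.0, sgn * 0.040, Lu]),
            f"elbow_lat_{side}": np.array([0.0, -sgn * 0.040, Lu]),
        })
        Ls = lengths[f"shank_{side}"]
        tpl[f"shank_{side}"].update({
            f"malleolus_med_{side}": np.array([0.0, sgn * 0.045, Ls]),
            f"malleolus_lat_{side}": np.array([0.0, -sgn * 0.045, Ls]),
        })
        Lt = lengths[f"thigh_{side}"]
        tpl[f"thigh_{side}"].update({
            f"knee_med_{side}": np.array([0.0, sgn * 0.050, Lt]),
            f"knee_lat_{side}": np.array([0.0, -sgn * 0.050, Lt]),
        })
    Lt = lengths["torso"]
    tpl["torso"].update({
        "c7": np.array([-0.060, 0.0, 0.92 * Lt]),
        "jugular_notch": np.array([0.060, 0.0, 0.88 * Lt]),
    })
    tpl["pelvis"].update({
        "psis_l": np.array([-0.080, 0.055, 0.030]),
        "psis_r": np.array([-0.080, -0.055, 0.030]),
    })
    return tpl


# ---------------------------------------------------------------------------
# path construction

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _path_profiles(tasks: tuple[TaskSegment, ...], s: np.ndarray, blend: float = 0.25):
    """Heading, elevation, slope and task occupancy along arc length ``s``.

    Slopes blend in/out over ``blend`` meters (C1 elevation); heading
    changes follow a smoothstep over each turn (C1 heading).
    """
    heading = np.zeros_like(s)
    slope = np.zeros_like(s)
    bounds = np.concatenate([[0.0], np.cumsum([t.length for t in tasks])])
    for k, t in enumerate(tasks):
        s0, s1 = bounds[k], bounds[k + 1]
        if t.angle != 0.0:
            heading += t.angle * _smoothstep((s - s0) / (s1 - s0))
        if t.rise != 0.0:
            occ = _smoothstep((s - s0) / blend) - _smoothstep((s - s1) / blend)
            slope += (t.rise / t.length) * occ
    ds = np.diff(s, prepend=s[0])
    z = np.cumsum(slope * ds)
    x = np.cumsum(np.cos(heading) * ds)
    y = np.cumsum(np.sin(heading) * ds)
    labels = np.full(s.shape, "level", dtype=object)
    for k, t in enumerate(tasks):
        inside = (s >= bounds[k]) & (s < bounds[k + 1])
        labels[inside] = t.kind
    return heading, np.stack([x, y, z], axis=1), slope, labels, bounds


def _occupancy(tasks, bounds, s, kind: str, blend: float = 0.4) -> np.ndarray:
    occ = np.zeros_like(s)
    for k, t in enumerate(tasks):
        if t.kind == kind:
            occ += _smoothstep((s - bounds[k]) / blend) - _smoothstep(
                (s - bounds[k + 1]) / blend
            )
    return occ


# ---------------------------------------------------------------------------
# forward kinematics

def _roty(a):  # batched rotations about the local y axis
    a = np.atleast_1d(np.asarray(a, dtype=float))
    return Rotation.from_euler("y", a[:, None]).as_matrix()


_FLIP = Rotation.from_euler("x", math.pi).as_matrix()  # zero-pose limb frame


def _euler_zyx(yaw, pitch, roll):
    ang = np.stack([yaw, pitch, roll], axis=-1)
    return Rotation.from_euler("ZYX", ang).as_matrix()


def generate_trial(
    spec: CircuitSpec,
    style: GaitStyle,
    profile: AnthropometricProfile,
    seed: int = 0,
) -> SyntheticTrial:
    """Generate one circuit traversal.

    The pelvis root follows the circuit path at the configured speed;
    joint angles are phase-locked sinusoid-plus-harmonic patterns whose
    amplitudes are modulated smoothly by task (more hip/knee flexion on
    stairs and ramps, trunk lean following the path slope). All
    trajectories are C1-continuous; per-trial variability (amplitude
    multipliers and phase offsets) is drawn once per trial from ``seed``.
    """
    rng = np.random.default_rng(seed)
    h = profile.height
    lengths = profile.segment_lengths()
    speed = spec.speed * style.speed_factor
    f_stride = spec.cadence / 120.0  # strides/s

    if speed > 0:
        step_length = speed / (spec.cadence / 60.0)
        if step_length > 0.9 * (lengths["thigh_l"] + lengths["shank_l"]):
            raise ValueError(
                f"infeasible spec: step length {step_length:.2f} m exceeds leg length"
            )
        duration = spec.path_length / speed
    else:
        duration = spec.duration
    n = max(int(round(duration * spec.rate)), 9)
    t = np.arange(n) / spec.rate
    s = speed * t

    tasks = spec.oriented_tasks()
    heading, path, path_slope, labels, bounds = _path_profiles(tasks, s)

    # task-dependent amplitude modulation (smooth in s, hence in t)
    stair = _occupancy(tasks, bounds, s, "stair")
    ramp = _occupancy(tasks, bounds, s, "ramp")
    hip_fac = 1.0 + 0.35 * stair + 0.12 * ramp
    knee_fac = 1.0 + 0.45 * stair + 0.15 * ramp
    lean = 0.05 + 0.25 * path_slope

    # per-trial variability: one multiplier/phase per pattern
    m = 1.0 + style.variability * rng.standard_normal(12)
    ph = 0.12 * rng.standard_normal(12)
    phi0 = rng.uniform(0.0, 2.0 * math.pi)

    phi_l = 2.0 * math.pi * f_stride * t + phi0 + (0.0 if spec.lead_leg == "l" else math.pi)
    phi_r = phi_l + math.pi
    tremor = style.tremor_amp * np.sin(2.0 * math.pi * style.tremor_freq * t + phi0)

    def hip(phi, asym, k):
        return 0.08 + style.hip_amp * asym * hip_fac * m[k] * np.sin(phi + ph[k])

    def knee(phi, asym, k):
        base = np.sin(phi - 1.2 + ph[k]) + 0.40 * np.sin(2.0 * (phi - 0.3) + ph[k])
        return 0.35 * knee_fac + style.knee_amp * asym * knee_fac * m[k] * base

    def ankle(phi, asym, k):
        return style.ankle_amp * asym * m[k] * np.sin(phi + 0.5 + ph[k])

    def shoulder(phi, asym, k):
        return -0.05 + style.arm_swing * asym * m[k] * np.sin(phi + math.pi + ph[k])

    def elbow(phi, asym, k):
        return 0.40 + style.elbow_amp * asym * m[k] * np.sin(phi + math.pi + ph[k]) + tremor

    aL, aR = style.asym_l, style.asym_r

    # pelvis root
    hip_height = 0.510 * h
    sway_dir = np.stack([-np.sin(heading), np.cos(heading), np.zeros(n)], axis=1)
    bounce = style.pelvis_bounce * np.sin(2.0 * phi_l + ph[8]) * m[8]
    sway = style.pelvis_sway * np.sin(phi_l + ph[9]) * m[9]
    p_pelvis = path + np.array([0.0, 0.0, hip_height]) + sway[:, None] * sway_dir
    p_pelvis[:, 2] += bounce

    pel_yaw = heading + style.pelvis_yaw * np.sin(phi_l + ph[10]) * m[10]
    pel_roll = style.pelvis_roll * np.sin(phi_l + math.pi / 2 + ph[10])
    R_pelvis = _euler_zyx(pel_yaw, 0.02 * np.ones(n), pel_roll)

    tor_yaw = heading + style.trunk_yaw * m[11] * np.sin(phi_l + math.pi + ph[11])
    tor_roll = style.trunk_roll * m[11] * np.sin(phi_l + ph[11])
    R_torso = _euler_zyx(tor_yaw, lean, tor_roll)

    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    poses["pelvis"] = (R_pelvis, p_pelvis)
    p_torso = p_pelvis + np.einsum("nij,j->ni", R_pelvis, [0.0, 0.0, lengths["pelvis"]])
    poses["torso"] = (R_torso, p_torso)

    hip_w = 0.050 * h
    sho_w = 0.110 * h
    sho_z = 0.85 * lengths["torso"]

    for side, phi, asym, sgn in (("l", phi_l, aL, 1.0), ("r", phi_r, aR, -1.0)):
        k_hip, k_knee, k_ank = (0, 1, 2) if side == "l" else (3, 4, 5)
        p_hip = p_pelvis + np.einsum("nij,j->ni", R_pelvis, [0.0, sgn * hip_w, 0.0])
        R_thigh = R_pelvis @ _roty(-hip(phi, asym, k_hip)) @ _FLIP
        p_knee = p_hip + np.einsum("nij,j->ni", R_thigh, [0, 0, lengths[f"thigh_{side}"]])
        R_shank = R_thigh @ _roty(-knee(phi, asym, k_knee))
        p_ankle = p_knee + np.einsum("nij,j->ni", R_shank, [0, 0, lengths[f"shank_{side}"]])
        R_foot = R_shank @ _roty(math.pi / 2 + ankle(phi, asym, k_ank))
        poses[f"thigh_{side}"] = (R_thigh, p_hip)
        poses[f"shank_{side}"] = (R_shank, p_knee)
        poses[f"foot_{side}"] = (R_foot, p_ankle)

        k_sho, k_elb = (6, 7) if side == "l" else (7, 6)
        p_sho = p_torso + np.einsum("nij,j->ni", R_torso, [0.0, sgn * sho_w, sho_z])
        R_uarm = R_torso @ _roty(-shoulder(phi, asym, k_sho)) @ _FLIP
        p_elb = p_sho + np.einsum("nij,j->ni", R_uarm, [0, 0, lengths[f"upper_arm_{side}"]])
        R_fore = R_uarm @ _roty(elbow(phi, asym, k_elb))
        poses[f"upper_arm_{side}"] = (R_uarm, p_sho)
        poses[f"forearm_{side}"] = (R_fore, p_elb)

    template = marker_template(lengths)
    all_labels: list[str] = []
    cols: list[np.ndarray] = []
    for seg, local in template.items():
        R, origin = poses[seg]
        for lab, p in local.items():
            all_labels.append(lab)
            cols.append(origin + np.einsum("nij,j->ni", R, p))
    markers = MarkerSeries(all_labels, np.stack(cols, axis=1), spec.rate)

    return SyntheticTrial(
        markers=markers,
        poses=poses,
        template=template,
        labels=labels,
        profile=profile,
        spec=spec,
        style=style,
        seed=seed,
    )


def make_cohort(
    n_trials: int,
    profiles: list[AnthropometricProfile],
    style: GaitStyle,
    seed: int = 0,
    spec: CircuitSpec | None = None,
    speed_sd: float = 0.05,
    cadence_sd: float = 0.04,
) -> list[SyntheticTrial]:
    """Generate a cohort of trials following the alternation protocol.

    Start points alternate A, B, A, B, ... and lead legs L, L, R, R, ...
    across consecutive trials; subjects (anthropometric profiles) rotate
    round-robin, so ``n`` trials over ``p`` profiles yields ``n/p`` trials
    each. Per-trial walking speed and cadence vary by the given relative
    SDs; each trial gets its own child seed from the master seed.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    base = default_circuit() if spec is None else spec
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials)
    rng = np.random.default_rng(ss.spawn(1)[0])
    trials = []
    for i in range(n_trials):
        start = "A" if i % 2 == 0 else "B"
        lead = "l" if (i // 2) % 2 == 0 else "r"
        trial_spec = replace(
            base,
            start=start,
            lead_leg=lead,
            speed=base.speed * max(1.0 + speed_sd * rng.standard_normal(), 0.5),
            cadence=base.cadence * max(1.0 + cadence_sd * rng.standard_normal(), 0.5),
        )
        trial_seed = int(children[i].generate_state(1)[0] % (2**31))
        trials.append(
            generate_trial(trial_spec, style, profiles[i % len(profiles)], trial_seed)
        )
    return trials
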