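"""Virtual inertial measurement units synthesized from marker kinematics.

Five sensor frames (left/right wrist, left/right ankle, neck) are built
from anatomical markers each frame. The accelerometer reports specific
force f = a - g in the local frame (so a stationary sensor reads +9.81
m/s^2 along whatever local axis points up), the gyroscope reports the
frame's angular velocity in local coordinates. Gaussian sensor noise and a
5-frame moving average emulate low-cost IMU hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .body_model import (
    DegenerateGeometryError,
    MarkerSeries,
    angular_velocity_from_rotations,
    differentiate,
)
from .momentum import moving_average

__all__ = [
    "SENSORS",
    "GRAVITY",
    "SensorFrameSpec",
    "DEFAULT_SENSOR_SPECS",
    "ImuSignal",
    "NoiseSpec",
    "build_sensor_frames",
    "synthesize_imu",
    "add_noise",
    "smooth_imu",
    "trial_imu_matrix",
    "imu_channel_names",
]

#: Sensor order used for the stacked 30-channel representation.
SENSORS = ("wrist_l", "wrist_r", "ankle_l", "ankle_r", "neck")

#: Lab-frame gravitational acceleration, m/s^2 (+Z up).
GRAVITY = np.array([0.0, 0.0, -9.81])


@dataclass(frozen=True)
class SensorFrameSpec:
    """Marker-based construction rule for one sensor frame.

    The origin is the midpoint of ``origin_markers``. The local z-axis
    points from the origin toward the midpoint of ``z_target_markers``
    (exact). ``y_hint_from``/``y_hint_to`` give an approximate anatomical
    y direction (midpoint to midpoint); x = y_hint x z and y = z x x, so
    the triad is exactly orthonormal and right-handed even when the hint is
    not perpendicular to z.
    """

    sensor: str
    origin_markers: tuple[str, ...]
    z_target_markers: tuple[str, ...]
    y_hint_from: tuple[str, ...]
    y_hint_to: tuple[str, ...]


#: Wrist z toward the elbow joint center (epicondyle midpoint), y toward
#: the dorsal side of the hand; ankle z toward the knee joint center, y
#: lateral; neck at C7 with z toward the PSIS midpoint and y posterior in
#: the C7 / PSIS-midpoint / jugular-notch plane.
DEFAULT_SENSOR_SPECS: dict[str, SensorFrameSpec] = {
    "wrist_l": SensorFrameSpec(
        "wrist_l",
        ("wrist_rad_l", "wrist_uln_l"),
        ("elbow_med_l", "elbow_lat_l"),
        ("wrist_rad_l", "wrist_uln_l"),
        ("hand_dorsal_l",),
    ),
    "wrist_r": SensorFrameSpec(
        "wrist_r",
        ("wrist_rad_r", "wrist_uln_r"),
        ("elbow_med_r", "elbow_lat_r"),
        ("wrist_rad_r", "wrist_uln_r"),
        ("hand_dorsal_r",),
    ),
    "ankle_l": SensorFrameSpec(
        "ankle_l",
        ("malleolus_med_l", "malleolus_lat_l"),
        ("knee_med_l", "knee_lat_l"),
        ("malleolus_med_l",),
        ("malleolus_lat_l",),
    ),
    "ankle_r": SensorFrameSpec(
        "ankle_r",
        ("malleolus_med_r", "malleolus_lat_r"),
        ("knee_med_r", "knee_lat_r"),
        ("malleolus_med_r",),
        ("malleolus_lat_r",),
    ),
    "neck": SensorFrameSpec(
        "neck",
        ("c7",),
        ("psis_l", "psis_r"),
        ("jugular_notch",),
        ("c7",),
    ),
}


@dataclass
class ImuSignal:
    """One sensor's local-frame acceleration and angular velocity."""

    sensor: str
    rate: float  # Hz
    acc: np.ndarray  # (n, 3) m/s^2, specific force, local frame
    gyro: np.ndarray  # (n, 3) rad/s, local frame
    noisy: bool = False
    smoothed: bool = False

    @property
    def n_frames(self) -> int:
        return self.acc.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian sensor noise levels."""

    accel_sigma: float = 0.15  # m/s^2
    gyro_sigma: float = 0.005  # rad/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_sigma < 0 or self.gyro_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")


def _midpoint(markers: MarkerSeries, labels: tuple[str, ...]) -> np.ndarray:
    return np.mean([markers.get(lab) for lab in labels], axis=0)


def build_sensor_frames(
    markers: MarkerSeries, spec: SensorFrameSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame sensor rotation (local -> lab) and origin series.

    Returns ``R`` of shape ``(n, 3, 3)`` whose columns are the local x, y,
    z axes in lab coordinates, and the origin series ``(n, 3)``.
    """
    origin = _midpoint(markers, spec.origin_markers)
    z = _midpoint(markers, spec.z_target_markers) - origin
    zn = np.linalg.norm(z, axis=1, keepdims=True)
    if np.any(zn < 1e-9):
        raise DegenerateGeometryError(f"{spec.sensor}: z-axis target coincides with origin")
    z = z / zn
    y_hint = _midpoint(markers, spec.y_hint_to) - _midpoint(markers, spec.y_hint_from)
    x = np.cross(y_hint, z)
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(xn < 1e-9):
        raise DegenerateGeometryError(f"{spec.sensor}: y hint parallel to z-axis")
    x = x / xn
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=-1)
    return R, origin


def synthesize_imu(
    origin: np.ndarray,
    rotation: np.ndarray,
    rate: float,
    sensor: str = "sensor",
    gravity: np.ndarray = GRAVITY,
) -> ImuSignal:
    """Noise-free IMU signal from a sensor frame trajectory.

    Proper (specific-force) acceleration is the origin's second derivative
    minus gravity, rotated into the local frame; angular velocity comes
    from the rotation series, rotated into the local frame.
    """
    origin = np.asarray(origin, dtype=float)
    if origin.shape[0] < 5:
        raise ValueError("series too short to differentiate twice")
    dt = 1.0 / rate
    acc_lab = differentiate(differentiate(origin, dt), dt) - np.asarray(gravity, float)
    omega_lab = angular_velocity_from_rotations(rotation, dt)
    Rt = np.swapaxes(rotation, -1, -2)
    acc = np.einsum("nij,nj->ni", Rt, acc_lab)
    gyro = np.einsum("nij,nj->ni", Rt, omega_lab)
    return ImuSignal(sensor=sensor, rate=rate, acc=acc, gyro=gyro)


def add_noise(sig: ImuSignal, spec: NoiseSpec) -> ImuSignal:
    """Add iid zero-mean Gaussian noise per channel; reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    acc = sig.acc + rng.normal(0.0, spec.accel_sigma, sig.acc.shape) if spec.accel_sigma > 0 else sig.acc.copy()
    gyro = sig.gyro + rng.normal(0.0, spec.gyro_sigma, sig.gyro.shape) if spec.gyro_sigma > 0 else sig.gyro.copy()
    return replace(sig, acc=acc, gyro=gyro, noisy=True)


def smooth_imu(sig: ImuSignal, window: int = 5) -> ImuSignal:
    """5-frame (by default) centered moving average on both channels."""
    return replace(
        sig,
        acc=moving_average(sig.acc, window),
        gyro=moving_average(sig.gyro, window),
        smoothed=True,
    )


def trial_imu_matrix(signals: dict[str, ImuSignal]) -> np.ndarray:
    """Stack the five sensors into the 30-channel network input.

    Sensor-major ordering (wrist_l, wrist_r, ankle_l, ankle_r, neck), each
    contributing [ax, ay, az, gx, gy, gz]. Shape ``(n_frames, 30)``.
    """
    cols = []
    for s in SENSORS:
        sig = signals[s]
        cols.append(sig.acc)
        cols.append(sig.gyro)
    return np.concatenate(cols, axis=1)


def imu_channel_names() -> list[str]:
    return [f"{s}_{c}" for s in SENSORS for c in ("ax", "ay", "az", "gx", "gy", "gz")]
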