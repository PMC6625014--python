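"""Twelve-segment rigid-body model: marker handling, pose estimation and
differentiation.

Conventions used throughout the package: SI units (m, kg, s, rad); the
laboratory frame is right-handed with +Z vertical up; rotation matrices map
segment-local coordinates into the laboratory frame; time is the leading
axis of every series array.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import signal

__all__ = [
    "SEGMENTS",
    "AnthropometricTable",
    "load_anthropometry",
    "MarkerSeries",
    "SegmentState",
    "BodyState",
    "rigid_fit",
    "fit_segment_poses",
    "segment_inertia",
    "differentiate",
    "angular_velocity_from_rotations",
    "butterworth_smooth",
    "body_state_from_poses",
]

#: The 12 tracked segments.
SEGMENTS = (
    "pelvis",
    "torso",
    "thigh_l",
    "thigh_r",
    "shank_l",
    "shank_r",
    "foot_l",
    "foot_r",
    "upper_arm_l",
    "upper_arm_r",
    "forearm_l",
    "forearm_r",
)

#: Radius-of-gyration floor so the inertia tensor stays positive definite.
MIN_GYRATION_RADIUS = 1e-6


class DegenerateGeometryError(ValueError):
    """Marker configuration too degenerate (collinear / too few points)."""


@dataclass(frozen=True)
class AnthropometricTable:
    """Per-segment mass fractions, COM fractions and radii of gyration.

    ``mass_fraction`` is relative to total body mass; ``com_fraction`` is
    the COM location along the segment's longitudinal axis as a fraction of
    segment length from the proximal end; ``radii`` are principal radii of
    gyration (sagittal, transverse, longitudinal) as fractions of segment
    length.
    """

    mass_fraction: dict[str, float]
    com_fraction: dict[str, float]
    radii: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        total = sum(self.mass_fraction.values())
        if not 0.0 < total <= 1.0 + 1e-9:
            raise ValueError(f"segment mass fractions sum to {total:.4f}, expected <= 1")
        for seg, f in self.mass_fraction.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"mass fraction of {seg} out of (0, 1): {f}")
        for seg, ks in self.radii.items():
            if any(not 0.0 <= k < 1.0 for k in ks):
                raise ValueError(f"radii of gyration of {seg} out of [0, 1): {ks}")

    @property
    def modeled_mass_fraction(self) -> float:
        return float(sum(self.mass_fraction.values()))


def load_anthropometry(path: str | None = None) -> AnthropometricTable:
    """Load the bundled de Leva-style table, or a user-supplied YAML file."""
    if path is None:
        ref = importlib.resources.files("wbam.data") / "anthropometry.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    segs = raw["segments"]
    return AnthropometricTable(
        mass_fraction={s: float(v["mass_fraction"]) for s, v in segs.items()},
        com_fraction={s: float(v["com_fraction"]) for s, v in segs.items()},
        radii={s: tuple(float(k) for k in v["radii"]) for s, v in segs.items()},
    )


@dataclass
class MarkerSeries:
    """Labeled marker trajectories, shape ``(n_frames, n_markers, 3)`` in m."""

    labels: list[str]
    data: np.ndarray
    rate: float  # Hz

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("marker data must have shape (n_frames, n_markers, 3)")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("label count does not match marker count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("marker labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("marker positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def get(self, label: str) -> np.ndarray:
        """Trajectory of one marker, shape ``(n_frames, 3)``."""
        try:
            j = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown marker label: {label}") from None
        return self.data[:, j, :]

    def frame(self, i: int) -> dict[str, np.ndarray]:
        """One frame as a label -> position mapping."""
        return {lab: self.data[i, j] for j, lab in enumerate(self.labels)}

    def subset(self, labels: list[str]) -> "MarkerSeries":
        idx = [self.labels.index(lab) for lab in labels]
        return MarkerSeries(list(labels), self.data[:, idx, :], self.rate)


@dataclass
class SegmentState:
    """Kinematic state of one segment over time.

    ``rotation`` maps local to lab coordinates; ``inertia_lab`` is the
    inertia tensor expressed in the lab frame about the segment COM.
    """

    segment: str
    rotation: np.ndarray  # (n, 3, 3)
    com: np.ndarray  # (n, 3) m
    vel: np.ndarray  # (n, 3) m/s
    acc: np.ndarray  # (n, 3) m/s^2
    omega: np.ndarray  # (n, 3) rad/s, lab frame
    mass: float  # kg
    inertia_local: np.ndarray  # (3, 3) kg m^2, principal, segment frame
    inertia_lab: np.ndarray = field(default=None)  # (n, 3, 3)

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("segment mass must be positive")
        R = self.rotation
        err = np.abs(R @ np.swapaxes(R, -1, -2) - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotations not orthonormal (max |R R^T - I| = {err:.2e})")
        if self.inertia_lab is None:
            # I_lab(t) = R I_local R^T
            self.inertia_lab = R @ self.inertia_local @ np.swapaxes(R, -1, -2)


@dataclass
class BodyState:
    """All segment states plus the whole-body COM trajectory."""

    segments: dict[str, SegmentState]
    r_body: np.ndarray  # (n, 3)
    v_body: np.ndarray  # (n, 3)
    height: float  # m
    mass: float  # kg, total subject mass

    @classmethod
    def from_segments(
        cls, segments: dict[str, SegmentState], height: float, mass: float
    ) -> "BodyState":
        masses = np.array([s.mass for s in segments.values()])
        coms = np.stack([s.com for s in segments.values()])  # (S, n, 3)
        vels = np.stack([s.vel for s in segments.values()])
        w = masses[:, None, None] / masses.sum()
        return cls(segments, (w * coms).sum(0), (w * vels).sum(0), height, mass)

    @property
    def n_frames(self) -> int:
        return self.r_body.shape[0]


def rigid_fit(
    reference: np.ndarray, observed: np.ndarray, cond_tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping ``reference`` onto ``observed``.

    Solves ``min_{R,t} sum_j ||R p_j + t - q_j||^2`` (Kabsch, via SVD) with
    ``det(R) = +1`` enforced.

    Parameters
    ----------
    reference : (m, 3) array of reference (e.g. segment-local) points.
    observed : (m, 3) or (n, m, 3) array; a leading axis batches frames.

    Returns
    -------
    R : (3, 3) or (n, 3, 3) rotation, t : (3,) or (n, 3) translation.
    """
    P = np.asarray(reference, dtype=float)
    Q = np.asarray(observed, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("reference must be (m, 3)")
    if P.shape[0] < 3:
        raise DegenerateGeometryError("rigid_fit needs at least 3 markers")
    single = Q.ndim == 2
    if single:
        Q = Q[None]
    if Q.shape[1:] != P.shape:
        raise ValueError("observed markers must match reference shape")

    p0 = P.mean(axis=0)
    Pc = P - p0
    # collinearity check on the reference configuration
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] <= cond_tol * sv[0]:
        raise DegenerateGeometryError("reference markers are (near-)collinear")

    q0 = Q.mean(axis=1)  # (n, 3)
    Qc = Q - q0[:, None, :]
    H = np.einsum("ji,njk->nik", Pc, Qc)  # (n, 3, 3) = P_c^T Q_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.swapaxes(Vt, -1, -2) @ np.swapaxes(U, -1, -2)))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.swapaxes(Vt, -1, -2) @ D @ np.swapaxes(U, -1, -2)
    t = q0 - np.einsum("nij,j->ni", R, p0)
    if single:
        return R[0], t[0]
    return R, t


def fit_segment_poses(
    markers: MarkerSeries, template: dict[str, dict[str, np.ndarray]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Track every segment through a trial by per-frame rigid fits.

    ``template`` maps segment -> {marker label -> local position}; this is
    the role a static calibration trial plays with real motion capture.
    Returns segment -> (rotation series (n,3,3), origin series (n,3)).
    """
    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for seg, local in template.items():
        labels = list(local.keys())
        P = np.stack([np.asarray(local[lab], dtype=float) for lab in labels])
        Q = markers.subset(labels).data
        poses[seg] = rigid_fit(P, Q)
    return poses


def segment_inertia(
    table: AnthropometricTable, segment: str, length: float, subject_mass: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mass, local COM offset and principal inertia tensor of one segment.

    The local frame has +z pointing from the proximal toward the distal end,
    so the COM offset is ``com_fraction * length`` along +z. The inertia
    tensor is diagonal, ``I_jj = m (k_jj * length)^2``, about the COM.
    """
    if length <= 0 or subject_mass <= 0:
        raise ValueError("length and subject mass must be positive")
    try:
        frac = table.mass_fraction[segment]
        cf = table.com_fraction[segment]
        radii = np.asarray(table.radii[segment], dtype=float)
    except KeyError:
        raise KeyError(f"unknown segment id: {segment}") from None
    m = frac * subject_mass
    radii = np.maximum(radii, MIN_GYRATION_RADIUS)
    inertia = np.diag(m * (radii * length) ** 2)
    offset = np.array([0.0, 0.0, cf * length])
    return m, offset, inertia


def differentiate(series: np.ndarray, dt: float) -> np.ndarray:
    """Time derivative by central differences (one-sided at the ends).

    ``series`` is any array with time as leading axis, uniformly sampled at
    spacing ``dt``. Same shape out.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 frames to differentiate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = np.empty_like(x)
    out[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    out[0] = (x[1] - x[0]) / dt
    out[-1] = (x[-1] - x[-2]) / dt
    return out


def angular_velocity_from_rotations(
    R: np.ndarray, dt: float, orthonormal_tol: float = 1e-6
) -> np.ndarray:
    """Lab-frame angular velocity from a rotation series.

    omega is read off the skew-symmetric part of ``Rdot R^T`` with ``Rdot``
    by central differences; one-sided at the ends.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 3 or R.shape[1:] != (3, 3):
        raise ValueError("R must be (n, 3, 3)")
    err = np.abs(R @ np.swapaxes(R, -1, -2) - np.eye(3)).max()
    if err > orthonormal_tol:
        raise ValueError(f"rotations not orthonormal (max error {err:.2e})")
    Rdot = differentiate(R, dt)
    W = Rdot @ np.swapaxes(R, -1, -2)
    # exact skew-symmetrization before extraction
    W = 0.5 * (W - np.swapaxes(W, -1, -2))
    return np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=-1)


def butterworth_smooth(
    data: np.ndarray, cutoff: float, rate: float, order: int = 4
) -> np.ndarray:
    """Zero-lag low-pass Butterworth smoothing (forward-backward filtfilt).

    The filter is designed at ``order`` and applied in both directions, so
    the effective attenuation order is doubled while the phase is zero.
    Applied along the leading (time) axis.
    """
    if rate <= 2.0 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    x = np.asarray(data, dtype=float)
    b, a = signal.butter(order, cutoff / (rate / 2.0), btype="low")
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise ValueError(f"series too short for filtering (need > {padlen} frames)")
    return signal.filtfilt(b, a, x, axis=0)


def body_state_from_poses(
    poses: dict[str, tuple[np.ndarray, np.ndarray]],
    segment_lengths: dict[str, float],
    table: AnthropometricTable,
    height: float,
    mass: float,
    rate: float,
) -> BodyState:
    """Build the full kinematic body state from segment pose series.

    For each segment the COM is placed at its anthropometric offset in the
    local frame, velocities/accelerations come from numerical
    differentiation, and angular velocity from the rotation series.
    """
    dt = 1.0 / rate
    states: dict[str, SegmentState] = {}
    for seg, (R, origin) in poses.items():
        m, offset, I_local = segment_inertia(table, seg, segment_lengths[seg], mass)
        com = origin + np.einsum("nij,j->ni", R, offset)
        vel = differentiate(com, dt)
        acc = differentiate(vel, dt)
        omega = angular_velocity_from_rotations(R, dt)
        states[seg] = SegmentState(
            segment=seg,
            rotation=R,
            com=com,
            vel=vel,
            acc=acc,
            omega=omega,
            mass=m,
            inertia_local=I_local,
        )
    return BodyState.from_segments(states, height=height, mass=mass)
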