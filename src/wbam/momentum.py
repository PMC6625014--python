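"""Segment contributions to whole-body angular momentum.

Each segment i contributes

    H_i = (r_i - r_body) x m_i (v_i - v_body) + I_i w_i

about the whole-body COM: an orbital term (mass times lever arm crossed
with relative velocity) plus a spin term (lab-frame inertia times segment
angular velocity). Contributions are re-expressed in a moving body-aligned
frame (anterior / mediolateral / vertical), summed into five momentum
groups (legs, arms, trunk), normalized by subject height times mass, and
smoothed with a short moving average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_model import BodyState, SegmentState

__all__ = [
    "GROUPS",
    "GROUPING",
    "AXES",
    "MomentumTrace",
    "segment_momentum",
    "body_frame",
    "express_in_body_frame",
    "group_and_normalize",
    "moving_average",
    "momentum_trace",
]

#: The five reported momentum groups, in channel order.
GROUPS = ("leg_l", "leg_r", "arm_l", "arm_r", "trunk")

#: Fixed 12-segment -> 5-group mapping.
GROUPING: dict[str, str] = {
    "thigh_l": "leg_l",
    "shank_l": "leg_l",
    "foot_l": "leg_l",
    "thigh_r": "leg_r",
    "shank_r": "leg_r",
    "foot_r": "leg_r",
    "upper_arm_l": "arm_l",
    "forearm_l": "arm_l",
    "upper_arm_r": "arm_r",
    "forearm_r": "arm_r",
    "torso": "trunk",
    "pelvis": "trunk",
}

#: Body-frame component order. The plane each axis is normal to gives the
#: clinical plane name: mediolateral -> sagittal, anterior -> frontal,
#: vertical -> transverse.
AXES = ("anterior", "mediolateral", "vertical")


class DegenerateOrientationError(ValueError):
    """Trunk anterior axis too close to vertical to define a body frame."""


@dataclass
class MomentumTrace:
    """Per-group 3D momentum contributions in the moving body frame.

    ``data`` has shape ``(n_frames, 5, 3)`` with groups ordered as
    :data:`GROUPS` and components as :data:`AXES`. When ``normalized`` is
    true the values are (kg m^2/s) / (kg m), i.e. divided by subject height
    times mass.
    """

    time: np.ndarray  # (n,) s
    data: np.ndarray  # (n, 5, 3)
    normalized: bool
    height: float
    mass: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channels(self) -> np.ndarray:
        """Flattened ``(n_frames, 15)`` view, group-major then axis."""
        return self.data.reshape(self.n_frames, 15)

    @staticmethod
    def channel_names() -> list[str]:
        return [f"{g}_{a}" for g in GROUPS for a in AXES]


def segment_momentum(state: SegmentState, body: BodyState) -> np.ndarray:
    """One segment's contribution to H about the body COM, lab frame.

    Returns shape ``(n_frames, 3)`` in kg m^2/s.
    """
    if state.com.shape != body.r_body.shape:
        raise ValueError("segment and body series lengths differ")
    lever = state.com - body.r_body
    rel_vel = state.vel - body.v_body
    orbital = np.cross(lever, state.mass * rel_vel)
    spin = np.einsum("nij,nj->ni", state.inertia_lab, state.omega)
    return orbital + spin


def body_frame(trunk_rotation: np.ndarray, min_angle_deg: float = 1.0) -> np.ndarray:
    """Per-frame body-aligned triad from the trunk rotation series.

    The vertical axis equals the lab vertical exactly; the anterior axis is
    the horizontal projection of the trunk's anterior (local +x) axis; the
    mediolateral axis completes the right-handed triad as vertical x
    anterior. Returns ``(n, 3, 3)`` with rows (anterior, mediolateral,
    vertical) expressed in lab coordinates.
    """
    R = np.asarray(trunk_rotation, dtype=float)
    if R.ndim == 2:
        R = R[None]
    anterior = R[:, :, 0].copy()  # trunk local +x in lab
    vertical = np.array([0.0, 0.0, 1.0])
    horiz = anterior - anterior[:, 2:3] * vertical
    norms = np.linalg.norm(horiz, axis=1)
    # |horizontal part| = sin(angle from vertical)
    if np.any(norms < np.sin(np.deg2rad(min_angle_deg))):
        raise DegenerateOrientationError(
            "trunk anterior axis within 1 degree of vertical"
        )
    ant = horiz / norms[:, None]
    ml = np.cross(vertical, ant)
    frames = np.stack([ant, ml, np.broadcast_to(vertical, ant.shape)], axis=1)
    return frames


def express_in_body_frame(H_lab: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Change of basis of a lab-frame vector series into the body frame.

    ``H_lab`` may be ``(n, 3)`` or ``(n, S, 3)``; ``frames`` is the
    ``(n, 3, 3)`` output of :func:`body_frame` (rows are the body axes), so
    the body-frame components are ``frames @ H``.
    """
    H = np.asarray(H_lab, dtype=float)
    if H.shape[0] != frames.shape[0]:
        raise ValueError("series length mismatch between H and frames")
    if H.ndim == 2:
        return np.einsum("nij,nj->ni", frames, H)
    return np.einsum("nij,nsj->nsi", frames, H)


def group_and_normalize(
    per_segment: dict[str, np.ndarray],
    height: float,
    mass: float,
    grouping: dict[str, str] | None = None,
    time: np.ndarray | None = None,
) -> MomentumTrace:
    """Sum per-segment contributions into the five groups and normalize.

    ``per_segment`` maps segment id -> ``(n, 3)`` body-frame contribution.
    Every segment must belong to exactly one group; the result is divided
    by ``height * mass``.
    """
    grouping = GROUPING if grouping is None else grouping
    unassigned = set(per_segment) - set(grouping)
    if unassigned:
        raise ValueError(f"segments not assigned to any group: {sorted(unassigned)}")
    n = next(iter(per_segment.values())).shape[0]
    data = np.zeros((n, len(GROUPS), 3))
    for seg, H in per_segment.items():
        data[:, GROUPS.index(grouping[seg]), :] += H
    data /= height * mass
    if time is None:
        time = np.arange(n, dtype=float)
    return MomentumTrace(time=time, data=data, normalized=True, height=height, mass=mass)


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average along the leading axis, same length out.

    The window must be odd; near the edges it shrinks symmetrically (the
    first/last frames keep smaller centered windows), so the filter stays
    zero-lag everywhere.
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = x.shape[0]
    if window > n:
        raise ValueError("window longer than signal")
    if window == 1:
        return x.copy()
    half = window // 2
    cs = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    out = np.empty_like(x)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (cs[i + h + 1] - cs[i - h]) / (2 * h + 1)
    return out


def momentum_trace(
    body: BodyState,
    rate: float = 100.0,
    smooth_window: int = 5,
    grouping: dict[str, str] | None = None,
) -> MomentumTrace:
    """Full per-trial momentum computation.

    Computes every segment's lab-frame contribution, re-expresses it in the
    moving body frame (built from the torso rotation), groups, normalizes
    by height times mass, and applies the moving average.
    """
    frames = body_frame(body.segments["torso"].rotation)
    per_segment = {
        seg: express_in_body_frame(segment_momentum(st, body), frames)
        for seg, st in body.segments.items()
    }
    time = np.arange(body.n_frames) / rate
    trace = group_and_normalize(
        per_segment, body.height, body.mass, grouping=grouping, time=time
    )
    if smooth_window > 1:
        trace.data = moving_average(trace.data, smooth_window)
    return trace
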