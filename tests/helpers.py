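"""Independent oracles shared by the test suite.

These implementations deliberately avoid the package's momentum code:
angular momentum is computed from point-particle mechanics, and the
free-floating reference motion comes from direct RK4 integration of the
torque-free Euler equations.
"""

from __future__ import annotations

import numpy as np

from wbam.body_model import (
    BodyState,
    SegmentState,
    angular_velocity_from_rotations,
    differentiate,
)


def particle_equivalent(mass: float, inertia_diag: np.ndarray):
    """Six point masses reproducing a rigid body's mass, COM and inertia.

    Particles sit at +-a, +-b, +-c on the local axes with equal masses
    m/6; the offsets are solved from I = diag(Ix, Iy, Iz) about the COM.
    """
    Ix, Iy, Iz = inertia_diag
    A = max((Iy + Iz - Ix) / 2.0, 0.0)  # = 2 mu a^2
    B = max((Ix + Iz - Iy) / 2.0, 0.0)
    C = max((Ix + Iy - Iz) / 2.0, 0.0)
    mu = mass / 6.0
    a, b, c = (np.sqrt(v / (2.0 * mu)) for v in (A, B, C))
    pts = np.array(
        [[a, 0, 0], [-a, 0, 0], [0, b, 0], [0, -b, 0], [0, 0, c], [0, 0, -c]]
    )
    return pts, np.full(6, mu)


def particle_angular_momentum(body: BodyState) -> np.ndarray:
    """Whole-body H about the COM, from pooled point particles, lab frame.

    Each segment is replaced by its six-particle equivalent; particle
    velocities are v_com + w x (R p). Returns (n_frames, 3).
    """
    n = body.n_frames
    H = np.zeros((n, 3))
    for st in body.segments.values():
        pts, mus = particle_equivalent(st.mass, np.diag(st.inertia_local))
        for p, mu in zip(pts, mus):
            arm = np.einsum("nij,j->ni", st.rotation, p)  # COM -> particle
            r = st.com + arm
            v = st.vel + np.cross(st.omega, arm)
            H += mu * np.cross(r - body.r_body, v - body.v_body)
    return H


def _skew(w):
    return np.array(
        [[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]], dtype=float
    )


def simulate_free_floating(
    n_bodies: int = 3,
    duration: float = 2.0,
    rate: float = 200.0,
    seed: int = 0,
    substeps: int = 10,
) -> BodyState:
    """Torque-free rigid bodies drifting in gravity-free space.

    Each body spins per Euler's equations (RK4 at ``rate * substeps``) and
    its COM translates uniformly. The sampled pose series is converted to
    segment states through the package's differentiation operators, so the
    resulting BodyState exercises the same numerical path as real data.
    """
    rng = np.random.default_rng(seed)
    dt_out = 1.0 / rate
    h = dt_out / substeps
    n = int(round(duration * rate)) + 1
    segments = {}
    for k in range(n_bodies):
        mass = rng.uniform(1.0, 5.0)
        I = np.sort(rng.uniform(0.05, 0.4, 3))
        # triangle inequality for physical inertia tensors
        I[2] = min(I[2], 0.95 * (I[0] + I[1]))
        Ib = np.diag(I)
        r0 = rng.uniform(-1, 1, 3)
        v0 = rng.uniform(-0.5, 0.5, 3)
        w_b = rng.uniform(-2.0, 2.0, 3)
        R = np.eye(3)
        Rs = np.empty((n, 3, 3))
        for i in range(n):
            Rs[i] = R
            for _ in range(substeps):
                R, w_b = _rk4_step(R, w_b, Ib, h)
        t = np.arange(n) * dt_out
        com = r0 + v0 * t[:, None]
        segments[f"body{k}"] = SegmentState(
            segment=f"body{k}",
            rotation=Rs,
            com=com,
            vel=differentiate(com, dt_out),
            acc=differentiate(differentiate(com, dt_out), dt_out),
            omega=angular_velocity_from_rotations(Rs, dt_out),
            mass=mass,
            inertia_local=Ib,
        )
    return BodyState.from_segments(segments, height=1.0, mass=1.0)


def _rk4_step(R, w_b, Ib, h):
    Iinv = 1.0 / np.diag(Ib)

    def wdot(w):
        return Iinv * (-np.cross(w, np.diag(Ib) * w))

    def Rdot(R, w):
        return R @ _skew(w)

    k1w = wdot(w_b)
    k1R = Rdot(R, w_b)
    k2w = wdot(w_b + 0.5 * h * k1w)
    k2R = Rdot(R + 0.5 * h * k1R, w_b + 0.5 * h * k1w)
    k3w = wdot(w_b + 0.5 * h * k2w)
    k3R = Rdot(R + 0.5 * h * k2R, w_b + 0.5 * h * k2w)
    k4w = wdot(w_b + h * k3w)
    k4R = Rdot(R + h * k3R, w_b + h * k3w)
    w_new = w_b + h / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
    R_new = R + h / 6.0 * (k1R + 2 * k2R + 2 * k3R + k4R)
    # project back onto SO(3)
    U, _, Vt = np.linalg.svd(R_new)
    return U @ Vt, w_new
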