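import math

import numpy as np
import pytest

from wbam.body_model import rigid_fit
from wbam.evaluation import trial_momentum
from wbam.synthetic_gait import (
    AnthropometricProfile,
    CircuitSpec,
    GaitStyle,
    TaskSegment,
    default_circuit,
    generate_trial,
    make_cohort,
    pd_surrogate,
    stair_task,
)

PROFILE = AnthropometricProfile()


def _zero_style():
    return GaitStyle(
        hip_amp=0, knee_amp=0, ankle_amp=0, arm_swing=0, elbow_amp=0,
        trunk_yaw=0, trunk_roll=0, pelvis_bounce=0, pelvis_sway=0,
        pelvis_yaw=0, pelvis_roll=0, variability=0,
    )


class TestGenerateTrial:
    def test_same_seed_bitwise_identical(self):
        spec = default_circuit()
        a = generate_trial(spec, GaitStyle(), PROFILE, seed=3)
        b = generate_trial(spec, GaitStyle(), PROFILE, seed=3)
        assert np.array_equal(a.markers.data, b.markers.data)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_differs(self):
        spec = default_circuit()
        a = generate_trial(spec, GaitStyle(), PROFILE, seed=3)
        b = generate_trial(spec, GaitStyle(), PROFILE, seed=4)
        assert not np.array_equal(a.markers.data, b.markers.data)

    def test_standing_still_markers_constant(self):
        spec = CircuitSpec(tasks=(TaskSegment("level", 5.0),), speed=0.0, duration=3.0)
        trial = generate_trial(spec, _zero_style(), PROFILE, seed=0)
        assert np.abs(trial.markers.data - trial.markers.data[0]).max() < 1e-12

    def test_level_walk_displacement_matches_speed(self):
        spec = CircuitSpec(tasks=(TaskSegment("level", 12.0),), speed=1.2, cadence=110.0)
        trial = generate_trial(spec, GaitStyle(variability=0.0), PROFILE, seed=1)
        assert trial.n_frames == pytest.approx(1000, abs=1)
        _, origin = trial.poses["pelvis"]
        disp = np.linalg.norm(origin[-1, :2] - origin[0, :2])
        assert disp == pytest.approx(12.0, rel=0.02)

    def test_infeasible_step_length_rejected(self):
        spec = CircuitSpec(tasks=(TaskSegment("level", 5.0),), speed=2.5, cadence=40.0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_trial(spec, GaitStyle(), PROFILE, seed=0)

    def test_task_labels_cover_circuit(self, circuit_trial):
        kinds = set(circuit_trial.labels)
        assert kinds == {"level", "stair", "turn", "ramp"}

    def test_signal_bandwidth_below_cutoff(self, short_trial):
        """Dominant marker motion stays below the 6 Hz marker-filter
        cutoff, so smoothing preserves the gait content."""
        x = short_trial.markers.get("forearm_l_m1")[:, 0]
        x = x - x.mean()
        spectrum = np.abs(np.fft.rfft(x * np.hanning(len(x))))
        freqs = np.fft.rfftfreq(len(x), 1.0 / short_trial.rate)
        assert freqs[np.argmax(spectrum)] < 6.0


class TestRigidConsistency:
    def test_markers_exactly_rigid_in_segment_frames(self, circuit_trial):
        for seg, local in circuit_trial.template.items():
            R, origin = circuit_trial.poses[seg]
            for lab, p in local.items():
                rebuilt = origin + np.einsum("nij,j->ni", R, p)
                emitted = circuit_trial.markers.get(lab)
                assert np.abs(rebuilt - emitted).max() < 1e-12

    def test_rigid_fit_recovers_ground_truth_poses(self, short_trial):
        for seg in ("thigh_r", "torso", "forearm_l"):
            local = short_trial.template[seg]
            labels = list(local)
            P = np.stack([local[lab] for lab in labels])
            Q = short_trial.markers.subset(labels).data
            R_fit, t_fit = rigid_fit(P, Q)
            R_true, o_true = short_trial.poses[seg]
            assert np.abs(R_fit - R_true).max() < 1e-8
            assert np.abs(t_fit - o_true).max() < 1e-8

    def test_momentum_robust_to_millimeter_marker_jitter(self, short_trial, table):
        """Momentum from poses fitted to jittered markers stays within a
        few percent RMS of the ground-truth-pose momentum."""
        clean = trial_momentum(short_trial).channels()
        noisy_trial = generate_trial(short_trial.spec, short_trial.style, short_trial.profile, seed=7)
        rng = np.random.default_rng(0)
        noisy_trial.markers.data = noisy_trial.markers.data + rng.normal(
            0, 1e-3, noisy_trial.markers.data.shape
        )
        noisy = trial_momentum(noisy_trial).channels()
        rms_err = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rms_err < 0.01 * np.sqrt(np.mean(clean**2))


class TestPeriodicity:
    def test_leg_momentum_periodic_at_stride_frequency(self, table):
        spec = CircuitSpec(tasks=(TaskSegment("level", 15.0),), speed=1.0, cadence=105.0)
        trial = generate_trial(spec, GaitStyle(variability=0.0), PROFILE, seed=2)
        trace = trial_momentum(trial, table)
        x = trace.data[:, 0, 1]  # left leg, mediolateral axis (sagittal plane)
        x = x - x.mean()
        stride = int(round(trial.rate * 120.0 / spec.cadence))
        ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
        ac /= ac[0]
        # autocorrelation at one stride lag (+-2 frames) close to 1
        assert ac[stride - 2 : stride + 3].max() > 0.9


class TestCohort:
    def test_alternation_schedule(self):
        trials = make_cohort(4, [PROFILE], GaitStyle(), seed=0)
        assert [t.spec.start for t in trials] == ["A", "B", "A", "B"]
        assert [t.spec.lead_leg for t in trials] == ["l", "l", "r", "r"]

    def test_profiles_rotate_evenly(self):
        profiles = [AnthropometricProfile(name=f"s{i}") for i in range(5)]
        trials = make_cohort(10, profiles, GaitStyle(), seed=0)
        names = [t.profile.name for t in trials]
        assert all(names.count(f"s{i}") == 2 for i in range(5))

    def test_cohort_deterministic_by_master_seed(self):
        a = make_cohort(3, [PROFILE], GaitStyle(), seed=9)
        b = make_cohort(3, [PROFILE], GaitStyle(), seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.markers.data, y.markers.data)

    def test_default_trial_durations_in_study_range(self):
        trials = make_cohort(6, [PROFILE], GaitStyle(), seed=1)
        for t in trials:
            assert 8.0 <= t.n_frames / t.rate <= 14.0


class TestPdSurrogate:
    def test_identity_parameters_leave_style_unchanged(self):
        style = GaitStyle()
        same = pd_surrogate(style, arm_swing_factor=1.0, asymmetry=1.0, speed_factor=1.0)
        assert same == style

    def test_asymmetry_scales_right_side(self):
        style = pd_surrogate(GaitStyle(), asymmetry=0.8)
        assert style.asym_r == pytest.approx(0.8)
        assert style.asym_l == pytest.approx(1.0)
        assert style.arm_swing == pytest.approx(0.25 * 0.6)
        assert style.speed_factor == pytest.approx(0.85)

    def test_surrogate_cohort_has_lateral_momentum_asymmetry(self, table):
        """Right-arm momentum drops relative to left in the surrogate
        cohort, while the base cohort stays near-symmetric (direction-only
        check on generated data)."""
        spec = CircuitSpec(tasks=(TaskSegment("level", 8.0),), speed=1.0)

        def asym_index(style, seed):
            vals = []
            for trial in make_cohort(4, [PROFILE], style, seed=seed, spec=spec):
                d = trial_momentum(trial, table).data
                arm_l = np.sqrt(np.mean(d[:, 2] ** 2))
                arm_r = np.sqrt(np.mean(d[:, 3] ** 2))
                vals.append(arm_r / arm_l)
            return np.mean(vals)

        base = asym_index(GaitStyle(), seed=4)
        surr = asym_index(pd_surrogate(GaitStyle()), seed=4)
        assert surr < base


class TestSpecValidation:
    def test_stair_step_rise_bounded(self):
        with pytest.raises(ValueError):
            stair_task(4, step_rise=0.35)

    def test_ramp_incline_bounded(self):
        with pytest.raises(ValueError):
            TaskSegment("ramp", 1.0, rise=0.5)  # ~27 degrees

    def test_reverse_start_flips_rises_and_angles(self):
        spec = default_circuit(start="B")
        tasks = spec.oriented_tasks()
        assert tasks[0].kind == "level"
        stair = [t for t in tasks if t.kind == "stair"][0]
        assert stair.rise == pytest.approx(-0.6)
        turn = [t for t in tasks if t.kind == "turn"][0]
        assert turn.angle == pytest.approx(-math.pi)
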