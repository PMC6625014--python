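# Methods

## The problem

Whole-body angular momentum about the body center of mass, *H*, is a
tightly regulated quantity during healthy gait and a sensitive marker of
balance impairment. Computing it requires full-body kinematics — normally
optical motion capture — which is impractical in a clinic. `wbam`
implements a sparse-sensing alternative: a dynamic autoregressive neural
network maps 30 channels of inertial signals (3-axis accelerometer and
gyroscope at the two wrists, the two ankles and the neck) to the 15
channels of segmental contributions to *H* (five momentum groups × three
anatomical planes). Because no motion-capture dataset ships with the
package, a synthetic articulated-gait generator stands in for recorded
subjects, so every stage is testable offline.

## Segment momentum model

The body is modeled as 12 rigid segments (pelvis, torso, and left/right
thigh, shank, foot, upper arm, forearm). Segment *i* contributes

    H_i = (r_i − r_body) × m_i (v_i − v_body) + I_i ω_i

about the whole-body COM: an orbital term (lever arm crossed with relative
momentum) plus a spin term (lab-frame inertia tensor times segment angular
velocity). Superposition holds exactly: the sum of the twelve
contributions is the whole-body *H*, and the test suite verifies this
against an independent point-particle discretization to 1e-9 relative.

Masses and inertias come from a bundled de Leva-1996-style anthropometric
table (mass fraction, COM fraction and radii of gyration per segment,
scaled by subject mass and segment length). The head is folded into the
torso entry and the hands into the forearms, so the 12 segments carry the
full body mass. The table is a YAML config and can be replaced by the
user; results depend on these ratios only through the momentum weighting,
not through any learned constant. Radii of gyration are floored at 1e-6 of
segment length so inertia tensors stay positive definite.

Contributions are re-expressed in a moving body-aligned frame: the
vertical axis equals the lab vertical exactly, the anterior axis is the
horizontal projection of the trunk's anterior axis, and the mediolateral
axis completes the right-handed triad. Plane naming follows the axis
normal to each plane: mediolateral → sagittal, anterior → frontal,
vertical → transverse. The twelve segments are pooled into five reported
groups (each leg = thigh+shank+foot, each arm = upper arm+forearm, trunk =
torso+pelvis), normalized by subject height × mass, and smoothed with a
5-frame centered moving average. Normalization is applied before
smoothing; both operations are linear, so the order is immaterial. At
series edges the moving-average window shrinks symmetrically, keeping the
filter zero-lag everywhere.

## Marker processing

Marker trajectories are smoothed with a zero-lag 4th-order low-pass
Butterworth filter at 6 Hz (forward–backward application, which doubles
the effective attenuation order). Segment poses are recovered per frame by
least-squares rigid registration (Kabsch/SVD, det(R)=+1 enforced) of each
segment's marker template; velocities and accelerations come from central
differences (one-sided at the series ends, which is why evaluations skip
the first and last frames of derivative-dependent signals); angular
velocity is read off the skew-symmetric part of Ṙ Rᵀ.

## Virtual IMUs

Five sensor frames are built from anatomical markers each frame: wrist
frames at the styloid midpoints with z toward the elbow-epicondyle
midpoint and y toward a dorsal hand marker; ankle frames at the malleolar
midpoints with z toward the knee-epicondyle midpoint and y lateral; the
neck frame at C7 with z toward the PSIS midpoint and y posterior in the
C7/PSIS/jugular-notch plane. The z rule is exact; the y hint only seeds
x = y_hint × z, after which y = z × x, so triads are exactly orthonormal.

The accelerometer reports specific force f = a − g in the local frame
(with g = (0, 0, −9.81) m/s²), so a stationary sensor reads +9.81 m/s²
along its up-pointing axis, matching real hardware. Sensor noise is
zero-mean Gaussian, σ = 0.15 m/s² (accelerometer) and 0.005 rad/s
(gyroscope) — both are accelerations/rates, stated here explicitly since
the units are easy to misread. Noise is injected only at evaluation time;
training uses clean signals. Both channels then receive the 5-frame
moving average. Bias drift, scale-factor error, cross-axis sensitivity and
misplacement are out of scope.

## NARX network and training

The regressor at frame t concatenates input taps 0–8 (the current and
eight previous 30-channel IMU frames) and output taps 1–8 (eight previous
15-channel momentum frames): 9·30 + 8·15 = 390 values. Tap choice
reconciles the two natural readings of "previous eight inputs and
outputs": the current output is the prediction target and can never be a
regressor, while the current input can. One hidden layer of 30 logistic
sigmoid units feeds 15 linear outputs. All channels are min–max scaled to
[−1, 1] with scalers fitted on the training partition only (degenerate
ranges floored).

Training is teacher-forced (series-parallel): output taps carry ground
truth. The optimizer is Møller's scaled conjugate gradient — batch
second-order steps with Hessian-vector products approximated by
finite-differencing the gradient along the search direction (σ = 5e-5),
Levenberg–Marquardt-style λ adaptation (initial λ = 5e-7) and a steepest-
descent restart every n-parameters iterations. Weights initialize uniform
in ±1/√fan-in from a seeded generator. Early stopping keeps the weights
with the best validation MSE and stops after 6 epochs without improvement;
the epoch cap defaults to 300, which on these smooth, strongly
autoregressive series is far past the point where validation error
flattens (the cap is configurable). Partitioning is by whole trial —
70/15/15 train/validation/test — never by frame, since frames within a
trial are strongly autocorrelated and frame-level splits would leak.

Prediction runs in two modes. Open-loop (teacher-forced) fills output taps
with ground truth and is the mode evaluated quantitatively, since the
intended deployment provides a measured recent history. Closed-loop fills
output taps with the network's own predictions from a ground-truth
initial history; it is reported alongside for transparency but drifts as
autoregressive rollouts do, and no accuracy claim is made for it.

## Synthetic gait generator

The generator is kinematic, not dynamic: the momentum computation needs
only kinematics plus inertia, so no contact or ground-reaction forces are
modeled. A pelvis root follows a circuit path — by default 2.5 m level, a
4-step stair (0.15 m rise, 0.30 m run), a 180° turn, a 2.5 m ramp at 10°
and 2.0 m level, walked forward from point A or reversed from point B —
with C¹-continuous elevation and heading profiles (smoothstep blending).
Limbs are driven by phase-locked sinusoid-plus-harmonic joint patterns;
stairs and ramps smoothly increase hip/knee amplitudes and trunk lean
follows the path slope. Default pacing (0.9 m/s, 105 steps/min) yields
10–12 s trials at 100 Hz. Cohorts alternate start point A/B and lead leg
L/L/R/R across trials and rotate subjects round-robin; per-trial speed,
cadence, amplitude multipliers and phase offsets vary through seeded
randomness. Every marker is rigidly attached to a segment frame, so the
emitted trajectories are exactly consistent with the ground-truth poses.

The perturbed-gait (parkinsonian surrogate) style reduces arm swing
(×0.6), scales the right-side amplitudes by 0.8, reduces speed (×0.85) and
optionally adds low-amplitude 4–6 Hz distal tremor (off by default). These
are style perturbations, not a pathology model.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline — momentum computation, sensor synthesis, training and
evaluation — is internally correct and that the sparse-to-dense mapping is
learnable under realistic signal bandwidths, amplitudes and noise. They do
not demonstrate accuracy on real human gait, which contains soft-tissue
artifact, marker occlusion, inter-subject pattern variability and
pathology-specific phenomena the generator does not emulate.

## Surrogate experiment and problem sizes

The packaged experiment generates 60 able-bodied-style trials over five
subjects sampled around typical young-adult stature statistics (height
1.75 ± 0.11 m, mass 66.8 ± 12.2 kg), trains on the 42-trial partition,
and evaluates open-loop on the 9 held-out test trials with sensor noise
injected, then on a 20-trial perturbed-gait cohort built from five
representative early-stage parkinsonian anthropometric profiles (heights
1.72–1.80 m, masses 54–95 kg). These sizes keep the run to roughly two
minutes on a single CPU while preserving sensible partition arithmetic
(42/9/9 trials). Every random draw descends from one master seed through
named child seeds, so the whole experiment is bitwise reproducible.

## Numerical choices and edge cases

- Rigid fits reject configurations with fewer than 3 markers or
  near-collinear references (second singular value ≤ 1e-6 of the first).
- The body frame is undefined when the trunk anterior axis is within 1° of
  vertical; this raises rather than returning a near-singular triad.
- `differentiate` needs ≥ 3 frames; IMU synthesis needs ≥ 5 (two
  derivative passes).
- Butterworth filtering requires series longer than the filtfilt padding
  (3× filter length).
- SCG aborts with a diagnostic on non-finite loss rather than continuing.
- Gradient-correctness tests floor the relative-error denominator at 1e-3
  of the gradient's max magnitude, because central differences bottom out
  near 1e-11 absolute and components at that floor are pure noise.

## Known limitations

- The generator's joint patterns are signal-realistic, not physiologically
  validated; feet are not constrained to the ground.
- The anthropometric table is one published parameterization among
  several; swapping tables shifts the momentum weighting slightly.
- C3D input is not supported; markers are read from TRC or generated.
- Closed-loop rollouts are exposed but not accuracy-certified.
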