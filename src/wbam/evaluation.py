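"""Accuracy metrics and the end-to-end surrogate experiment.

The experiment emulates a clinical circuit-walking protocol: a cohort of
able-bodied-style synthetic trials is generated, segment momenta (the
gold standard) and clean virtual-IMU signals are computed from the
markers, the NARX network is trained teacher-forced on the 70% training
partition, and performance is measured on held-out test trials with
Gaussian sensor noise injected, plus on a separately generated
perturbed-gait (parkinsonian surrogate) cohort that the network never
saw. Reported metrics: one pooled Pearson correlation per cohort and
per-signal RMS errors as a percentage of the per-trial peak signal
magnitude (5 momentum groups by 3 planes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .body_model import (
    AnthropometricTable,
    MarkerSeries,
    body_state_from_poses,
    butterworth_smooth,
    fit_segment_poses,
    load_anthropometry,
)
from .momentum import GROUPS, MomentumTrace, momentum_trace
from .narx import (
    NarxConfig,
    NarxModel,
    TrainReport,
    TrialSet,
    partition_trials,
    predict_closed_loop,
    predict_open_loop,
    scg_train,
)
from .synthetic_gait import (
    AnthropometricProfile,
    CircuitSpec,
    GaitStyle,
    SyntheticTrial,
    make_cohort,
    pd_surrogate,
)
from .virtual_imu import (
    DEFAULT_SENSOR_SPECS,
    NoiseSpec,
    add_noise,
    build_sensor_frames,
    smooth_imu,
    synthesize_imu,
    trial_imu_matrix,
)

__all__ = [
    "GROUP_NAMES",
    "PLANES",
    "pooled_correlation",
    "normalized_rms_error",
    "trial_momentum",
    "trial_imu",
    "ExperimentConfig",
    "EvaluationReport",
    "run_experiment",
]

GROUP_NAMES = ("Left Leg", "Right Leg", "Left Arm", "Right Arm", "Trunk")

#: Clinical plane -> body-frame axis index (axes are anterior, mediolateral,
#: vertical; a plane is named for the axis normal to it).
PLANES = {"Sagittal": 1, "Frontal": 0, "Transverse": 2}

#: Anthropometrics of five representative early-stage parkinsonian
#: subjects, used for the surrogate PD cohort.
PD_PROFILES = tuple(
    AnthropometricProfile(height=h, mass=m, name=f"pd{i+1}")
    for i, (h, m) in enumerate(
        [(1.72, 94.8), (1.72, 54.4), (1.72, 82.6), (1.80, 92.5), (1.72, 63.5)]
    )
)


# ---------------------------------------------------------------------------
# metrics

def pooled_correlation(predicted: list[np.ndarray], actual: list[np.ndarray]) -> float:
    """Pearson r pooled over all frames, channels and trials.

    Both lists hold per-trial arrays of matching shape; everything is
    concatenated and flattened into two long vectors before correlating.
    """
    p = np.concatenate([np.ravel(a) for a in predicted])
    a = np.concatenate([np.ravel(x) for x in actual])
    if p.shape != a.shape or p.size < 2:
        raise ValueError("predicted/actual must align and hold >= 2 samples")
    if p.std() == 0 or a.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(p, a)[0, 1])


def normalized_rms_error(predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Per-channel RMS error as % of the peak |actual| of that channel.

    Operates on one trial: arrays of shape ``(n_frames, n_channels)``;
    returns ``(n_channels,)`` percentages.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted/actual shape mismatch")
    peak = np.abs(actual).max(axis=0)
    if np.any(peak == 0):
        bad = np.flatnonzero(peak == 0)
        raise ValueError(f"zero peak signal magnitude in channels {bad.tolist()}")
    rms = np.sqrt(np.mean((predicted - actual) ** 2, axis=0))
    return 100.0 * rms / peak


# ---------------------------------------------------------------------------
# per-trial processing

def trial_momentum(
    trial: SyntheticTrial,
    table: AnthropometricTable | None = None,
    marker_cutoff: float = 6.0,
    smooth_window: int = 5,
) -> MomentumTrace:
    """Gold-standard momentum trace from a trial's markers.

    Markers are low-pass filtered (zero-lag Butterworth), segment poses are
    recovered by per-frame rigid fits against the trial's marker template,
    and the grouped, normalized, smoothed momentum trace is returned.
    """
    table = load_anthropometry() if table is None else table
    filtered = MarkerSeries(
        trial.markers.labels,
        butterworth_smooth(trial.markers.data, marker_cutoff, trial.rate),
        trial.rate,
    )
    poses = fit_segment_poses(filtered, trial.template)
    body = body_state_from_poses(
        poses,
        trial.profile.segment_lengths(),
        table,
        trial.profile.height,
        trial.profile.mass,
        trial.rate,
    )
    return momentum_trace(body, rate=trial.rate, smooth_window=smooth_window)


def trial_imu(
    trial: SyntheticTrial,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    marker_cutoff: float = 6.0,
    smooth_window: int = 5,
) -> np.ndarray:
    """30-channel virtual-IMU matrix for one trial.

    Sensor frames are built from the filtered markers, gravity-inclusive
    signals synthesized, optional Gaussian noise added (per-sensor child
    seeds derived from ``seed``), then the 5-frame moving average applied.
    """
    filtered = MarkerSeries(
        trial.markers.labels,
        butterworth_smooth(trial.markers.data, marker_cutoff, trial.rate),
        trial.rate,
    )
    sensor_seeds = np.random.SeedSequence(seed).generate_state(len(DEFAULT_SENSOR_SPECS))
    signals = {}
    for j, (name, spec) in enumerate(DEFAULT_SENSOR_SPECS.items()):
        R, origin = build_sensor_frames(filtered, spec)
        sig = synthesize_imu(origin, R, trial.rate, sensor=name)
        if noise is not None:
            sig = add_noise(sig, replace(noise, seed=int(sensor_seeds[j] % 2**31)))
        signals[name] = smooth_imu(sig, smooth_window)
    return trial_imu_matrix(signals)


# ---------------------------------------------------------------------------
# the experiment

@dataclass
class ExperimentConfig:
    """Everything needed to reproduce the surrogate experiment."""

    n_trials: int = 60
    n_pd_trials: int = 20
    n_subjects: int = 5
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    circuit: CircuitSpec | None = None  # default circuit when None
    style: GaitStyle = field(default_factory=GaitStyle)
    pd_arm_swing_factor: float = 0.6
    pd_asymmetry: float = 0.8
    pd_speed_factor: float = 0.85
    narx: NarxConfig = field(default_factory=NarxConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    closed_loop: bool = True  # also evaluate closed-loop simulation
    seed: int = 0


@dataclass
class EvaluationReport:
    """Cohort metrics plus full provenance (config, seeds, training)."""

    pooled_r: dict[str, float]  # cohort -> open-loop r
    pooled_r_closed: dict[str, float]
    nrmse_mean: dict[str, pd.DataFrame]  # cohort -> 5x3 table, % peak
    nrmse_sd: dict[str, pd.DataFrame]
    per_task: dict[str, pd.DataFrame]  # cohort -> task x channel mean NRMSE
    config: ExperimentConfig
    train_report: TrainReport
    model: NarxModel

    def max_nrmse(self, cohort: str) -> float:
        return float(self.nrmse_mean[cohort].to_numpy().max())

    def summary(self) -> str:
        lines = []
        for cohort in self.pooled_r:
            lines.append(f"== {cohort} ==")
            lines.append(f"pooled r (open loop): {self.pooled_r[cohort]:.4f}")
            if cohort in self.pooled_r_closed:
                lines.append(
                    f"pooled r (closed loop): {self.pooled_r_closed[cohort]:.4f}"
                )
            tab = self.nrmse_mean[cohort].round(2).astype(str)
            sd = self.nrmse_sd[cohort].round(2).astype(str)
            lines.append("RMS error, % of peak signal magnitude, mean (SD) over trials:")
            lines.append((tab + " (" + sd + ")").to_string())
            lines.append("")
        return "\n".join(lines)

    def write_csv(self, directory: str) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        for cohort in self.nrmse_mean:
            self.nrmse_mean[cohort].to_csv(f"{directory}/nrmse_mean_{cohort}.csv")
            self.nrmse_sd[cohort].to_csv(f"{directory}/nrmse_sd_{cohort}.csv")
            self.per_task[cohort].to_csv(f"{directory}/per_task_{cohort}.csv")
        pd.Series(
            {**{f"r_open_{c}": v for c, v in self.pooled_r.items()},
             **{f"r_closed_{c}": v for c, v in self.pooled_r_closed.items()}}
        ).to_csv(f"{directory}/pooled_r.csv", header=False)


def _error_tables(per_trial_nrmse: list[np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    arr = np.stack(per_trial_nrmse)  # (trials, 15)
    mean = arr.mean(axis=0).reshape(5, 3)
    sd = arr.std(axis=0, ddof=1).reshape(5, 3) if arr.shape[0] > 1 else np.zeros((5, 3))
    cols = list(PLANES.keys())
    axis_order = list(PLANES.values())  # body-frame axis per plane column
    mk = lambda a: pd.DataFrame(a[:, axis_order], index=list(GROUP_NAMES), columns=cols)
    return mk(mean), mk(sd)


def _evaluate_cohort(
    model: NarxModel,
    trials: list[SyntheticTrial],
    traces: list[MomentumTrace],
    noise: NoiseSpec,
    noise_seeds: np.ndarray,
    closed_loop: bool,
) -> dict:
    """Noisy-input prediction and metrics for a list of trials."""
    L = model.config.max_lag
    preds, preds_cl, actuals, nrmse_rows, task_rows = [], [], [], [], []
    for k, (trial, trace) in enumerate(zip(trials, traces)):
        Y = trace.channels()
        U = trial_imu(trial, noise=noise, seed=int(noise_seeds[k]))
        yhat = predict_open_loop(model, U, Y)
        preds.append(yhat[L:])
        actuals.append(Y[L:])
        nrmse_rows.append(normalized_rms_error(yhat[L:], Y[L:]))
        if closed_loop:
            ycl = predict_closed_loop(model, U, y_init=Y)
            preds_cl.append(ycl[L:])
        # per-task breakdown on this trial (peak normalization per trial)
        peak = np.abs(Y[L:]).max(axis=0)
        err = yhat[L:] - Y[L:]
        row = {}
        for task in np.unique(trial.labels[L:]):
            sel = trial.labels[L:] == task
            row[task] = (
                100.0 * np.sqrt(np.mean(err[sel] ** 2, axis=0)) / peak
            ).mean()
        task_rows.append(row)
    out = {
        "r_open": pooled_correlation(preds, actuals),
        "nrmse": nrmse_rows,
        "per_task": pd.DataFrame(task_rows).mean(axis=0).to_frame("mean_nrmse_pct"),
    }
    if closed_loop:
        out["r_closed"] = pooled_correlation(preds_cl, actuals)
    return out


def run_experiment(config: ExperimentConfig | None = None) -> EvaluationReport:
    """Run the full surrogate experiment; see the module docstring.

    Deterministic given ``config.seed``: cohort generation, partitioning,
    weight initialization and test-time noise all draw from child seeds of
    the master seed.
    """
    config = ExperimentConfig() if config is None else config
    ss = np.random.SeedSequence(config.seed)
    s_profiles, s_cohort, s_part, s_narx, s_noise, s_pd, s_pd_noise = (
        int(x % 2**31) for x in ss.generate_state(7)
    )

    # able-bodied subjects around typical young-adult stature statistics
    rng = np.random.default_rng(s_profiles)
    profiles = [
        AnthropometricProfile(
            height=float(np.clip(rng.normal(1.75, 0.11), 1.5, 2.0)),
            mass=float(np.clip(rng.normal(66.8, 12.2), 45.0, 100.0)),
            name=f"ab{i+1}",
        )
        for i in range(config.n_subjects)
    ]

    kwargs = {} if config.circuit is None else {"spec": config.circuit}
    cohort = make_cohort(config.n_trials, profiles, config.style, seed=s_cohort, **kwargs)
    table = load_anthropometry()
    traces = [trial_momentum(t, table) for t in cohort]
    inputs = [trial_imu(t, noise=None) for t in cohort]
    targets = [tr.channels() for tr in traces]

    ts = TrialSet(inputs=inputs, targets=targets)
    partition_trials(ts, config.fractions, seed=s_part)
    model, train_report = scg_train(ts, replace(config.narx, seed=s_narx))

    idx_test = ts.indices("test")
    noise_seeds = np.random.SeedSequence(s_noise).generate_state(len(idx_test)) % 2**31
    ab = _evaluate_cohort(
        model,
        [cohort[i] for i in idx_test],
        [traces[i] for i in idx_test],
        config.noise,
        noise_seeds,
        config.closed_loop,
    )

    pd_style = pd_surrogate(
        config.style,
        arm_swing_factor=config.pd_arm_swing_factor,
        asymmetry=config.pd_asymmetry,
        speed_factor=config.pd_speed_factor,
    )
    pd_cohort = make_cohort(
        config.n_pd_trials, list(PD_PROFILES), pd_style, seed=s_pd, **kwargs
    )
    pd_traces = [trial_momentum(t, table) for t in pd_cohort]
    pd_noise_seeds = (
        np.random.SeedSequence(s_pd_noise).generate_state(len(pd_cohort)) % 2**31
    )
    pdc = _evaluate_cohort(
        model, pd_cohort, pd_traces, config.noise, pd_noise_seeds, config.closed_loop
    )

    nm_ab, ns_ab = _error_tables(ab["nrmse"])
    nm_pd, ns_pd = _error_tables(pdc["nrmse"])
    return EvaluationReport(
        pooled_r={"able_bodied": ab["r_open"], "pd": pdc["r_open"]},
        pooled_r_closed=(
            {"able_bodied": ab["r_closed"], "pd": pdc["r_closed"]}
            if config.closed_loop
            else {}
        ),
        nrmse_mean={"able_bodied": nm_ab, "pd": nm_pd},
        nrmse_sd={"able_bodied": ns_ab, "pd": ns_pd},
        per_task={"able_bodied": ab["per_task"], "pd": pdc["per_task"]},
        config=config,
        train_report=train_report,
        model=model,
    )
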