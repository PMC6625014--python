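"""Nonlinear autoregressive network with exogenous inputs (NARX).

A feedforward network fed by tapped delay lines: the regressor at frame t
concatenates lagged copies of the 30 exogenous input channels (taps 0..8)
and of the 15 output channels (taps 1..8). One hidden layer of logistic
sigmoid units and a linear output layer. Training is teacher-forced
(series-parallel: ground-truth outputs fill the output taps) and uses
Moller's scaled conjugate gradient with early stopping on a validation
partition; deployment-style prediction can run closed-loop, feeding the
network its own past predictions.

Everything is plain numpy and deterministic given the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

__all__ = [
    "NarxConfig",
    "Scaler",
    "NarxModel",
    "TrainReport",
    "TrialSet",
    "assemble_regressors",
    "forward",
    "scg_train",
    "predict_open_loop",
    "predict_closed_loop",
    "partition_trials",
]


@dataclass(frozen=True)
class NarxConfig:
    """Architecture and training hyperparameters."""

    n_inputs: int = 30
    n_outputs: int = 15
    n_hidden: int = 30
    input_taps: tuple[int, ...] = tuple(range(9))  # current + 8 previous
    output_taps: tuple[int, ...] = tuple(range(1, 9))  # 8 previous
    activation: str = "logistic"  # or "identity" (linear network)
    max_epochs: int = 300
    patience: int = 6
    seed: int = 0
    scg_sigma: float = 5e-5
    scg_lambda: float = 5e-7

    def __post_init__(self) -> None:
        if not self.input_taps or not self.output_taps:
            raise ValueError("delay tap sets must be non-empty")
        if 0 in self.output_taps:
            raise ValueError("output taps must exclude lag 0 (the prediction target)")
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")
        if self.activation not in ("logistic", "identity"):
            raise ValueError("activation must be 'logistic' or 'identity'")

    @property
    def max_lag(self) -> int:
        return max(max(self.input_taps), max(self.output_taps))

    @property
    def regressor_dim(self) -> int:
        return len(self.input_taps) * self.n_inputs + len(self.output_taps) * self.n_outputs


@dataclass
class Scaler:
    """Per-channel affine min-max map to [-1, 1], range floored."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, arrays: list[np.ndarray], floor: float = 1e-12) -> "Scaler":
        stacked = np.concatenate(arrays, axis=0)
        lo = stacked.min(axis=0)
        hi = stacked.max(axis=0)
        degenerate = hi - lo < floor
        hi = np.where(degenerate, lo + 1.0, hi)
        return cls(lo=lo, hi=hi)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * (x + 1.0) * (self.hi - self.lo) + self.lo


@dataclass
class TrialSet:
    """Synchronized per-trial (30-channel input, 15-channel target) pairs."""

    inputs: list[np.ndarray]  # each (n_t, 30)
    targets: list[np.ndarray]  # each (n_t, 15)
    partition: np.ndarray = None  # (n_trials,) of {"train","val","test"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets must pair one-to-one")
        for u, y in zip(self.inputs, self.targets):
            if u.shape[0] != y.shape[0]:
                raise ValueError("input/target length mismatch within a trial")

    @property
    def n_trials(self) -> int:
        return len(self.inputs)

    def indices(self, part: str) -> np.ndarray:
        if self.partition is None:
            raise ValueError("trial set is not partitioned")
        return np.flatnonzero(self.partition == part)


@dataclass
class TrainReport:
    """Per-epoch error history and stopping information."""

    train_mse: list[float]
    val_mse: list[float]
    test_mse: list[float]
    best_epoch: int
    stop_reason: str
    seed: int
    final_lambda: float

    @property
    def n_epochs(self) -> int:
        return len(self.train_mse)


@dataclass
class NarxModel:
    """Weights, biases and channel scalers of the trained network."""

    W1: np.ndarray  # (hidden, regressor_dim)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (n_outputs, hidden)
    b2: np.ndarray  # (n_outputs,)
    in_scaler: Scaler
    out_scaler: Scaler
    config: NarxConfig

    @classmethod
    def initialize(cls, config: NarxConfig, in_scaler: Scaler, out_scaler: Scaler) -> "NarxModel":
        rng = np.random.default_rng(config.seed)
        d = config.regressor_dim
        lim1 = 1.0 / np.sqrt(d)
        lim2 = 1.0 / np.sqrt(config.n_hidden)
        return cls(
            W1=rng.uniform(-lim1, lim1, (config.n_hidden, d)),
            b1=rng.uniform(-lim1, lim1, config.n_hidden),
            W2=rng.uniform(-lim2, lim2, (config.n_outputs, config.n_hidden)),
            b2=rng.uniform(-lim2, lim2, config.n_outputs),
            in_scaler=in_scaler,
            out_scaler=out_scaler,
            config=config,
        )

    # -- parameter vector packing -------------------------------------
    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(), self.b2])

    def unpack(self, w: np.ndarray) -> None:
        c = self.config
        d = c.regressor_dim
        i = 0
        self.W1 = w[i : i + c.n_hidden * d].reshape(c.n_hidden, d)
        i += c.n_hidden * d
        self.b1 = w[i : i + c.n_hidden].copy()
        i += c.n_hidden
        self.W2 = w[i : i + c.n_outputs * c.n_hidden].reshape(c.n_outputs, c.n_hidden)
        i += c.n_outputs * c.n_hidden
        self.b2 = w[i:].copy()

    @property
    def n_params(self) -> int:
        return self.pack().size

    def regressor_scale_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """lo/hi expanded to regressor layout (inputs per tap, outputs per tap)."""
        c = self.config
        lo = np.concatenate(
            [np.tile(self.in_scaler.lo, len(c.input_taps)),
             np.tile(self.out_scaler.lo, len(c.output_taps))]
        )
        hi = np.concatenate(
            [np.tile(self.in_scaler.hi, len(c.input_taps)),
             np.tile(self.out_scaler.hi, len(c.output_taps))]
        )
        return lo, hi

    def save(self, path: str) -> None:
        np.savez(
            path,
            W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
            in_lo=self.in_scaler.lo, in_hi=self.in_scaler.hi,
            out_lo=self.out_scaler.lo, out_hi=self.out_scaler.hi,
            config=json.dumps(asdict(self.config)),
            format_version=1,
        )

    @classmethod
    def load(cls, path: str) -> "NarxModel":
        z = np.load(path, allow_pickle=False)
        cfg = json.loads(str(z["config"]))
        cfg["input_taps"] = tuple(cfg["input_taps"])
        cfg["output_taps"] = tuple(cfg["output_taps"])
        return cls(
            W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"],
            in_scaler=Scaler(z["in_lo"], z["in_hi"]),
            out_scaler=Scaler(z["out_lo"], z["out_hi"]),
            config=NarxConfig(**cfg),
        )


# ---------------------------------------------------------------------------
# regressors and forward pass

def assemble_regressors(
    u: np.ndarray, y: np.ndarray, config: NarxConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Teacher-forced (open-loop) regressor rows and aligned targets.

    For every frame t >= max lag the regressor concatenates
    ``u[t - d]`` over the input taps and ``y[t - d]`` over the output taps
    (ground-truth y, i.e. series-parallel mode); the target is ``y[t]``.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    L = config.max_lag
    n = u.shape[0]
    if y.shape[0] != n:
        raise ValueError("input and output sequences must have equal length")
    if n < L + 1:
        raise ValueError(f"sequence length {n} shorter than max lag + 1 = {L + 1}")
    rows = []
    for d in config.input_taps:
        rows.append(u[L - d : n - d])
    for d in config.output_taps:
        rows.append(y[L - d : n - d])
    return np.concatenate(rows, axis=1), y[L:]


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    return expit(z) if kind == "logistic" else z


def _forward_scaled(model: NarxModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = _activate(X @ model.W1.T + model.b1, model.config.activation)
    return A @ model.W2.T + model.b2, A


def forward(model: NarxModel, regressor: np.ndarray) -> np.ndarray:
    """Network output for raw (unscaled) regressor rows.

    Scales each regressor entry with its channel's scaler, runs
    y = W2 sigma(W1 x + b1) + b2 in scaled space, and unscales the output.
    Accepts a single regressor vector or a batch of rows.
    """
    x = np.asarray(regressor, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None]
    if x.shape[1] != model.config.regressor_dim:
        raise ValueError(
            f"regressor dim {x.shape[1]} != expected {model.config.regressor_dim}"
        )
    lo, hi = model.regressor_scale_vectors()
    Xs = 2.0 * (x - lo) / (hi - lo) - 1.0
    Ys, _ = _forward_scaled(model, Xs)
    Y = model.out_scaler.inverse(Ys)
    return Y[0] if single else Y


# ---------------------------------------------------------------------------
# loss and gradient (scaled space)

def _loss(model: NarxModel, w: np.ndarray, X: np.ndarray, T: np.ndarray) -> float:
    model.unpack(w)
    Y, _ = _forward_scaled(model, X)
    return 0.5 * float(np.mean((Y - T) ** 2))


def _loss_grad(
    model: NarxModel, w: np.ndarray, X: np.ndarray, T: np.ndarray
) -> tuple[float, np.ndarray]:
    model.unpack(w)
    Z = X @ model.W1.T + model.b1
    A = _activate(Z, model.config.activation)
    Y = A @ model.W2.T + model.b2
    err = Y - T
    E = 0.5 * float(np.mean(err**2))
    d2 = err / err.size  # dE/dY
    gW2 = d2.T @ A
    gb2 = d2.sum(axis=0)
    dA = d2 @ model.W2
    if model.config.activation == "logistic":
        dZ = dA * A * (1.0 - A)
    else:
        dZ = dA
    gW1 = dZ.T @ X
    gb1 = dZ.sum(axis=0)
    g = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return E, g


def _mse(model: NarxModel, w: np.ndarray, X: np.ndarray, T: np.ndarray) -> float:
    model.unpack(w)
    Y, _ = _forward_scaled(model, X)
    return float(np.mean((Y - T) ** 2))


# ---------------------------------------------------------------------------
# scaled conjugate gradient (Moller 1993)

def _scg(
    model: NarxModel,
    w0: np.ndarray,
    X: np.ndarray,
    T: np.ndarray,
    on_epoch,
    max_epochs: int,
    sigma0: float,
    lam0: float,
) -> tuple[np.ndarray, float, str]:
    """Minimize the training loss from ``w0``.

    Second-order information enters through Hessian-vector products
    approximated by finite-differencing the gradient along the search
    direction; lambda adapts Levenberg-Marquardt style; the direction
    restarts to steepest descent every ``len(w0)`` iterations.

    ``on_epoch(k, w)`` is called after every iteration and may return True
    to request a stop (early stopping hook).
    """
    w = w0.copy()
    N = w.size
    E, g = _loss_grad(model, w, X, T)
    r = -g
    p = r.copy()
    lam, lam_bar = lam0, 0.0
    success = True
    reason = "max_epochs"
    delta_raw = 1.0
    for k in range(1, max_epochs + 1):
        p2 = float(p @ p)
        pnorm = np.sqrt(p2)
        if pnorm < 1e-15:
            reason = "gradient_vanished"
            break
        if success:
            sigma = sigma0 / pnorm
            _, g_sig = _loss_grad(model, w + sigma * p, X, T)
            s = (g_sig - g) / sigma  # Hessian-vector product along p
            delta_raw = float(p @ s)
        # scale curvature with lambda
        delta = delta_raw + (lam - lam_bar) * p2
        if delta <= 0:  # make Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p2)
            delta = -delta + lam * p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        E_new = _loss(model, w + alpha * p, X, T)
        Delta = 2.0 * delta * (E - E_new) / (mu * mu)
        if Delta >= 0:
            w = w + alpha * p
            E, g = _loss_grad(model, w, X, T)
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % N == 0:
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lam *= 0.25
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam += delta * (1.0 - Delta) / p2
        if not np.isfinite(E):
            raise FloatingPointError("SCG: non-finite training loss")
        if on_epoch(k, w):
            reason = "patience"
            break
        if float(np.abs(r).max()) < 1e-12:
            reason = "converged"
            break
    return w, lam, reason


def scg_train(trials: TrialSet, config: NarxConfig) -> tuple[NarxModel, TrainReport]:
    """Train on the trial set's training partition, teacher-forced.

    Channel scalers are fitted on the training partition only. Returns the
    weights achieving the best validation MSE, with the per-epoch error
    history. Deterministic given ``config.seed`` and the data.
    """
    if trials.partition is None:
        raise ValueError("partition the trial set before training")
    idx_train = trials.indices("train")
    if idx_train.size < 1:
        raise ValueError("need at least one training trial")
    in_scaler = Scaler.fit([trials.inputs[i] for i in idx_train])
    out_scaler = Scaler.fit([trials.targets[i] for i in idx_train])
    model = NarxModel.initialize(config, in_scaler, out_scaler)

    def build(part: str) -> tuple[np.ndarray, np.ndarray]:
        Xs, Ts = [], []
        for i in trials.indices(part):
            X, T = assemble_regressors(
                in_scaler.transform(trials.inputs[i]),
                out_scaler.transform(trials.targets[i]),
                config,
            )
            Xs.append(X)
            Ts.append(T)
        if not Xs:
            return np.zeros((0, config.regressor_dim)), np.zeros((0, config.n_outputs))
        return np.concatenate(Xs), np.concatenate(Ts)

    Xtr, Ttr = build("train")
    Xva, Tva = build("val")
    Xte, Tte = build("test")

    hist = {"train": [], "val": [], "test": []}
    best = {"val": np.inf, "w": model.pack(), "epoch": 0}

    def on_epoch(k: int, w: np.ndarray) -> bool:
        hist["train"].append(_mse(model, w, Xtr, Ttr))
        va = _mse(model, w, Xva, Tva) if Xva.size else np.nan
        te = _mse(model, w, Xte, Tte) if Xte.size else np.nan
        hist["val"].append(va)
        hist["test"].append(te)
        if Xva.size and va < best["val"]:
            best.update(val=va, w=w.copy(), epoch=k)
        if Xva.size and k - best["epoch"] > config.patience:
            return True
        return False

    w_final, lam, reason = _scg(
        model, model.pack(), Xtr, Ttr, on_epoch,
        config.max_epochs, config.scg_sigma, config.scg_lambda,
    )
    w_best = best["w"] if Xva.size else w_final
    model.unpack(w_best)
    report = TrainReport(
        train_mse=hist["train"],
        val_mse=hist["val"],
        test_mse=hist["test"],
        best_epoch=best["epoch"] if Xva.size else len(hist["train"]),
        stop_reason=reason,
        seed=config.seed,
        final_lambda=lam,
    )
    return model, report


# ---------------------------------------------------------------------------
# prediction

def predict_open_loop(model: NarxModel, u: np.ndarray, y_true: np.ndarray) -> np.ndarray:
    """Teacher-forced prediction: output taps filled with ground truth.

    Returns an ``(n, n_outputs)`` array; the first ``max_lag`` frames are
    copied from ``y_true`` (no prediction exists before one full delay
    line), the rest are network outputs.
    """
    c = model.config
    Xs, _ = assemble_regressors(
        model.in_scaler.transform(u), model.out_scaler.transform(y_true), c
    )
    Ys, _ = _forward_scaled(model, Xs)
    out = np.asarray(y_true, dtype=float).copy()
    out[c.max_lag :] = model.out_scaler.inverse(Ys)
    return out


def predict_closed_loop(
    model: NarxModel, u: np.ndarray, y_init: np.ndarray | None = None
) -> np.ndarray:
    """Autoregressive simulation: output taps filled with own predictions.

    ``y_init`` provides the first ``max_lag`` frames of output history
    (ground truth in practice); pass None to start from zero history.
    Strictly causal: the prediction at frame t uses inputs up to t and
    predictions before t.
    """
    c = model.config
    u = np.asarray(u, dtype=float)
    n = u.shape[0]
    L = c.max_lag
    if n < L + 1:
        raise ValueError("input shorter than max lag + 1")
    us = model.in_scaler.transform(u)
    ys = np.zeros((n, c.n_outputs))
    if y_init is not None:
        if y_init.shape[0] < L:
            raise ValueError(f"y_init must provide at least {L} frames")
        ys[:L] = model.out_scaler.transform(y_init[:L])
    for t in range(L, n):
        reg = np.concatenate(
            [us[t - d] for d in c.input_taps] + [ys[t - d] for d in c.output_taps]
        )
        A = _activate(model.W1 @ reg + model.b1, c.activation)
        ys[t] = model.W2 @ A + model.b2
    return model.out_scaler.inverse(ys)


def partition_trials(trials: TrialSet, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> TrialSet:
    """Random train/val/test split by whole trial (never by frame).

    Validation and test counts are rounded from the fractions with a floor
    of one trial each; reproducible by seed.
    """
    n = trials.n_trials
    if n < 3:
        raise ValueError("need at least 3 trials to partition")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = max(1, int(round(fractions[1] * n)))
    n_test = max(1, int(round(fractions[2] * n)))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("fractions leave no training trials")
    order = np.random.default_rng(seed).permutation(n)
    part = np.empty(n, dtype=object)
    part[order[:n_train]] = "train"
    part[order[n_train : n_train + n_val]] = "val"
    part[order[n_train + n_val :]] = "test"
    trials.partition = part.astype(str)
    return trials
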