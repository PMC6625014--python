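"""Readers and writers: TRC marker files, CSV signal tables, trial archives.

A trial archive is a plain directory holding ``markers.trc``,
``template.json`` (segment -> marker -> local coordinates),
``meta.json`` (subject anthropometrics, rate, seed) and ``labels.csv``
(per-frame task labels), plus any derived ``momentum.csv`` / ``imu.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .body_model import MarkerSeries
from .momentum import MomentumTrace
from .synthetic_gait import AnthropometricProfile, SyntheticTrial
from .virtual_imu import imu_channel_names

__all__ = [
    "write_trc",
    "read_trc",
    "momentum_to_csv",
    "momentum_from_csv",
    "imu_to_csv",
    "imu_from_csv",
    "write_trial",
    "read_trial",
]


def write_trc(markers: MarkerSeries, path: str | Path, name: str = "trial") -> None:
    """Write markers in the tab-separated TRC motion-capture format."""
    n, m = markers.n_frames, len(markers.labels)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{name}.trc\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{markers.rate:g}\t{markers.rate:g}\t{n}\t{m}\tm\t{markers.rate:g}\t1\t{n}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(markers.labels) + "\n")
        fh.write(
            "\t\t"
            + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m))
            + "\n\n"
        )
        t = markers.time
        for i in range(n):
            row = markers.data[i].ravel()
            fh.write(
                f"{i+1}\t{t[i]:.5f}\t" + "\t".join(f"{v:.8f}" for v in row) + "\n"
            )


def read_trc(path: str | Path) -> MarkerSeries:
    with open(path) as fh:
        lines = fh.read().splitlines()
    rate = float(lines[2].split("\t")[0])
    header = lines[3].split("\t")
    labels = [h for h in header[2:] if h.strip()]
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        rows.append([float(v) for v in parts[2:] if v.strip() != ""])
    data = np.asarray(rows).reshape(len(rows), len(labels), 3)
    return MarkerSeries(labels, data, rate)


def momentum_to_csv(trace: MomentumTrace, path: str | Path) -> None:
    """Momentum trace as a time + 15-channel table.

    Channels are group-major (leg_l, leg_r, arm_l, arm_r, trunk), axes
    (anterior, mediolateral, vertical) of the moving body frame; values
    are normalized by height*mass when the trace is normalized.
    """
    df = pd.DataFrame(trace.channels(), columns=MomentumTrace.channel_names())
    df.insert(0, "time", trace.time)
    with open(path, "w") as fh:
        fh.write(
            f"# body-frame momentum, normalized={trace.normalized}, "
            f"height={trace.height:g} m, mass={trace.mass:g} kg\n"
        )
        df.to_csv(fh, index=False)


def momentum_from_csv(path: str | Path) -> MomentumTrace:
    with open(path) as fh:
        head = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(
        item.strip().split("=") for item in head.lstrip("#").split(",") if "=" in item
    )
    time = df["time"].to_numpy()
    data = df[MomentumTrace.channel_names()].to_numpy().reshape(len(df), 5, 3)
    return MomentumTrace(
        time=time,
        data=data,
        normalized=meta.get("normalized", "True").strip() == "True",
        height=float(meta.get("height", "0").split()[0]),
        mass=float(meta.get("mass", "0").split()[0]),
    )


def imu_to_csv(matrix: np.ndarray, rate: float, path: str | Path) -> None:
    """30-channel IMU stream, sensor-major (see channel names in header)."""
    df = pd.DataFrame(matrix, columns=imu_channel_names())
    df.insert(0, "time", np.arange(matrix.shape[0]) / rate)
    df.to_csv(path, index=False)


def imu_from_csv(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    rate = 1.0 / (t[1] - t[0])
    return df[imu_channel_names()].to_numpy(), float(round(rate, 6))


def write_trial(trial: SyntheticTrial, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_trc(trial.markers, d / "markers.trc")
    tpl = {
        seg: {lab: np.asarray(p).tolist() for lab, p in local.items()}
        for seg, local in trial.template.items()
    }
    (d / "template.json").write_text(json.dumps(tpl))
    meta = {
        "height": trial.profile.height,
        "mass": trial.profile.mass,
        "name": trial.profile.name,
        "rate": trial.rate,
        "seed": trial.seed,
    }
    (d / "meta.json").write_text(json.dumps(meta))
    pd.Series(trial.labels, name="task").to_csv(d / "labels.csv", index=False)


def read_trial(directory: str | Path) -> SyntheticTrial:
    d = Path(directory)
    markers = read_trc(d / "markers.trc")
    tpl_raw = json.loads((d / "template.json").read_text())
    template = {
        seg: {lab: np.asarray(p, dtype=float) for lab, p in local.items()}
        for seg, local in tpl_raw.items()
    }
    meta = json.loads((d / "meta.json").read_text())
    labels = pd.read_csv(d / "labels.csv")["task"].to_numpy(dtype=object)
    profile = AnthropometricProfile(
        height=meta["height"], mass=meta["mass"], name=meta.get("name", "subject")
    )
    return SyntheticTrial(
        markers=markers,
        template=template,
        profile=profile,
        labels=labels,
        seed=meta.get("seed", 0),
    )
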