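"""File formats for traces, recordings, metrics, scores and models.

CSV carries small tabular artifacts (traces as ``t,x,y``, LFP as ``t,v``,
metric matrices, MES series, feature matrices with ``band_sub`` headers);
HDF5 carries sessions (``/behavior/{cursor,target}`` and ``/lfp/v`` with
``fs`` attributes).  Models serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from stnmes.behavior import METRICS, MetricMatrix, Trace
from stnmes.mes import MESeries, MESModel
from stnmes.spectral import LFPRecording, SpectralFeatures, build_band_scheme


def write_trace_csv(trace: Trace, path) -> None:
    pd.DataFrame({"t": trace.t, "x": trace.x, "y": trace.y}).to_csv(path, index=False)


def read_trace_csv(path, fs: float | None = None, role: str = "cursor") -> Trace:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return Trace(t=t, x=df["x"].to_numpy(float), y=df["y"].to_numpy(float), fs=fs, role=role)


def write_behavior_h5(cursor: Trace, target: Trace, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("behavior")
        for name, tr in (("cursor", cursor), ("target", target)):
            d = g.create_dataset(name, data=np.column_stack([tr.t, tr.x, tr.y]))
            d.attrs["fs"] = tr.fs


def read_behavior_h5(path) -> tuple[Trace, Trace]:
    with h5py.File(path, "r") as f:
        out = []
        for name in ("cursor", "target"):
            d = f[f"behavior/{name}"]
            arr = d[()]
            out.append(
                Trace(t=arr[:, 0], x=arr[:, 1], y=arr[:, 2], fs=float(d.attrs["fs"]), role=name)
            )
    return out[0], out[1]


def write_lfp_h5(rec: LFPRecording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp/v", data=rec.v)
        d.attrs["fs"] = rec.fs
        f.create_dataset("lfp/mask", data=rec.mask.astype(np.uint8))


def read_lfp_h5(path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        d = f["lfp/v"]
        mask = f["lfp/mask"][()].astype(bool) if "lfp/mask" in f else None
        return LFPRecording(v=d[()], fs=float(d.attrs["fs"]), mask=mask)


def write_lfp_csv(rec: LFPRecording, path) -> None:
    t = np.arange(len(rec)) / rec.fs
    pd.DataFrame({"t": t, "v": rec.v}).to_csv(path, index=False)


def read_lfp_csv(path) -> LFPRecording:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t)))
    return LFPRecording(v=df["v"].to_numpy(float), fs=round(fs))


def read_metrics_csv(path, epoch_len: float | None = None) -> MetricMatrix:
    df = pd.read_csv(path)
    epochs = df[["epoch_start", "epoch_end"]].to_numpy(float)
    if epoch_len is None:
        epoch_len = float(np.median(epochs[:, 1] - epochs[:, 0]))
    return MetricMatrix(
        epochs=epochs, values=df[list(METRICS)], epoch_len=epoch_len
    )


def write_mes_csv(series: MESeries, path) -> None:
    pd.DataFrame(
        {
            "epoch_start": series.times[:, 0],
            "epoch_end": series.times[:, 1],
            "mes": series.mes,
        }
    ).to_csv(path, index=False)


def read_mes_csv(path) -> MESeries:
    df = pd.read_csv(path)
    times = df[["epoch_start", "epoch_end"]].to_numpy(float)
    el = float(np.median(times[:, 1] - times[:, 0]))
    return MESeries(times=times, mes=df["mes"].to_numpy(float), epoch_len=el)


def write_features_csv(features: SpectralFeatures, path) -> None:
    df = features.values.copy()
    df.insert(0, "epoch_start", features.times[:, 0])
    df.insert(1, "epoch_end", features.times[:, 1])
    df.to_csv(path, index=False)


def read_features_csv(path) -> SpectralFeatures:
    df = pd.read_csv(path)
    times = df[["epoch_start", "epoch_end"]].to_numpy(float)
    scheme = build_band_scheme()
    vals = df[list(scheme.feature_names)]
    el = float(np.median(times[:, 1] - times[:, 0]))
    return SpectralFeatures(times=times, values=vals, scheme=scheme, epoch_len=el)


def write_mes_model(model: MESModel, path) -> None:
    payload = {
        "w": model.w.tolist(),
        "b": model.b,
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "cv_auc": model.cv_auc,
        "fold_aucs": model.fold_aucs.tolist(),
        "n_folds": model.n_folds,
        "split": list(model.split),
        "metrics": list(model.metrics),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_mes_model(path) -> MESModel:
    d = json.loads(Path(path).read_text())
    return MESModel(
        w=np.asarray(d["w"], float),
        b=float(d["b"]),
        mean=np.asarray(d["mean"], float),
        sd=np.asarray(d["sd"], float),
        cv_auc=float(d["cv_auc"]),
        fold_aucs=np.asarray(d["fold_aucs"], float),
        n_folds=int(d["n_folds"]),
        split=tuple(d["split"]),
        metrics=tuple(d["metrics"]),
    )
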