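"""NPZ archive layouts for intermediate pipeline artifacts.

Window archive: per-window channel arrays (``w{i}_{channel}``) plus label,
start, subject, provenance vectors and a JSON metadata blob with rates.
Feature archive: the two branch tensors, labels, provenance, scaler state
and ordering metadata.  Both round-trip losslessly.
"""

from __future__ import annotations

import json

import numpy as np

from mmfd.features import FeatureDataset, FeatureScaler
from mmfd.preprocess import Window

__all__ = ["save_windows", "load_windows", "save_features", "load_features"]


def save_windows(path, windows: list[Window]) -> None:
    meta = {
        "n": len(windows),
        "subjects": [w.subject for w in windows],
        "starts": [w.start_s for w in windows],
        "lengths": [w.length_s for w in windows],
        "labels": [None if w.label is None else int(w.label) for w in windows],
        "provenance": [w.provenance for w in windows],
        "rates": [w.rates for w in windows],
        "channels": [w.channel_names for w in windows],
    }
    arrays = {}
    for i, w in enumerate(windows):
        for ch, vals in w.channels.items():
            arrays[f"w{i}_{ch}"] = vals
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_windows(path) -> list[Window]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        windows = []
        for i in range(meta["n"]):
            channels = {ch: data[f"w{i}_{ch}"] for ch in meta["channels"][i]}
            windows.append(
                Window(
                    subject=meta["subjects"][i],
                    start_s=meta["starts"][i],
                    length_s=meta["lengths"][i],
                    channels=channels,
                    rates=meta["rates"][i],
                    label=meta["labels"][i],
                    provenance=meta["provenance"][i],
                )
            )
    return windows


def save_features(path, dataset: FeatureDataset) -> None:
    arrays = {
        "X_t": dataset.X_t,
        "X_f": dataset.X_f,
        "y": dataset.y,
        "provenance": dataset.provenance.astype(str),
    }
    if dataset.scaler is not None:
        arrays.update(
            scaler_t_mean=dataset.scaler.t_mean,
            scaler_t_sd=dataset.scaler.t_sd,
            scaler_f_mean=dataset.scaler.f_mean,
            scaler_f_sd=dataset.scaler.f_sd,
        )
    np.savez(path, meta=json.dumps(dataset.meta), **arrays)


def load_features(path) -> FeatureDataset:
    with np.load(path, allow_pickle=False) as data:
        scaler = None
        if "scaler_t_mean" in data.files:
            scaler = FeatureScaler(
                t_mean=data["scaler_t_mean"],
                t_sd=data["scaler_t_sd"],
                f_mean=data["scaler_f_mean"],
                f_sd=data["scaler_f_sd"],
            )
        return FeatureDataset(
            X_t=data["X_t"],
            X_f=data["X_f"],
            y=data["y"],
            provenance=data["provenance"].astype(str),
            meta=json.loads(str(data["meta"])),
            scaler=scaler,
        )
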