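"""Artifact serialization: HDF5 weight snapshots, CSV rasters, JSON metrics."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .core import ModelKind, NetworkWeights

__all__ = [
    "save_weights",
    "load_weights",
    "events_to_csv",
    "events_from_csv",
    "save_metrics_json",
]


def save_weights(path, weights: NetworkWeights, attrs: Optional[dict] = None) -> None:
    """Write all populated matrices as HDF5 datasets plus a JSON attribute
    block (kind, N, K, and any caller-supplied metadata such as step/seed)."""
    with h5py.File(path, "w") as f:
        for name, mat in weights.matrices().items():
            f.create_dataset(name, data=mat)
        if weights.W_mask is not None:
            f.create_dataset("W_mask", data=weights.W_mask)
        for name in ("mask_exc", "mask_inh", "mask_G"):
            m = getattr(weights, name)
            if m is not None:
                f.create_dataset(name, data=m.astype(np.uint8))
        meta = {"kind": weights.kind.value, "N": weights.N, "K": weights.K}
        if weights.n_exc is not None:
            meta["n_exc"] = weights.n_exc
        if attrs:
            meta.update(attrs)
        f.attrs["meta"] = json.dumps(meta)


def load_weights(path) -> tuple[NetworkWeights, dict]:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        kind = ModelKind(meta["kind"])
        kw = {"kind": kind, "W": f["W"][...]}
        names = {
            ModelKind.NDL: ("M", "G"),
            ModelKind.SIGNED: ("M_exc", "M_inh", "G"),
            ModelKind.DL: ("M_XE", "G_path1", "G_path2"),
        }[kind]
        for n in names:
            kw[n] = f[n][...]
        for n in ("mask_exc", "mask_inh", "mask_G"):
            if n in f:
                kw[n] = f[n][...].astype(bool)
        if "W_mask" in f:
            kw["W_mask"] = f["W_mask"][...]
        if "n_exc" in meta:
            kw["n_exc"] = meta["n_exc"]
    return NetworkWeights(**kw), meta


def events_to_csv(path, events: np.ndarray, population: str = "net") -> None:
    """Spike raster as an event list: ``neuron_id,time_ms,population``."""
    df = pd.DataFrame(
        {
            "neuron_id": events[:, 0].astype(int) if len(events) else [],
            "time_ms": events[:, 1] if len(events) else [],
            "population": population,
        }
    )
    df.to_csv(path, index=False)


def events_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_metrics_json(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
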