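"""On-disk formats: HDF5 recordings with BIDS-style TSV sidecars, tidy CSV
feature tables, and connectivity matrices."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ncreann import ConnectivityResult
from .synth import Recording
from .tfr import ErspMap

__all__ = [
    "save_recording",
    "load_recording",
    "save_ersp",
    "load_ersp",
    "save_connectivity",
    "load_connectivity_long",
]


def save_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as ``<stem>.h5`` (datasets /signal, /time; attrs
    fs, labels, grid) plus ``<stem>_events.tsv`` and ``<stem>_channels.tsv``.
    """
    path = Path(path)
    stem = path.with_suffix("")
    with h5py.File(stem.with_suffix(".h5"), "w") as f:
        f.create_dataset("signal", data=recording.signal, compression="gzip")
        f.create_dataset(
            "time", data=np.arange(recording.signal.shape[1]) / recording.fs
        )
        f.attrs["fs"] = recording.fs
        f.attrs["channel_labels"] = list(recording.channel_labels)
        f.attrs["grid_xy"] = recording.grid_xy
        f.attrs["meta"] = json.dumps(recording.meta, default=str)
    ev = recording.events.rename(columns={"tone_type": "trial_type"})
    ev.to_csv(stem.parent / f"{stem.name}_events.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "name": recording.channel_labels,
            "x_mm": recording.grid_xy[:, 0],
            "y_mm": recording.grid_xy[:, 1],
        }
    ).to_csv(stem.parent / f"{stem.name}_channels.tsv", sep="\t", index=False)


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    stem = path.with_suffix("")
    with h5py.File(stem.with_suffix(".h5"), "r") as f:
        signal = f["signal"][()]
        fs = float(f.attrs["fs"])
        labels = tuple(str(x) for x in f.attrs["channel_labels"])
        grid = np.asarray(f.attrs["grid_xy"])
        meta = json.loads(f.attrs["meta"])
    events = pd.read_csv(stem.parent / f"{stem.name}_events.tsv", sep="\t")
    events = events.rename(columns={"trial_type": "tone_type"})
    return Recording(
        signal=signal, fs=fs, channel_labels=labels, grid_xy=grid,
        events=events, meta=meta,
    )


def save_ersp(ersp: ErspMap, path: str | Path) -> None:
    """Write an ERSP map as HDF5: /values (channels x freqs x times, dB)
    plus the frequency and time axes and the analysis parameters."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=ersp.values, compression="gzip")
        f.create_dataset("freqs", data=ersp.freqs)
        f.create_dataset("times", data=ersp.times)
        f.attrs["channel_labels"] = list(ersp.channel_labels)
        f.attrs["params"] = json.dumps(ersp.params, default=str)
        f.attrs["meta"] = json.dumps(ersp.meta, default=str)


def load_ersp(path: str | Path) -> ErspMap:
    with h5py.File(path, "r") as f:
        return ErspMap(
            values=f["values"][()],
            freqs=f["freqs"][()],
            times=f["times"][()],
            channel_labels=tuple(str(x) for x in f.attrs["channel_labels"]),
            params=json.loads(f.attrs["params"]),
            meta=json.loads(f.attrs["meta"]),
        )


def save_connectivity(
    result: ConnectivityResult, outdir: str | Path, prefix: str = "connectivity"
) -> None:
    """Write lC/NC as labelled CSV matrices, a long-format table with
    p-values and significance, and a diagnostics JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = list(result.channel_labels)
    for name, mat in (("lc", result.lc), ("nc", result.nc)):
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(
            outdir / f"{prefix}_{name}.csv"
        )
    rows = []
    M = len(labels)
    for i in range(M):
        for j in range(M):
            if i == j:
                continue
            rows.append(
                {
                    "from": labels[i],
                    "to": labels[j],
                    "lC": result.lc[i, j],
                    "NC": result.nc[i, j],
                    "p_lC": result.p_lc[i, j] if result.p_lc is not None else np.nan,
                    "p_NC": result.p_nc[i, j] if result.p_nc is not None else np.nan,
                    "sig_lC": bool(result.sig_lc[i, j])
                    if result.sig_lc is not None
                    else False,
                    "sig_NC": bool(result.sig_nc[i, j])
                    if result.sig_nc is not None
                    else False,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / f"{prefix}_long.csv", index=False)
    with open(outdir / f"{prefix}_diagnostics.json", "w") as f:
        json.dump(result.diagnostics, f, indent=2, default=float)


def load_connectivity_long(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
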