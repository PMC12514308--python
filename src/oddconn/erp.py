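"""Event-related potentials: condition averages, deviant-minus-standard
difference waves, component peaks and peak-to-peak amplitudes.

Component search windows (ms): P1 20-80, N1 60-150, P2 70-250, N2 100-330,
P3 130-600.  P components are window maxima, N components window minima;
ties go to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "DifferenceErp",
    "COMPONENT_WINDOWS",
    "PEAK_TO_PEAK_PAIRS",
    "average_and_difference",
    "grand_average",
    "detect_peaks",
    "peak_to_peak",
]

COMPONENT_WINDOWS = {
    "P1": (20.0, 80.0),
    "N1": (60.0, 150.0),
    "P2": (70.0, 250.0),
    "N2": (100.0, 330.0),
    "P3": (130.0, 600.0),
}

# (label, positive peak, negative peak); amplitude = amp(positive) - amp(negative)
PEAK_TO_PEAK_PAIRS = (
    ("P1N1", "P1", "N1"),
    ("N1P2", "P2", "N1"),
    ("P2N2", "P2", "N2"),
    ("N2P3", "P3", "N2"),
)


@dataclass
class DifferenceErp:
    data: np.ndarray  # (channels, time), microvolts
    times: np.ndarray  # ms
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)


def average_and_difference(
    epochs: EpochSet,
) -> tuple[np.ndarray, np.ndarray, DifferenceErp]:
    """Per-channel mean over kept trials for each condition and their
    deviant-minus-standard difference wave."""
    means = {}
    for cond in ("standard", "deviant"):
        sel = epochs.kept & (epochs.condition == cond)
        if not sel.any():
            raise ValueError(f"no kept trials in condition {cond!r}")
        means[cond] = epochs.data[sel].mean(axis=0)
    diff = DifferenceErp(
        data=means["deviant"] - means["standard"],
        times=epochs.times.copy(),
        channel_labels=epochs.channel_labels,
        meta={
            **{k: epochs.meta.get(k) for k in ("subject", "group", "treatment")},
            "n_standard": int((epochs.kept & (epochs.condition == "standard")).sum()),
            "n_deviant": int((epochs.kept & (epochs.condition == "deviant")).sum()),
        },
    )
    return means["standard"], means["deviant"], diff


def grand_average(waves: list[DifferenceErp]) -> DifferenceErp:
    """Unweighted mean of subject-level difference waves."""
    if not waves:
        raise ValueError("no waves to average")
    ref = waves[0]
    for w in waves[1:]:
        if not np.allclose(w.times, ref.times):
            raise ValueError("waves have mismatched time axes")
    data = np.mean([w.data for w in waves], axis=0)
    return DifferenceErp(
        data=data,
        times=ref.times.copy(),
        channel_labels=ref.channel_labels,
        meta={"n_subjects": len(waves)},
    )


def detect_peaks(
    wave: DifferenceErp,
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Locate component peaks per channel.

    Returns a tidy frame with columns (component, channel, latency, amplitude),
    latency in ms, amplitude in microvolts read at the peak sample.
    """
    windows = windows if windows is not None else COMPONENT_WINDOWS
    t = wave.times
    rows = []
    for comp, (lo, hi) in windows.items():
        sel = (t >= lo) & (t <= hi)
        if not sel.any():
            raise ValueError(
                f"component window {comp} ({lo}-{hi} ms) outside the wave's "
                f"time axis [{t[0]:.1f}, {t[-1]:.1f}] ms"
            )
        seg = wave.data[:, sel]
        tw = t[sel]
        # argmax/argmin return the first (earliest) extremum on ties
        idx = seg.argmin(axis=1) if comp.startswith("N") else seg.argmax(axis=1)
        for ci, lab in enumerate(wave.channel_labels):
            rows.append((comp, lab, tw[idx[ci]], seg[ci, idx[ci]]))
    return pd.DataFrame(rows, columns=["component", "channel", "latency", "amplitude"])


def peak_to_peak(peaks: pd.DataFrame) -> pd.DataFrame:
    """Append peak-to-peak amplitude rows (P1N1, N1P2, P2N2, N2P3).

    Each span is the positive component's amplitude minus the negative
    component's, so a canonical morphology yields positive spans.
    """
    amp = peaks.set_index(["component", "channel"])["amplitude"]
    channels = peaks["channel"].unique()
    rows = []
    for label, pos, neg in PEAK_TO_PEAK_PAIRS:
        for ch in channels:
            try:
                a = amp[(pos, ch)] - amp[(neg, ch)]
            except KeyError as e:
                raise ValueError(f"missing component row {e.args[0]}") from e
            rows.append((label, ch, np.nan, a))
    extra = pd.DataFrame(rows, columns=["component", "channel", "latency", "amplitude"])
    return pd.concat([peaks, extra], ignore_index=True)
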