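"""Filtering, epoching, artifact rejection, channel interpolation and
feature-table imputation.

The bandpass is a one-pass Kaiser-window FIR (0.1-45 Hz by default) whose
order follows the standard Kaiser design relations; the group delay is
compensated symmetrically so filtered samples stay aligned with the raw
time base.  Epochs span -100..700 ms around tone onset with the pre-stimulus
interval as baseline; trials exceeding a 500 microvolt peak-to-peak delta
criterion are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import Recording

__all__ = [
    "FilterKernel",
    "EpochSet",
    "design_bandpass_fir",
    "apply_filter",
    "epoch_and_baseline",
    "reject_artifacts",
    "interpolate_channel",
    "impute_features",
]


# ---------------------------------------------------------------------------
# FIR design
# ---------------------------------------------------------------------------

@dataclass
class FilterKernel:
    taps: np.ndarray
    fs: float
    band: tuple[float, float]
    order: int
    beta: float
    attenuation_db: float
    ripple: float
    transition_width: float

    @property
    def group_delay(self) -> int:
        return self.order // 2


def design_bandpass_fir(
    fs: float,
    low: float = 0.1,
    high: float = 45.0,
    ripple: float = 0.001,
    transition_width: float = 0.2,
) -> FilterKernel:
    """Kaiser-window FIR bandpass.

    Stopband attenuation A = -20 log10(ripple); the Kaiser shape parameter
    beta and the order N = (A - 8) / (2.285 * dw) (dw the transition width
    in rad/sample) follow Kaiser's empirical design relations.  N is rounded
    up to the next even integer so the group delay N/2 is an integer number
    of samples; the kernel has N + 1 taps.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band ({low}, {high}) Hz at fs={fs}")
    if not (0 < ripple < 1):
        raise ValueError("ripple must be in (0, 1)")
    atten = -20.0 * math.log10(ripple)
    if atten > 50.0:
        beta = 0.1102 * (atten - 8.7)
    elif atten >= 21.0:
        beta = 0.5842 * (atten - 21.0) ** 0.4 + 0.07886 * (atten - 21.0)
    else:
        beta = 0.0
    dw = 2.0 * math.pi * transition_width / fs
    order = math.ceil((atten - 8.0) / (2.285 * dw))
    if order % 2:
        order += 1
    taps = sps.firwin(
        order + 1,
        [low, high],
        window=("kaiser", beta),
        pass_zero=False,
        fs=fs,
    )
    return FilterKernel(
        taps=taps,
        fs=float(fs),
        band=(low, high),
        order=order,
        beta=beta,
        attenuation_db=atten,
        ripple=ripple,
        transition_width=transition_width,
    )


def apply_filter(recording: Recording, kernel: FilterKernel) -> Recording:
    """Filter every channel, compensating the linear-phase group delay.

    The kernel length is odd, so overlap-add convolution in ``same`` mode
    centres the output on the input time base (zero net delay).  Samples
    within half a kernel of either edge are influenced by zero padding and
    flagged via ``meta['edge_invalid_samples']``.
    """
    if kernel.fs != recording.fs:
        raise ValueError("kernel fs does not match recording fs")
    n = recording.signal.shape[1]
    if n <= kernel.taps.size:
        raise ValueError("recording shorter than the filter kernel")
    filtered = sps.oaconvolve(
        recording.signal, kernel.taps[None, :], axes=1, mode="same"
    )
    meta = dict(recording.meta)
    meta["edge_invalid_samples"] = kernel.group_delay
    meta["filter_band"] = kernel.band
    return recording.copy_with(signal=filtered, meta=meta)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Trials x channels x time, time in ms relative to tone onset."""

    data: np.ndarray
    times: np.ndarray  # ms
    condition: np.ndarray  # str per trial
    kept: np.ndarray  # bool per trial
    fs: float
    channel_labels: tuple[str, ...]
    grid_xy: np.ndarray
    meta: dict = field(default_factory=dict)
    rejection_log: pd.DataFrame | None = None
    bad_channels: tuple[str, ...] = ()

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)


def epoch_and_baseline(
    recording: Recording,
    window: tuple[float, float] = (-100.0, 700.0),
    baseline: tuple[float, float] = (-100.0, 0.0),
) -> EpochSet:
    """Cut per-tone epochs and subtract the pre-stimulus mean.

    Both the epoch window and the baseline interval are half-open
    ``[start, stop)`` in ms.  Trials whose window falls outside the
    recording are dropped and listed in ``meta['dropped_trials']``.
    """
    if len(recording.events) == 0:
        raise ValueError("recording has no events to epoch around")
    fs = recording.fs
    n = recording.signal.shape[1]
    n_samp = int(round((window[1] - window[0]) / 1000.0 * fs))
    offset = int(round(window[0] / 1000.0 * fs))
    times = (np.arange(n_samp) + offset) / fs * 1000.0

    onset_samples = np.round(recording.events["onset"].to_numpy() * fs).astype(int)
    starts = onset_samples + offset
    ok = (starts >= 0) & (starts + n_samp <= n)
    dropped = np.nonzero(~ok)[0]

    data = np.stack(
        [recording.signal[:, s : s + n_samp] for s in starts[ok]], axis=0
    )
    bl = (times >= baseline[0]) & (times < baseline[1])
    data = data - data[:, :, bl].mean(axis=2, keepdims=True)

    cond = recording.events["tone_type"].to_numpy()[ok]
    meta = dict(recording.meta)
    meta["dropped_trials"] = dropped.tolist()
    meta["event_index"] = np.nonzero(ok)[0].tolist()
    return EpochSet(
        data=data,
        times=times,
        condition=cond,
        kept=np.ones(data.shape[0], dtype=bool),
        fs=fs,
        channel_labels=recording.channel_labels,
        grid_xy=recording.grid_xy,
        meta=meta,
    )


def reject_artifacts(
    epochs: EpochSet,
    delta_criterion: float = 500.0,
    bad_channel_fraction: float = 0.5,
) -> EpochSet:
    """Reject trials whose within-epoch peak-to-peak range exceeds the delta
    criterion on any retained channel.

    A channel that would by itself reject more than ``bad_channel_fraction``
    of the trials is marked bad (noisy electrode) and excluded from the
    trial-level decision; downstream stages interpolate or drop it.
    """
    if delta_criterion <= 0:
        raise ValueError("delta_criterion must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (trials, ch)
    exceed = ptp > delta_criterion
    ch_rate = exceed.mean(axis=0)
    bad_idx = np.nonzero(ch_rate > bad_channel_fraction)[0]
    bad = tuple(epochs.channel_labels[i] for i in bad_idx)
    good = np.setdiff1d(np.arange(len(epochs.channel_labels)), bad_idx)
    reject = exceed[:, good].any(axis=1)

    trials, chans = np.nonzero(exceed)
    log = pd.DataFrame(
        {
            "trial": trials,
            "channel": [epochs.channel_labels[c] for c in chans],
            "ptp_uV": ptp[trials, chans],
            "channel_marked_bad": np.isin(chans, bad_idx),
        }
    )
    kept = epochs.kept & ~reject
    return epochs.copy_with(kept=kept, rejection_log=log, bad_channels=bad)


def interpolate_channel(epochs: EpochSet, bad_channel: str) -> EpochSet:
    """Replace one channel by the inverse-distance-weighted (power 2)
    average of the remaining good channels on the planar grid."""
    labels = list(epochs.channel_labels)
    if bad_channel not in labels:
        raise ValueError(f"unknown channel {bad_channel!r}")
    bi = labels.index(bad_channel)
    good = [
        i
        for i, lab in enumerate(labels)
        if i != bi and lab not in epochs.bad_channels
    ]
    if len(good) < 3:
        raise ValueError("need at least 3 good channels to interpolate")
    d = np.linalg.norm(epochs.grid_xy[good] - epochs.grid_xy[bi], axis=1)
    w = 1.0 / d**2
    w /= w.sum()
    data = epochs.data.copy()
    data[:, bi, :] = np.einsum("g,tgs->ts", w, data[:, good, :])
    meta = dict(epochs.meta)
    meta.setdefault("interpolated_channels", []).append(bad_channel)
    bad = tuple(c for c in epochs.bad_channels if c != bad_channel)
    return epochs.copy_with(data=data, meta=meta, bad_channels=bad)


# ---------------------------------------------------------------------------
# Feature-table imputation
# ---------------------------------------------------------------------------

def impute_features(
    table: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 10,
    tol: float = 1e-3,
    n_estimators: int = 30,
) -> pd.DataFrame:
    """Iterative round-robin imputation with an ensemble-of-trees regressor.

    Missing cells start at the column median; each incomplete column is then
    repeatedly regressed on all others until the relative change of the
    imputed values drops below ``tol`` or ``max_iter`` rounds have run.
    Deterministic for a fixed seed.  Non-numeric columns are passed through
    untouched.
    """
    from sklearn.ensemble import ExtraTreesRegressor
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    num = table.select_dtypes(include=[np.number])
    rest = table.drop(columns=num.columns)
    if num.isna().all(axis=0).any():
        bad = num.columns[num.isna().all(axis=0)].tolist()
        raise ValueError(f"columns entirely missing, cannot impute: {bad}")
    if (num.notna().sum(axis=0) < 2).any():
        bad = num.columns[num.notna().sum(axis=0) < 2].tolist()
        raise ValueError(f"columns with fewer than 2 observed values: {bad}")
    if not num.isna().any().any():
        return table.copy()
    imputer = IterativeImputer(
        estimator=ExtraTreesRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ),
        max_iter=max_iter,
        tol=tol,
        initial_strategy="median",
        random_state=seed,
        sample_posterior=False,
    )
    filled = pd.DataFrame(
        imputer.fit_transform(num), columns=num.columns, index=num.index
    )
    out = pd.concat([rest, filled], axis=1)
    return out[table.columns]
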