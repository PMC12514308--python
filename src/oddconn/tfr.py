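"""Event-related spectral perturbation (ERSP) maps and per-band maxima.

Power is computed with a sliding Hann-tapered FFT (400-sample window at
3 kHz, zero-padded by the configured pad ratio), averaged over trials, and
expressed in dB relative to the mean pre-stimulus baseline power of the
same condition:  ERSP(f, t) = 10 log10( P(f, t) / P_baseline(f) ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "ErspMap",
    "BANDS",
    "compute_ersp",
    "ersp_contrast",
    "band_features",
]

BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
    "low_beta": (12.0, 15.0),
    "mid_beta": (15.0, 18.0),
    "high_beta": (18.0, 30.0),
    "whole": (1.0, 45.0),
}


@dataclass
class ErspMap:
    values: np.ndarray  # (channels, freqs, times), dB
    freqs: np.ndarray  # Hz
    times: np.ndarray  # ms (window centres)
    channel_labels: tuple[str, ...]
    params: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _sliding_power(
    data: np.ndarray,
    times: np.ndarray,
    fs: float,
    window_samples: int,
    pad_ratio: int,
    n_times: int,
    fmin: float,
    fmax: float,
):
    """Trial-averaged sliding-window power.

    ``data`` is (trials, channels, samples); returns (power (ch, f, t),
    freqs, centre times ms).
    """
    n_samp = data.shape[2]
    if window_samples > n_samp:
        raise ValueError("epoch shorter than the analysis window")
    if pad_ratio < 1 or (pad_ratio & (pad_ratio - 1)):
        raise ValueError("pad_ratio must be a power of two")
    nfft = window_samples * pad_ratio
    taper = np.hanning(window_samples)
    norm = (taper**2).sum() * fs  # density normalisation (power per Hz)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    fsel = (freqs >= fmin) & (freqs <= fmax)

    half = window_samples // 2
    centres = np.unique(
        np.linspace(half, n_samp - (window_samples - half), n_times).astype(int)
    )
    power = np.zeros((data.shape[1], int(fsel.sum()), centres.size))
    for ti, c in enumerate(centres):
        seg = data[:, :, c - half : c - half + window_samples] * taper
        spec = np.fft.rfft(seg, n=nfft, axis=2)
        p = (spec.real**2 + spec.imag**2) / norm
        power[:, :, ti] = p[:, :, fsel].mean(axis=0)
    return power, freqs[fsel], times[centres]


def compute_ersp(
    epochs: EpochSet,
    window_samples: int = 400,
    pad_ratio: int = 64,
    n_times: int = 200,
    fmin: float = 1.0,
    fmax: float = 45.0,
    condition: str | None = None,
    baseline_floor: float = 1e-20,
) -> ErspMap:
    """ERSP for one condition (or all kept trials when ``condition`` is
    None), baseline-normalised in dB against the mean power of windows
    centred before stimulus onset.

    The baseline is floored at the absolute power ``baseline_floor``
    (microvolts^2/Hz) so that numerically silent frequencies — possible in
    noise-free synthetic signals — cannot blow up the dB ratio; any
    physiological baseline sits many orders of magnitude above it."""
    sel = epochs.kept.copy()
    if condition is not None:
        sel &= epochs.condition == condition
    if not sel.any():
        raise ValueError(f"no kept trials for condition {condition!r}")
    power, freqs, ctimes = _sliding_power(
        epochs.data[sel], epochs.times, epochs.fs,
        window_samples, pad_ratio, n_times, fmin, fmax,
    )
    base_sel = ctimes < 0
    if not base_sel.any():
        base_sel = np.zeros_like(ctimes, dtype=bool)
        base_sel[0] = True  # fall back to the earliest window
    baseline = power[:, :, base_sel].mean(axis=2, keepdims=True)
    baseline = np.maximum(baseline, baseline_floor)
    values = 10.0 * np.log10(np.maximum(power, baseline_floor) / baseline)
    return ErspMap(
        values=values,
        freqs=freqs,
        times=ctimes,
        channel_labels=epochs.channel_labels,
        params={
            "window_samples": window_samples,
            "pad_ratio": pad_ratio,
            "taper": "hann",
            "n_times": n_times,
        },
        meta={
            **{k: epochs.meta.get(k) for k in ("subject", "group", "treatment")},
            "condition": condition,
            "n_trials": int(sel.sum()),
        },
    )


def ersp_contrast(epochs: EpochSet, **kw) -> dict[str, ErspMap]:
    """Standard and deviant ERSP maps plus their deviant-minus-standard
    contrast."""
    std = compute_ersp(epochs, condition="standard", **kw)
    dev = compute_ersp(epochs, condition="deviant", **kw)
    contrast = ErspMap(
        values=dev.values - std.values,
        freqs=dev.freqs.copy(),
        times=dev.times.copy(),
        channel_labels=dev.channel_labels,
        params=dict(dev.params),
        meta={**dev.meta, "condition": "deviant-standard"},
    )
    return {"standard": std, "deviant": dev, "contrast": contrast}


def band_features(
    ersp: ErspMap,
    bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Maximum post-stimulus ERSP per channel and band, with its latency and
    frequency.  Ties break to the earliest time, then the lowest frequency.
    """
    bands = bands if bands is not None else BANDS
    tsel = ersp.times >= 0
    rows = []
    for band, (lo, hi) in bands.items():
        fsel = (ersp.freqs >= lo) & (ersp.freqs <= hi)
        if not fsel.any():
            raise ValueError(f"band {band} ({lo}-{hi} Hz) empty on this map")
        sub = ersp.values[:, fsel][:, :, tsel]  # (ch, f, t)
        fgrid = ersp.freqs[fsel]
        tgrid = ersp.times[tsel]
        for ci, lab in enumerate(ersp.channel_labels):
            # time-major flat index => earliest time wins, then lowest freq
            flat = sub[ci].T.reshape(-1)  # (t, f) flattened
            k = int(flat.argmax())
            ti, fi = divmod(k, fgrid.size)
            rows.append((band, lab, flat[k], tgrid[ti], fgrid[fi]))
    return pd.DataFrame(
        rows, columns=["band", "channel", "max_db", "latency", "frequency"]
    )
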