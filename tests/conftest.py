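import numpy as np
import pytest

from oddconn.preprocess import EpochSet
from oddconn.synth import CHANNEL_LABELS, GRID_XY


def make_epochs(
    data: np.ndarray,
    fs: float = 600.0,
    condition=None,
    t0_ms: float = -100.0,
    labels=None,
) -> EpochSet:
    """Wrap a (trials, channels, time) array as an EpochSet."""
    n_trials, n_ch, n_samp = data.shape
    if labels is None:
        labels = CHANNEL_LABELS[:n_ch]
    if condition is None:
        condition = np.array(
            ["deviant" if i % 7 == 0 else "standard" for i in range(n_trials)]
        )
    times = t0_ms + np.arange(n_samp) / fs * 1000.0
    return EpochSet(
        data=np.asarray(data, dtype=float),
        times=times,
        condition=np.asarray(condition),
        kept=np.ones(n_trials, dtype=bool),
        fs=fs,
        channel_labels=tuple(labels),
        grid_xy=GRID_XY[:n_ch].copy(),
        meta={"subject": "test", "group": "control", "treatment": "pre"},
    )


@pytest.fixture
def planted_epochs():
    """40 trials x 3 channels at 600 Hz: deviants carry a 50 ms Gaussian
    bump of 10 microvolts on top of the standard response."""
    fs = 600.0
    n_samp = int(0.8 * fs)
    t = -100.0 + np.arange(n_samp) / fs * 1000.0
    bump = 10.0 * np.exp(-0.5 * ((t - 50.0) / 10.0) ** 2)
    data = np.zeros((40, 3, n_samp))
    condition = np.array(["deviant" if i % 4 == 0 else "standard" for i in range(40)])
    data[condition == "deviant"] += bump
    return make_epochs(data, fs=fs, condition=condition)
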