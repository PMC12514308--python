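"""Synthetic data generators for the oddball-ECoG pipeline.

Everything the downstream stages consume can be produced here with known
ground truth: multichannel recordings from a two-tone auditory oddball
session over a 3x3 epidural grid, time series from a non-linear
multivariate autoregressive (nMVAR) model with planted directed couplings,
and daily drinking tables from an alcohol-deprivation-effect (ADE)
paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NonlinearTerm",
    "NmvarSpec",
    "Recording",
    "CHANNEL_LABELS",
    "GRID_XY",
    "PRESETS",
    "simulate_nmvar",
    "make_stimulus_sequence",
    "simulate_session",
    "simulate_drinking",
    "default_drinking_schedule",
]

# 3x3 epidural grid over medial PFC.  Columns: frontal (F), medial (M),
# posterior (P) rows x left/central/right.  Electrode spacing 1.5 mm
# mediolateral, 2.0 mm rostrocaudal; FC is the stimulation site.
CHANNEL_LABELS = ("FC", "FL", "FR", "MC", "ML", "MR", "PC", "PL", "PR")

_COL_X = {"L": -1.5, "C": 0.0, "R": 1.5}
_ROW_Y = {"F": 2.0, "M": 0.0, "P": -2.0}
GRID_XY = np.array([[_COL_X[lab[1]], _ROW_Y[lab[0]]] for lab in CHANNEL_LABELS])


# ---------------------------------------------------------------------------
# nMVAR ground-truth generator
# ---------------------------------------------------------------------------

_FUNCTION_TAGS = ("square", "scaled_tanh", "cross_product")


@dataclass(frozen=True)
class NonlinearTerm:
    """One non-linear coupling: ``target(n) += weight * g(source(n - lag))``.

    ``kind`` selects g: ``square`` -> x^2, ``scaled_tanh`` -> tanh(x),
    ``cross_product`` -> x(n-lag) * x(n-lag-1) of the source channel
    (requires lag + 1 <= p).
    """

    source: int
    lag: int
    target: int
    weight: float
    kind: str = "square"


@dataclass
class NmvarSpec:
    """Specification of a non-linear MVAR process.

    x(n) = sum_k A[:, :, k] x(n-k) + (non-linear terms) + noise, with
    A[target, source, lag] the linear coefficient tensor.
    """

    M: int
    p: int
    A: np.ndarray
    nonlinear_terms: list[NonlinearTerm] = field(default_factory=list)
    noise_sd: float | np.ndarray = 1.0

    def companion(self) -> np.ndarray:
        """Companion matrix of the linear part (M*p x M*p)."""
        M, p = self.M, self.p
        C = np.zeros((M * p, M * p))
        C[:M, :] = np.concatenate(
            [self.A[:, :, k] for k in range(p)], axis=1
        )  # [A1 A2 ... Ap]
        if p > 1:
            C[M:, :-M] = np.eye(M * (p - 1))
        return C

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def validate(self) -> None:
        if self.p < 1:
            raise ValueError("model order p must be >= 1")
        if self.A.shape != (self.M, self.M, self.p):
            raise ValueError(
                f"A must have shape (M, M, p) = {(self.M, self.M, self.p)}, "
                f"got {self.A.shape}"
            )
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"linear part unstable: companion spectral radius {rho:.4f} >= 1"
            )
        for t in self.nonlinear_terms:
            if t.kind not in _FUNCTION_TAGS:
                raise ValueError(
                    f"unknown non-linear function tag {t.kind!r}; "
                    f"allowed: {_FUNCTION_TAGS}"
                )
            max_lag = t.lag + 1 if t.kind == "cross_product" else t.lag
            if not (1 <= max_lag <= self.p):
                raise ValueError(f"term {t} uses lags beyond the model order")
            if not (0 <= t.source < self.M and 0 <= t.target < self.M):
                raise ValueError(f"term {t} has out-of-range channels")


def simulate_nmvar(spec: NmvarSpec, n_samples: int, seed: int) -> np.ndarray:
    """Forward-simulate an nMVAR process.

    Returns a (M, n_samples) array.  The first ``p`` samples are pure
    innovation noise.
    """
    spec.validate()
    if n_samples <= 10 * spec.p:
        raise ValueError("n_samples must exceed 10 * p")
    rng = np.random.default_rng(seed)
    M, p = spec.M, spec.p
    sd = np.broadcast_to(np.asarray(spec.noise_sd, float), (M,))
    x = np.zeros((M, n_samples))
    noise = rng.standard_normal((M, n_samples)) * sd[:, None]
    x[:, :p] = noise[:, :p]
    for n in range(p, n_samples):
        acc = noise[:, n].copy()
        for k in range(p):
            acc += spec.A[:, :, k] @ x[:, n - k - 1]
        for t in spec.nonlinear_terms:
            u = x[t.source, n - t.lag]
            if t.kind == "square":
                g = u * u
            elif t.kind == "scaled_tanh":
                g = np.tanh(u)
            else:  # cross_product
                g = u * x[t.source, n - t.lag - 1]
            acc[t.target] += t.weight * g
        x[:, n] = acc
    return x


# ---------------------------------------------------------------------------
# Oddball stimulus sequence
# ---------------------------------------------------------------------------

def make_stimulus_sequence(
    n_blocks: int = 6,
    block_duration: float = 300.0,
    isi: float = 1.0,
    tone_duration: float = 0.05,
    deviant_fraction: float = 0.13,
    seed: int = 0,
    standard_freq: float = 1000.0,
    deviant_freq: float = 2000.0,
    standard_level: float = 70.0,
    deviant_level: float = 80.0,
) -> pd.DataFrame:
    """Two-tone oddball sequence: frequent standards, rare deviants.

    Stimulus-onset asynchrony is ``isi + tone_duration`` (the inter-stimulus
    interval is read offset-to-onset).  The deviant count is
    ``round(deviant_fraction * total)`` and deviants are placed uniformly at
    random among all placements with no two deviants adjacent, so every
    deviant is preceded and followed by at least one standard.
    """
    if not (0.0 < deviant_fraction < 0.5):
        raise ValueError("deviant_fraction must be in (0, 0.5)")
    soa = isi + tone_duration
    per_block = int(np.floor(block_duration / soa))
    total = n_blocks * per_block
    n_dev = int(round(deviant_fraction * total))
    if n_dev > (total + 1) // 2:
        raise ValueError("deviant fraction too high for non-adjacent placement")
    rng = np.random.default_rng(seed)
    # Uniform sample of a size-n_dev subset with pairwise gaps >= 2:
    # choose from total - n_dev + 1 slots, then spread.
    slots = rng.choice(total - n_dev + 1, size=n_dev, replace=False)
    dev_pos = np.sort(slots) + np.arange(n_dev)
    is_dev = np.zeros(total, dtype=bool)
    is_dev[dev_pos] = True

    idx = np.arange(total)
    block = idx // per_block
    within = idx % per_block
    onset = block * block_duration + within * soa
    return pd.DataFrame(
        {
            "onset": onset,
            "tone_type": np.where(is_dev, "deviant", "standard"),
            "tone_freq": np.where(is_dev, deviant_freq, standard_freq),
            "level": np.where(is_dev, deviant_level, standard_level),
            "duration": tone_duration,
            "block": block,
        }
    )


# ---------------------------------------------------------------------------
# Session simulator
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A continuous multichannel ECoG recording plus its event table."""

    signal: np.ndarray  # (channels, samples), microvolts
    fs: float
    channel_labels: tuple[str, ...]
    grid_xy: np.ndarray  # (channels, 2), mm
    events: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


# Evoked component templates: (name, latency ms, width ms, deviant amplitude
# microvolts, signed).  Standards get the same morphology scaled down
# (habituation to the frequent tone).
_BASE_COMPONENTS = {
    "P1": (50.0, 14.0, 6.0),
    "N1": (100.0, 22.0, -8.0),
    "P2": (170.0, 35.0, 5.0),
    "N2": (250.0, 45.0, -4.0),
    "P3": (380.0, 80.0, 3.0),
}

# Oscillatory burst templates: band -> (center freq Hz, burst center ms,
# burst sd ms, deviant amplitude microvolts).
_BASE_BURSTS = {
    "delta": (2.5, 250.0, 120.0, 3.0),
    "theta": (6.0, 180.0, 90.0, 2.5),
    "alpha": (10.0, 150.0, 70.0, 2.0),
    "beta": (14.0, 120.0, 60.0, 1.8),
    "gamma": (38.0, 90.0, 40.0, 1.0),
}


def _preset_params(preset: str) -> dict:
    """Component/burst scalings implementing the group x treatment effect
    directions: alcohol shrinks P1N1 and N1P2, grows P2N2, damps delta-beta
    power while boosting gamma and shifting the beta peak up; stimulation
    (post) enhances amplitudes and powers, evenly across channels in
    controls but concentrated at the FC stimulation site (and weaker
    overall) in the alcohol group.
    """
    comp = {k: 1.0 for k in _BASE_COMPONENTS}
    burst = {k: 1.0 for k in _BASE_BURSTS}
    beta_freq = _BASE_BURSTS["beta"][0]
    channel_gain = np.ones(len(CHANNEL_LABELS))
    if preset.startswith("alcohol"):
        comp.update(P1=0.65, N1=0.6, P2=0.85, N2=1.5, P3=0.9)
        for b in ("delta", "theta", "alpha", "beta"):
            burst[b] = 0.65
        burst["gamma"] = 1.8
        beta_freq = 20.0  # beta maximum shifted toward high-beta
    if preset.endswith("post"):
        if preset == "control_post":
            gain = 1.5
        else:
            gain = 1.25  # weaker stimulation response after chronic alcohol
            fc = CHANNEL_LABELS.index("FC")
            channel_gain[:] = 1.0
            channel_gain[fc] = 1.5  # enhancement concentrated at the
            # stimulation electrode
        comp = {k: v * gain for k, v in comp.items()}
        burst = {k: v * gain for k, v in burst.items()}
    return {
        "component_scale": comp,
        "burst_scale": burst,
        "beta_freq": beta_freq,
        "channel_gain": channel_gain,
    }


PRESETS = ("control_pre", "control_post", "alcohol_pre", "alcohol_post")


def _one_over_f_noise(rng, n_ch, n, fs, chi=1.0, rms=15.0):
    """Background with a 1/f^chi amplitude spectrum, scaled to the target
    RMS in microvolts."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-chi / 2.0)
    spec = (
        rng.standard_normal((n_ch, freqs.size))
        + 1j * rng.standard_normal((n_ch, freqs.size))
    ) * shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    x *= rms / np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x


def simulate_session(
    events: pd.DataFrame,
    preset: str,
    fs: float = 600.0,
    seed: int = 0,
    noise_scale: float = 1.0,
    artifact_trials: tuple[int, ...] = (),
    components: dict | None = None,
    bursts: dict | None = None,
    standard_scale: float = 0.35,
    subject: str = "sub-00",
    padding: float = 1.0,
) -> Recording:
    """Simulate one oddball session for a given group/treatment preset.

    The signal is 1/f background noise plus, at every tone onset, a sum of
    Gaussian-windowed evoked components (P1..P3) and Gaussian-enveloped
    band-limited oscillatory bursts.  Deviant responses are full scale,
    standard responses are ``standard_scale`` of it.  ``artifact_trials``
    lists event indices that receive a >500 microvolt transient.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {PRESETS}")
    if fs < 200:
        raise ValueError("fs must be at least 200 Hz")
    params = _preset_params(preset)
    comp_defs = components if components is not None else _BASE_COMPONENTS
    burst_defs = bursts if bursts is not None else _BASE_BURSTS

    rng = np.random.default_rng(seed)
    n_ch = len(CHANNEL_LABELS)
    # Lead-in pad so the pre-stimulus window of the first trial is in range.
    events = events.copy()
    events["onset"] = events["onset"] + padding
    n = int(np.ceil((float(events["onset"].max()) + 2 * padding) * fs))
    if noise_scale > 0:
        signal = _one_over_f_noise(rng, n_ch, n, fs, rms=15.0 * noise_scale)
        signal += rng.standard_normal((n_ch, n)) * 2.0 * noise_scale
    else:
        signal = np.zeros((n_ch, n))

    # Single-trial evoked template on a [0, 700] ms grid, per channel.
    tmpl_n = int(round(0.7 * fs))
    tt = np.arange(tmpl_n) / fs * 1000.0  # ms
    evoked = np.zeros(tmpl_n)
    for name, (lat, width, amp) in comp_defs.items():
        scale = params["component_scale"].get(name, 1.0)
        evoked += amp * scale * np.exp(-0.5 * ((tt - lat) / width) ** 2)
    burst_wave = np.zeros(tmpl_n)
    for name, (f0, center, sd_ms, amp) in burst_defs.items():
        scale = params["burst_scale"].get(name, 1.0)
        if name == "beta":
            f0 = params["beta_freq"]
        env = np.exp(-0.5 * ((tt - center) / sd_ms) ** 2)
        burst_wave += amp * scale * env * np.sin(2 * np.pi * f0 * tt / 1000.0)
    template = evoked + burst_wave

    onsets = events["onset"].to_numpy()
    is_dev = (events["tone_type"] == "deviant").to_numpy()
    gains = params["channel_gain"]
    for i, onset in enumerate(onsets):
        start = int(round(onset * fs))
        if start + tmpl_n > n:
            continue
        amp = 1.0 if is_dev[i] else standard_scale
        # trial-to-trial variability of the evoked response
        jitter = 1.0 + 0.1 * rng.standard_normal() * (noise_scale > 0)
        add = template * (amp * jitter)
        signal[:, start : start + tmpl_n] += add[None, :] * gains[:, None]

    for i in artifact_trials:
        start = int(round(onsets[i] * fs))
        width = int(round(0.05 * fs))
        stop = min(start + width, n)
        ch = int(rng.integers(n_ch))
        signal[ch, start:stop] += 700.0 * np.hanning(stop - start)

    return Recording(
        signal=signal,
        fs=float(fs),
        channel_labels=CHANNEL_LABELS,
        grid_xy=GRID_XY.copy(),
        events=events.reset_index(drop=True),
        meta={
            "subject": subject,
            "group": preset.split("_")[0],
            "treatment": preset.split("_")[1],
            "preset": preset,
            "seed": int(seed),
            "artifact_trials": tuple(int(i) for i in artifact_trials),
        },
    )


# ---------------------------------------------------------------------------
# ADE drinking tables
# ---------------------------------------------------------------------------

CONCENTRATIONS = (5, 10, 20)

# Cohort-mean daily intake of pure ethanol (g/kg/day) per solution during
# baseline and on the first post-deprivation (ADE) day.
DEFAULT_BL_MEANS = {5: 1.02, 10: 1.25, 20: 1.16}
DEFAULT_ADE_MEANS = {5: 1.58, 10: 1.49, 20: 1.59}


def default_drinking_schedule(n_cycles: int = 4) -> list[tuple[str, int]]:
    """Alternating free-access / deprivation phases.  The first drinking
    phase is long (8 weeks of continuous access); later drinking phases run
    4-6 weeks with 2-3 week deprivations, varied deterministically."""
    sched: list[tuple[str, int]] = [("drinking_0", 56)]
    drink_len = (28, 35, 42, 28, 35)
    depr_len = (14, 21, 14, 21, 14)
    for c in range(n_cycles):
        sched.append((f"deprivation_{c}", depr_len[c % 5]))
        sched.append((f"drinking_{c + 1}", drink_len[c % 5]))
    return sched


def simulate_drinking(
    n_rats: int = 10,
    schedule: list[tuple[str, int]] | None = None,
    bl_means: dict[int, float] | None = None,
    ade_means: dict[int, float] | None = None,
    seed: int = 0,
    rat_sd: float = 0.3,
    day_sd: float = 0.15,
) -> pd.DataFrame:
    """Daily per-rat intake table for the ADE paradigm.

    Ordinary drinking days are drawn around the per-concentration baseline
    means with a rat-level random effect; the first day after each
    deprivation is drawn around the (higher) ADE means; deprivation days
    are zero for all concentrations.
    """
    schedule = schedule if schedule is not None else default_drinking_schedule()
    bl = bl_means if bl_means is not None else dict(DEFAULT_BL_MEANS)
    ade = ade_means if ade_means is not None else dict(DEFAULT_ADE_MEANS)
    if any(v <= 0 for v in bl.values()):
        raise ValueError("baseline means must be positive")
    labels = [lab for lab, _ in schedule]
    kinds = [lab.rsplit("_", 1)[0] for lab in labels]
    if any(a == b for a, b in zip(kinds, kinds[1:])):
        raise ValueError("schedule must alternate drinking and deprivation phases")

    rng = np.random.default_rng(seed)
    rows = []
    for rat in range(n_rats):
        rat_eff = {c: rng.normal(0.0, rat_sd) for c in CONCENTRATIONS}
        day = 0
        prev_was_depr = False
        for lab, n_days in schedule:
            kind = lab.rsplit("_", 1)[0]
            for d in range(n_days):
                for c in CONCENTRATIONS:
                    if kind == "deprivation":
                        intake = 0.0
                    else:
                        mean = ade[c] if (prev_was_depr and d == 0) else bl[c]
                        intake = max(0.0, mean + rat_eff[c] + rng.normal(0, day_sd))
                    rows.append((f"rat{rat:02d}", day, lab, c, intake))
                day += 1
            prev_was_depr = kind == "deprivation"
    return pd.DataFrame(
        rows, columns=["rat", "day", "phase", "concentration", "intake"]
    )
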