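"""Non-linear directed connectivity via an nMVAR model fitted by a
single-hidden-layer perceptron (the nCREANN approach).

The network predicts x(n) from the M*p lagged samples
x_p = [x_1(n-1) ... x_M(n-p)].  The learned map f is split into a linear
part — its average Jacobian over the training inputs, i.e. the network's
best linear approximation on the standardized input distribution — and a
non-linear remainder.  Directed linear connectivity lC(i->j) sums the
average-Jacobian magnitudes from source i (all lags) to target j;
non-linear connectivity NC(i->j) is the mean absolute input-dependence of
the Jacobian on those entries, relative to the target's mean linear
sensitivity.  Significance comes from a randomisation test with
time-shifted surrogates, which preserve each channel's dynamics while
destroying cross-channel causal alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .preprocess import EpochSet, interpolate_channel

__all__ = [
    "ContrastSet",
    "TrainingData",
    "NetConfig",
    "TrainedNet",
    "OrderSelection",
    "ConnectivityResult",
    "SubjectExcluded",
    "contrast_trials",
    "build_training_data",
    "select_model_order",
    "train_network",
    "extract_connectivity",
    "surrogate_test",
    "estimate_connectivity",
]


class SubjectExcluded(RuntimeError):
    """Raised when a subject fails the minimum-electrode selection rule."""


# ---------------------------------------------------------------------------
# Contrast signals
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    """Single-trial contrast signals: each kept deviant trial minus the mean
    of the kept standard trials."""

    data: np.ndarray  # (trials, channels, time)
    times: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def copy_with(self, **kw) -> "ContrastSet":
        return replace(self, **kw)


def contrast_trials(epochs: EpochSet) -> ContrastSet:
    std_sel = epochs.kept & (epochs.condition == "standard")
    dev_sel = epochs.kept & (epochs.condition == "deviant")
    if not dev_sel.any():
        raise ValueError("no kept deviant trials")
    if not std_sel.any():
        raise ValueError("no kept standard trials")
    std_mean = epochs.data[std_sel].mean(axis=0)
    return ContrastSet(
        data=epochs.data[dev_sel] - std_mean,
        times=epochs.times.copy(),
        fs=epochs.fs,
        channel_labels=epochs.channel_labels,
        meta=dict(epochs.meta),
    )


# ---------------------------------------------------------------------------
# Training data
# ---------------------------------------------------------------------------

@dataclass
class TrainingData:
    X: np.ndarray  # (N, M*p) lagged standardized inputs
    Y: np.ndarray  # (N, M) standardized targets
    seg_ids: np.ndarray  # original trial of each row
    folds: np.ndarray  # (n_reps, N) int8: 0 train / 1 val / 2 test
    mean: np.ndarray
    sd: np.ndarray
    M: int
    p: int
    channel_labels: tuple[str, ...] = ()


def _lagged_rows(series: np.ndarray, p: int):
    """Boundary-respecting lagged design rows from (trials, M, T) data.

    Input column ordering is lag-major blocks of channels:
    column(i, k) = (k - 1) * M + i for source i at lag k, matching
    x_p = [x_1(n-1), ..., x_M(n-1), x_1(n-2), ..., x_M(n-p)].
    """
    n_trials, M, T = series.shape
    if p >= T:
        raise ValueError(f"model order p={p} >= trial length {T}")
    rows_per_trial = T - p
    n_rows = n_trials * rows_per_trial
    X = np.empty((n_rows, M * p))
    # targets x(n) for n = p..T-1, trials stacked
    Y = series[:, :, p:].transpose(0, 2, 1).reshape(n_rows, M)
    for k in range(p):
        lagged = series[:, :, p - k - 1 : T - k - 1]  # x(n - k - 1)
        X[:, k * M : (k + 1) * M] = lagged.transpose(0, 2, 1).reshape(n_rows, M)
    seg = np.repeat(np.arange(n_trials), rows_per_trial)
    return X, Y, seg


def build_training_data(
    contrast: ContrastSet, p: int, seed: int, n_reps: int = 10
) -> TrainingData:
    """Standardize channels over the concatenated trials and build lagged
    rows that never span a trial boundary, plus ``n_reps`` independent
    random 80/10/10 train/validation/test splits."""
    data = np.asarray(contrast.data, dtype=float)
    mean = data.mean(axis=(0, 2))
    sd = data.std(axis=(0, 2))
    sd = np.where(sd > 0, sd, 1.0)
    z = (data - mean[None, :, None]) / sd[None, :, None]
    X, Y, seg = _lagged_rows(z, p)

    n = X.shape[0]
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    rng = np.random.default_rng(seed)
    folds = np.empty((n_reps, n), dtype=np.int8)
    for r in range(n_reps):
        perm = rng.permutation(n)
        f = np.empty(n, dtype=np.int8)
        f[perm[:n_train]] = 0
        f[perm[n_train : n_train + n_val]] = 1
        f[perm[n_train + n_val :]] = 2
        folds[r] = f
    return TrainingData(
        X=X, Y=Y, seg_ids=seg, folds=folds, mean=mean, sd=sd,
        M=data.shape[1], p=p, channel_labels=contrast.channel_labels,
    )


# ---------------------------------------------------------------------------
# Model-order selection (linear MVAR, least squares)
# ---------------------------------------------------------------------------

@dataclass
class OrderSelection:
    orders: np.ndarray
    aic: np.ndarray
    bic: np.ndarray
    chosen: int
    criterion: str


def select_model_order(
    contrast: ContrastSet, p_max: int, criterion: str = "bic"
) -> OrderSelection:
    """Fit linear MVAR models of order 1..p_max by least squares and score
    them with AIC / BIC on the residual covariance determinant."""
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    data = np.asarray(contrast.data, dtype=float)
    M = data.shape[1]
    aic, bic = [], []
    for p in range(1, p_max + 1):
        X, Y, _ = _lagged_rows(data, p)
        n = X.shape[0]
        coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        if rank < X.shape[1]:
            raise ValueError(
                f"singular design at order {p}; try a lower p_max or more data"
            )
        resid = Y - X @ coef
        sigma = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = -np.inf
        k = p * M * M
        aic.append(logdet + 2.0 * k / n)
        bic.append(logdet + np.log(n) * k / n)
    orders = np.arange(1, p_max + 1)
    scores = np.array(bic if criterion == "bic" else aic)
    return OrderSelection(
        orders=orders,
        aic=np.array(aic),
        bic=np.array(bic),
        chosen=int(orders[int(np.argmin(scores))]),
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# MLP training: incremental backprop, momentum, adaptive learning rate
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    hidden: int = 10
    momentum: float = 0.9
    eta0: float = 0.001  # per-sample updates: larger rates stall in a noise ball
    max_epochs: int = 200
    patience: int = 6
    lr_up: float = 1.05
    lr_down: float = 0.7
    err_increase: float = 1.04
    n_reps: int = 10


@dataclass
class RepResult:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    mse_train: float
    mse_val: float
    mse_test: float
    r2_train: float
    r2_test: float
    n_epochs: int
    train_trace: np.ndarray
    val_trace: np.ndarray
    eta_trace: np.ndarray


@dataclass
class TrainedNet:
    reps: list[RepResult]
    best_rep: int  # repetition with median test MSE
    M: int
    p: int
    config: NetConfig

    @property
    def best(self) -> RepResult:
        return self.reps[self.best_rep]


@njit(cache=True)
def _sgd_epochs(
    X, Y, train_idx, val_idx,
    W1, b1, W2, b2,
    momentum, eta0, lr_up, lr_down, err_inc,
    max_epochs, patience, seed,
):
    n_in = X.shape[1]
    n_out = Y.shape[1]
    hid = b1.shape[0]

    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)

    bW1 = W1.copy(); bb1 = b1.copy(); bW2 = W2.copy(); bb2 = b2.copy()
    best_val = np.inf
    prev_mse = np.inf
    eta = eta0
    wait = 0
    diverged_at = -1

    train_trace = np.full(max_epochs, np.nan)
    val_trace = np.full(max_epochs, np.nan)
    eta_trace = np.full(max_epochs, np.nan)
    n_epochs = 0

    for epoch in range(max_epochs):
        sW1 = W1.copy(); sb1 = b1.copy(); sW2 = W2.copy(); sb2 = b2.copy()
        svW1 = vW1.copy(); svb1 = vb1.copy()
        svW2 = vW2.copy(); svb2 = vb2.copy()

        np.random.seed(seed + epoch)
        order = np.random.permutation(train_idx.shape[0])
        sse = 0.0
        for oi in range(order.shape[0]):
            r = train_idx[order[oi]]
            x = X[r]
            h = np.tanh(W1 @ x + b1)
            yhat = W2 @ h + b2
            e = yhat - Y[r]
            for j in range(n_out):
                sse += e[j] * e[j]
            # backprop
            dh = (W2.T @ e) * (1.0 - h * h)
            for j in range(n_out):
                for m in range(hid):
                    vW2[j, m] = momentum * vW2[j, m] - eta * e[j] * h[m]
                    W2[j, m] += vW2[j, m]
                vb2[j] = momentum * vb2[j] - eta * e[j]
                b2[j] += vb2[j]
            for m in range(hid):
                for i in range(n_in):
                    vW1[m, i] = momentum * vW1[m, i] - eta * dh[m] * x[i]
                    W1[m, i] += vW1[m, i]
                vb1[m] = momentum * vb1[m] - eta * dh[m]
                b1[m] += vb1[m]
        mse = sse / (order.shape[0] * n_out)
        n_epochs = epoch + 1
        train_trace[epoch] = mse
        eta_trace[epoch] = eta
        if not np.isfinite(mse):
            diverged_at = epoch
            break
        if mse > prev_mse * err_inc:
            # reject the epoch: roll the weights back, damp the rate
            W1[:] = sW1; b1[:] = sb1; W2[:] = sW2; b2[:] = sb2
            vW1[:] = svW1; vb1[:] = svb1; vW2[:] = svW2; vb2[:] = svb2
            eta *= lr_down
            wait += 1
        else:
            if mse < prev_mse:
                eta *= lr_up
            prev_mse = mse
            # validation MSE
            vsse = 0.0
            for vi in range(val_idx.shape[0]):
                r = val_idx[vi]
                h = np.tanh(W1 @ X[r] + b1)
                yhat = W2 @ h + b2
                for j in range(n_out):
                    d = yhat[j] - Y[r, j]
                    vsse += d * d
            vmse = vsse / max(val_idx.shape[0] * n_out, 1)
            val_trace[epoch] = vmse
            if vmse < best_val * (1.0 - 1e-6):
                best_val = vmse
                bW1[:] = W1; bb1[:] = b1; bW2[:] = W2; bb2[:] = b2
                wait = 0
            else:
                wait += 1
        if wait > patience:
            break
    return (
        bW1, bb1, bW2, bb2, best_val, diverged_at, n_epochs,
        train_trace[:n_epochs], val_trace[:n_epochs], eta_trace[:n_epochs],
    )


def _forward(X, W1, b1, W2, b2):
    H = np.tanh(X @ W1.T + b1)
    return H @ W2.T + b2


def _mse_r2(X, Y, W1, b1, W2, b2):
    pred = _forward(X, W1, b1, W2, b2)
    sse = float(((pred - Y) ** 2).sum())
    sst = float(((Y - Y.mean(axis=0)) ** 2).sum())
    mse = sse / Y.size
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return mse, r2


def train_network(
    data: TrainingData, config: NetConfig | None = None, seed: int = 0
) -> TrainedNet:
    """Train the one-hidden-layer predictor once per cross-validation
    repetition.

    Training is incremental (weights updated after every presented sample)
    gradient descent with momentum and an adaptive learning rate: the rate
    grows by ``lr_up`` after an epoch that lowers the training MSE and the
    epoch is rolled back with the rate damped by ``lr_down`` when the MSE
    rises by more than ``err_increase``.  Early stopping restores the
    best-validation weights.  The repetition with median test MSE is marked
    as the representative network.
    """
    config = config if config is not None else NetConfig()
    if data.X.shape[0] == 0:
        raise ValueError("empty training data")
    n_reps = min(config.n_reps, data.folds.shape[0])
    rng = np.random.default_rng(seed)
    reps = []
    for r in range(n_reps):
        fold = data.folds[r]
        tr = np.nonzero(fold == 0)[0]
        va = np.nonzero(fold == 1)[0]
        te = np.nonzero(fold == 2)[0]
        n_in = data.X.shape[1]
        W1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), (config.hidden, n_in))
        b1 = np.zeros(config.hidden)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(config.hidden), (data.M, config.hidden))
        b2 = np.zeros(data.M)
        kernel_seed = int((seed * 1009 + r * 9973) % (2**31 - 1))
        (
            W1, b1, W2, b2, best_val, diverged_at, n_epochs,
            train_trace, val_trace, eta_trace,
        ) = _sgd_epochs(
            data.X, data.Y, tr, va, W1, b1, W2, b2,
            config.momentum, config.eta0, config.lr_up, config.lr_down,
            config.err_increase, config.max_epochs, config.patience,
            kernel_seed,
        )
        if diverged_at >= 0:
            raise RuntimeError(
                f"training diverged (NaN loss) at epoch {diverged_at} "
                f"with learning rate {eta_trace[diverged_at]:.3g}"
            )
        mse_train, r2_train = _mse_r2(data.X[tr], data.Y[tr], W1, b1, W2, b2)
        mse_test, r2_test = _mse_r2(data.X[te], data.Y[te], W1, b1, W2, b2)
        reps.append(
            RepResult(
                W1=W1, b1=b1, W2=W2, b2=b2,
                mse_train=mse_train, mse_val=float(best_val),
                mse_test=mse_test, r2_train=r2_train, r2_test=r2_test,
                n_epochs=int(n_epochs),
                train_trace=train_trace, val_trace=val_trace,
                eta_trace=eta_trace,
            )
        )
    test_mses = np.array([r.mse_test for r in reps])
    best_rep = int(np.argsort(test_mses)[len(reps) // 2])
    return TrainedNet(reps=reps, best_rep=best_rep, M=data.M, p=data.p, config=config)


# ---------------------------------------------------------------------------
# Connectivity extraction
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityResult:
    lc: np.ndarray  # (M, M), [i, j] = lC(i -> j)
    nc: np.ndarray
    channel_labels: tuple[str, ...]
    p_lc: np.ndarray | None = None
    p_nc: np.ndarray | None = None
    sig_lc: np.ndarray | None = None
    sig_nc: np.ndarray | None = None
    surrogate: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _rep_connectivity(rep: RepResult, X: np.ndarray, M: int, p: int):
    """lC and NC matrices for one trained repetition.

    The network's input-dependent Jacobian is
    G(u) = W2 diag(1 - h(u)^2) W1 with h(u) the hidden activations.  Its
    average over the training inputs, Gbar = E[G(u)], is the network's best
    linear approximation over the input distribution (for standardized
    inputs this is the Bussgang linearization), and serves as f_lin:
    lC(i->j) sums |Gbar| entries from source i (all lags) to target j.

    The non-linear part is the input dependence of the Jacobian itself:
    NC(i->j) is the mean over inputs and lags of |G(u) - Gbar| for the
    (i, j) entries, expressed relative to target j's mean linear
    sensitivity so that NC is scale-free.  A purely linear fitted function
    has G(u) constant and NC = 0.
    """
    W1, b1, W2 = rep.W1, rep.b1, rep.W2
    H = np.tanh(X @ W1.T + b1)
    D = 1.0 - H**2  # (N, hidden) activation slopes
    d_bar = D.mean(axis=0)
    G_bar = W2 @ (d_bar[:, None] * W1)  # (M, M*p) average Jacobian
    lc = np.abs(G_bar).reshape(M, p, M).sum(axis=1).T  # (source i, target j)

    Dc = D - d_bar
    acc = np.zeros((M, M * p))
    chunk = 4096
    for s in range(0, X.shape[0], chunk):
        T = np.einsum("nh,jh,hc->njc", Dc[s : s + chunk], W2, W1, optimize=True)
        acc += np.abs(T).sum(axis=0)
    acc /= X.shape[0]
    nc_abs = acc.reshape(M, p, M).mean(axis=1).T
    row_scale = np.abs(G_bar).mean(axis=1)  # per target j
    nc = np.divide(
        nc_abs, row_scale[None, :],
        out=np.zeros_like(nc_abs), where=row_scale[None, :] > 0,
    )
    return lc, nc


def extract_connectivity(net: TrainedNet, data: TrainingData) -> ConnectivityResult:
    """Directed linear (lC) and non-linear (NC) connectivity, averaged over
    the cross-validation repetitions.  Orientation: entry [i, j] carries the
    influence of channel i on channel j; the diagonal (self-connections) is
    reported but excluded from significance testing and group statistics.
    """
    if data.X.shape[1] != net.M * net.p:
        raise ValueError("network and training data dimensions do not match")
    lcs, ncs = [], []
    for rep in net.reps:
        lc, nc = _rep_connectivity(rep, data.X, net.M, net.p)
        lcs.append(lc)
        ncs.append(nc)
    return ConnectivityResult(
        lc=np.mean(lcs, axis=0),
        nc=np.mean(ncs, axis=0),
        channel_labels=data.channel_labels,
        diagnostics={
            "mse_train": [r.mse_train for r in net.reps],
            "mse_test": [r.mse_test for r in net.reps],
            "r2_train": [r.r2_train for r in net.reps],
            "r2_test": [r.r2_test for r in net.reps],
            "n_epochs": [r.n_epochs for r in net.reps],
        },
    )


# ---------------------------------------------------------------------------
# Time-shifted surrogate significance
# ---------------------------------------------------------------------------

def _fit_once(
    series: np.ndarray,
    labels: tuple[str, ...],
    p: int,
    config: NetConfig,
    seed: int,
    n_reps: int,
):
    contrast = ContrastSet(
        data=series,
        times=np.arange(series.shape[2], dtype=float),
        fs=1.0,
        channel_labels=labels,
    )
    data = build_training_data(contrast, p=p, seed=seed, n_reps=n_reps)
    cfg = replace(config, n_reps=n_reps)
    net = train_network(data, cfg, seed=seed)
    res = extract_connectivity(net, data)
    return res, net


def surrogate_test(
    contrast: ContrastSet,
    p: int = 8,
    config: NetConfig | None = None,
    n_surrogates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    surrogate_config: NetConfig | None = None,
    surrogate_n_reps: int = 1,
) -> ConnectivityResult:
    """Full connectivity estimate plus a time-shifted-surrogate null.

    Each surrogate circularly shifts every channel's concatenated contrast
    series by an independent uniform offset in [0.1 L, 0.9 L] — leaving each
    channel's spectrum untouched while destroying cross-channel causal
    alignment — and reruns the identical build/train/extract chain.  Per
    connection, p = (1 + #{surrogate >= observed}) / (1 + n_surrogates).
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates")
    config = config if config is not None else NetConfig()
    surr_cfg = surrogate_config if surrogate_config is not None else config
    n_trials, M, T = contrast.data.shape
    L = n_trials * T

    observed, net = _fit_once(
        contrast.data, contrast.channel_labels, p, config, seed, config.n_reps
    )

    rng = np.random.default_rng(seed + 1)
    concat = np.ascontiguousarray(
        contrast.data.transpose(1, 0, 2).reshape(M, L)
    )
    lc_null = np.empty((n_surrogates, M, M))
    nc_null = np.empty((n_surrogates, M, M))
    for s in range(n_surrogates):
        shifts = rng.integers(int(0.1 * L), int(0.9 * L) + 1, size=M)
        shifted = np.empty_like(concat)
        for ch in range(M):
            shifted[ch] = np.roll(concat[ch], int(shifts[ch]))
        series = shifted.reshape(M, n_trials, T).transpose(1, 0, 2)
        res_s, _ = _fit_once(
            series, contrast.channel_labels, p, surr_cfg,
            int((seed * 131 + 7 * s + 13) % (2**31 - 1)), surrogate_n_reps,
        )
        lc_null[s] = res_s.lc
        nc_null[s] = res_s.nc

    p_lc = (1.0 + (lc_null >= observed.lc).sum(axis=0)) / (1.0 + n_surrogates)
    p_nc = (1.0 + (nc_null >= observed.nc).sum(axis=0)) / (1.0 + n_surrogates)
    off_diag = ~np.eye(M, dtype=bool)
    observed.p_lc = p_lc
    observed.p_nc = p_nc
    observed.sig_lc = (p_lc <= alpha) & off_diag
    observed.sig_nc = (p_nc <= alpha) & off_diag
    observed.surrogate = {
        "n": n_surrogates,
        "lc_mean": lc_null.mean(axis=0),
        "lc_q95": np.quantile(lc_null, 0.95, axis=0),
        "nc_mean": nc_null.mean(axis=0),
        "nc_q95": np.quantile(nc_null, 0.95, axis=0),
    }
    return observed


# ---------------------------------------------------------------------------
# Subject-level orchestrator
# ---------------------------------------------------------------------------

def estimate_connectivity(
    epochs: EpochSet,
    p: int = 8,
    config: NetConfig | None = None,
    n_surrogates: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    min_channels: int = 8,
    surrogate_config: NetConfig | None = None,
    surrogate_n_reps: int = 1,
) -> ConnectivityResult:
    """Per-subject connectivity chain with the minimum-electrode rule.

    Subjects with fewer than ``min_channels`` usable electrodes are excluded
    (SubjectExcluded); a single missing electrode out of the full grid is
    interpolated before estimation.
    """
    n_ch = len(epochs.channel_labels)
    good = [lab for lab in epochs.channel_labels if lab not in epochs.bad_channels]
    if len(good) < min_channels:
        raise SubjectExcluded(
            f"insufficient channels: {len(good)} usable of {n_ch} "
            f"(minimum {min_channels})"
        )
    for bad in epochs.bad_channels:
        epochs = interpolate_channel(epochs, bad)
    contrast = contrast_trials(epochs)
    return surrogate_test(
        contrast, p=p, config=config, n_surrogates=n_surrogates,
        seed=seed, alpha=alpha, surrogate_config=surrogate_config,
        surrogate_n_reps=surrogate_n_reps,
    )
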