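# oddconn

Event-related ECoG analysis and non-linear directed connectivity for the
alcohol-deprivation-effect (ADE) rat model.

Chronic alcohol consumption leaves measurable signatures in prefrontal
event-related activity: smaller P1N1/N1P2 deviant responses, damped
delta-beta and elevated gamma oscillatory power, and weakened directed
connectivity between cortical sites.  `oddconn` implements the full
analysis chain used to characterize those signatures and the effect of
direct cortical stimulation on them — driven entirely by a synthetic-data
module, so every stage runs, and is testable against planted ground truth,
without any recording downloads.

The pipeline:

1. **synth** — simulate two-tone oddball sessions (87% standards / 13%
   deviants, 6 x 5-min blocks, 1-s ISI) on a 3x3 epidural grid over medial
   PFC, with group/treatment presets, planted evoked components and
   oscillatory bursts; plus ground-truth non-linear MVAR time series and
   ADE drinking tables.
2. **preprocess** — 0.1-45 Hz Kaiser FIR bandpass (beta = 5.65, 54,330
   points at 3 kHz), epoching to [-100, 700) ms, baseline correction,
   500 uV delta-criterion artifact rejection, inverse-distance channel
   interpolation, missForest-style feature imputation.
3. **erp / tfr** — deviant-minus-standard difference waves; P1/N1/P2/N2/P3
   peak latencies and peak-to-peak amplitudes (P1N1, N1P2, P2N2, N2P3);
   event-related spectral perturbation (ERSP, dB) with per-band maxima.
4. **ncreann** — the core estimator.  A non-linear MVAR model of order p,

       x(n) = f(x_p) + e(n),    x_p = [x_1(n-1), ..., x_M(n-p)],

   is fitted by a one-hidden-layer perceptron (10 tanh units, incremental
   backprop with momentum and adaptive learning rate, tenfold permuted
   cross-validation, early stopping).  The learned f is split into
   f = f_lin + f_nonlin via the network's Jacobian: linear connectivity
   lC(i->j) from the average Jacobian (the best linear approximation over
   the inputs), non-linear connectivity NC(i->j) from the input-dependence
   of the Jacobian.  Significance per directed connection comes from a
   randomisation test against 100 time-shifted surrogates.
5. **stats** — mixed ANOVA (group x treatment x channel), channelwise
   paired t-tests with Benjamini-Hochberg FDR, Mann-Whitney U with
   rank-biserial effect sizes for connectivity, partial Spearman
   correlations, and BL / ADE / relapse drinking measures with their tests.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a ground-truth system in which channel 2 is driven by the square
of channel 1's previous sample, and ask the estimator which directed
connections are non-linear:

```python
import numpy as np
from oddconn.synth import NmvarSpec, NonlinearTerm, simulate_nmvar
from oddconn.ncreann import ContrastSet, NetConfig, surrogate_test

spec = NmvarSpec(
    M=2, p=1, A=np.diag([0.3, 0.0])[:, :, None],
    nonlinear_terms=[NonlinearTerm(source=0, lag=1, target=1,
                                   weight=0.8, kind="square")],
)
x = simulate_nmvar(spec, 4000, seed=3)
contrast = ContrastSet(data=x[None], times=np.arange(4000.0), fs=1.0,
                       channel_labels=("ch1", "ch2"))
res = surrogate_test(contrast, p=1, config=NetConfig(max_epochs=40, n_reps=2),
                     n_surrogates=20, seed=0,
                     surrogate_config=NetConfig(max_epochs=20, n_reps=1))
print("NC:", np.round(res.nc, 2))
print("p(NC):", np.round(res.p_nc, 3))
```

prints

```
NC: [[ 0.21 27.19]
 [ 0.05  0.84]]
p(NC): [[0.857 0.048]
 [0.857 0.238]]
```

NC is the non-linear sensitivity of each target (column) to each source
(row), relative to the target's linear sensitivity: the planted 1 -> 2
quadratic coupling stands out (27.2, p = 0.048, the smallest p attainable
with 20 surrogates) while the reverse direction is indistinguishable from
the time-shifted null.

The full pipeline — cohort simulation through group statistics — runs from
the command line:

```sh
oddconn run-all --smoke --seed 3 --out results/smoke
```

or stage by stage via the numbered scripts in `analysis/`
(`01_simulate.py` ... `05_stats.py`), which print what each stage found and
write their tables under `results/`.

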