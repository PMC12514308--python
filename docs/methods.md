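# Methods

`oddconn` re-implements, as a tested pipeline over synthetic data, an
event-related ECoG analysis of alcohol-dependent versus control rats: an
auditory-oddball session simulator, classical ERP/ERSP feature extraction,
a neural-network estimator of directed linear and non-linear connectivity
(nCREANN), and the group- and drinking-behaviour statistics of the
alcohol-deprivation-effect (ADE) model.  No animal recordings are consumed;
the synthetic generator defines the study conditions, and every downstream
claim the test suite makes is a claim about recovery of quantities that the
generator planted.

## The session simulator

A session is a passive two-tone oddball paradigm recorded from a 3x3
epidural grid over medial prefrontal cortex (electrode spacing 1.5 mm
mediolateral x 2.0 mm rostrocaudal; the frontocentral electrode FC is the
stimulation site).  Tones are presented in 6 blocks of 5 min at a
stimulus-onset asynchrony of 1.05 s (a 1 s offset-to-onset interval plus
50 ms tone duration), which yields 1,710 stimuli per session; 13% are
deviants (2 kHz, 80 dB SPL) and the rest standards (1 kHz, 70 dB SPL).
Deviant positions are an exactly-counted uniform draw over all placements
with no two deviants adjacent, implemented by the gap construction (choose
positions among `N - k + 1` slots and spread), which samples the
constrained placements uniformly rather than by rejection.

The signal model per channel is

* 1/f background noise (spectral exponent chi = 1, 15 uV RMS) plus 2 uV
  white sensor noise;
* at every tone onset, a sum of five Gaussian-windowed evoked components
  (P1 at 50 ms ... P3 at 380 ms, amplitudes 3-8 uV) and five
  Gaussian-enveloped band-limited bursts (delta through gamma);
  deviant responses are full scale, standard responses 0.35 of it
  (habituation to the frequent tone);
* optional artifact transients (700 uV) at chosen trial indices, used to
  plant ground truth for the rejection stage.

Group/treatment presets scale these templates in the directions the ADE
model shows: the alcohol preset shrinks P1 and N1 (hence P1N1 and N1P2),
deepens N2 (larger P2N2), damps delta-beta burst power, boosts gamma, and
shifts the beta burst centre from 14 to 20 Hz; post-stimulation presets
scale amplitudes and powers up — uniformly across channels in controls
(x1.5), weaker and concentrated at the FC stimulation site in the alcohol
group (x1.25 with an extra FC gain).  The magnitudes are calibration
choices, not measured values; only their directions are meaningful, and the
tests assert directions and recovery, not magnitudes.

What the generator does not emulate: volume conduction between electrodes
(channels share no background noise), non-stationary arousal drift,
movement artifacts with realistic morphology, and line noise.  Passing
tests therefore show that each algorithm recovers what it is defined to
recover under controlled conditions — not that the pipeline is robust to
every pathology of real recordings.

## Preprocessing

The bandpass is a one-pass Kaiser-window FIR, 0.1-45 Hz.  With ripple
delta = 0.001 (60 dB), transition width 0.2 Hz and fs = 3 kHz, the standard
Kaiser relations (beta = 0.1102(A - 8.7) = 5.653; N = (A - 8)/(2.285 dw)
rounded up to even) give an order of 54,330 points.  The group delay N/2 is
compensated exactly (odd-length symmetric kernel applied in centred
overlap-add convolution), so filtering commutes with epoching; samples
within half a kernel of the edges are flagged unreliable.  Note that DC
sits exactly at the lower stopband edge of this design, where the realized
attenuation is about 54 dB, not the nominal 60 dB reached inside the
stopband — a property of the design, verified by FFT of the taps.

Epochs span [-100, 700) ms around tone onset (half-open at both ends; 2,400
samples at 3 kHz), baseline-corrected by the per-trial, per-channel mean
over [-100, 0) ms.  Trials whose peak-to-peak range on any retained channel
exceeds the 500 uV delta criterion are rejected; a channel that would
reject more than half the trials by itself is instead marked bad (noisy
electrode) and excluded from the trial decision.  The original workflow's
visual inspection has no quantitative analogue and is deliberately not
reproduced.  A missing electrode is interpolated by inverse-distance
weighting (power 2) on the planar grid — appropriate for a flat 3x3 array
where spherical-spline methods have no geometry to exploit; for the centre
electrode this reproduces any planar-linear field exactly.

Feature tables with cells lost to bad channels are completed by iterative
round-robin imputation with an extremely-randomized-trees regressor
(missForest-style; median initialisation, tolerance 1e-3, at most 10
rounds, fixed seed).  Like any forest imputer it interpolates but cannot
extrapolate beyond the observed covariate range.

## ERP and ERSP features

Analysis is performed on the deviant-minus-standard difference wave, whose
peaks are window extrema: P1 the maximum in 20-80 ms, N1 the minimum in
60-150 ms, P2 max in 70-250 ms, N2 min in 100-330 ms, P3 max in
130-600 ms, ties resolved to the earliest sample.  Peak-to-peak amplitudes
are the signed spans P1N1 = amp(P1) - amp(N1), N1P2 = amp(P2) - amp(N1),
P2N2 = amp(P2) - amp(N2), N2P3 = amp(P3) - amp(N2), positive for canonical
morphology.

The event-related spectral perturbation (ERSP) uses a sliding Hann-tapered
FFT (400 samples at 3 kHz, zero-padded by a pad ratio of 64), per-trial
power averaged within condition and expressed as
10 log10(P(f, t) / P_baseline(f)) against the mean power of windows centred
before stimulus onset.  Frequencies below the taper's native resolution
(7.5 Hz at 400 samples / 3 kHz) come from the zero-padded grid and are
spectrally smoothed; delta-band values inherit that smoothing by
construction.  The baseline is floored at an absolute power of
1e-20 uV^2/Hz so that numerically silent frequencies in noise-free
synthetic signals cannot blow up the dB ratio; physiological baselines sit
many orders of magnitude above the floor, which therefore never binds on
real-scale data.  Band maxima (value, latency, frequency) are taken over
post-stimulus times within delta 1-4, theta 4-8, alpha 8-12, beta 12-30
(plus 12-15 / 15-18 / 18-30 subranges), gamma 30-45 Hz and the whole 1-45
Hz range; ties resolve to the earliest time, then the lowest frequency.

## Directed connectivity (nCREANN)

The connectivity input is the set of single-trial contrast signals: each
kept deviant trial minus the mean of the kept standard trials, on
[-100, 700] ms.  Trials are concatenated, channels z-scored, and lagged
design rows x_p = [x_1(n-1), ..., x_M(n-p)] built strictly within trials
(order p = 8 by default; AIC/BIC curves from least-squares linear MVAR fits
are reported for diagnostics, and recover the true order on simulated VAR
data).

A single-hidden-layer perceptron (10 tanh units, affine output) is trained
to predict x(n) from x_p by incremental (per-sample) gradient descent with
momentum 0.9 and an adaptive learning rate: the rate grows 5% after an
epoch that lowers the training MSE and the epoch is rolled back with the
rate damped to 0.7x when the MSE rises by more than 4%.  The initial rate
is 0.001: with per-sample updates this step size converges to within 0.02
R-squared of the least-squares solution on linear benchmarks, whereas 0.01
stalls in a stochastic noise ball well short of it.  Early stopping (patience
6, max 200 epochs) restores the best-validation weights.  Ten independent
random 80/10/10 train/validation/test partitions are fitted ("permuted
cross-validation"); per-fold MSE and pooled R-squared for train and test
are reported, and a healthy fit keeps test MSE within 1.5x train MSE.

The fitted map f is split into linear and non-linear parts via its
input-dependent Jacobian G(u) = W2 diag(1 - h(u)^2) W1:

* **linear part**: the average Jacobian Gbar = E[G(u)] over the training
  inputs — the network's best linear approximation on the standardized
  input distribution (the Bussgang linearization for Gaussian-like
  inputs).  Linear connectivity lC(i->j) sums |Gbar| over the p lag
  columns of source i in target row j.
* **non-linear part**: the input-dependence of the Jacobian itself.
  NC(i->j) is the mean over training inputs and lags of
  |G(u) - Gbar| on the (i->j) entries, divided by target j's mean linear
  sensitivity so that NC is scale-free.  A perfectly linear fitted
  function has G constant and NC = 0.

The origin-Jacobian alternative (linear part = Jacobian at u = 0) was
implemented first and rejected: tanh units that fit a strong *linear*
coupling operate partly in saturation, so |G(u) - G(0)| acquires a
component proportional to the coupling itself, and NC on purely linear
systems exceeded its surrogate null roughly tenfold.  Centring on the
average Jacobian removes the systematic offset, and the row normalization
removes the residual dependence on overall fitted signal scale.

Matrices are oriented from-row to to-column: entry [i, j] carries the
influence of channel i on channel j.  Connectivity is averaged across the
cross-validation repetitions; the repetition with median test MSE is kept
as the representative network for diagnostics.  Self-connections are
excluded from significance testing and group statistics.

**Significance** uses a randomisation test with time-shifted surrogates:
each surrogate circularly shifts every channel's concatenated contrast
series by an independent uniform offset in [0.1 L, 0.9 L], preserving each
channel's spectrum and dynamics exactly while destroying cross-channel
causal alignment, then reruns the identical build/train/extract chain.
Per connection, p = (1 + #{surrogate >= observed}) / (1 + n_surrogates)
(add-one rule; p is never zero), with 100 surrogates by default and a mask
at alpha = 0.05.  Two budget regimes matter:

* In the production pipeline the observed estimate averages the CV
  repetitions while each surrogate is fitted once (same architecture and
  schedule).  Averaging concentrates the observed value near the null mean
  under no-coupling, so the test is *conservative* — appropriate when the
  question is which connections survive a stringent null.
* Exact level-alpha behaviour of a randomisation test requires observed
  and surrogates to be exchangeable, i.e. identical budgets.  The
  calibration checks in the test suite use that matched regime and recover
  the attainable rate 1/(S+1) on independent channels.

A caveat established while validating: when channels carry little
autocorrelation and all structure is cross-channel, surrogate networks fit
systematically less total signal than the observed network and the NC null
is mildly too low (specificity ~85% rather than ~95%).  With realistically
autocorrelation-dominated channels (self-lag AR coefficients ~0.5, as in
cortical recordings) the budgets match and specificity holds.  Band-limited
connectivity (low/mid/high-beta) is obtained by FIR band-passing the
concatenated contrast series before estimation.

Subjects enter connectivity analysis only with at least 8 usable
electrodes; a single missing electrode of the 3x3 grid is interpolated
first, and subjects below the threshold are excluded with a logged reason.

## Statistics

* **Omnibus per measure**: mixed-design ANOVA with between factor group and
  within factors treatment (pre/post) and channel, subjects as the repeated
  unit; sums of squares computed from cell means of the balanced complete
  design (hence imputation first).  Greenhouse-Geisser-corrected p-values
  accompany the channel effects; the uncorrected p is the default report.
  The implementation is cross-checked against an independent
  repeated-measures ANOVA implementation on one-group designs and reduces
  exactly to a paired t (F = t^2) in the 2-level/1-channel case.
* **Treatment contrasts**: channelwise paired t-tests, Benjamini-Hochberg
  FDR across channels.  Zero-variance differences are flagged rather than
  propagated as infinite statistics.  (BH adjustment is not idempotent;
  re-adjusting adjusted values is a user error the API does not hide.)
* **Connectivity group comparison**: per-connection two-sided
  Mann-Whitney U (exact for small tie-free samples) with the rank-biserial
  effect size r = 1 - 2U/(n_a n_b), FDR across connections.
* **Partial Spearman**: all three series rank-transformed, residuals of
  ranked x and y after regressing on the ranked covariate correlated, t
  approximation on n - 3 degrees of freedom; used to relate
  post-stimulation activity to drinking while controlling for
  pre-stimulation activity.
* **Drinking measures**: per rat and concentration (5/10/20% v/v and their
  total), BL = mean intake over the last 7 free-access days of each
  drinking phase (averaged across phases), ADE = intake on the first day
  after each deprivation (averaged across cycles), relapse = per-cycle
  ADE minus the preceding phase's BL.  Phase x concentration
  repeated-measures ANOVA and one-sample t-tests of relapse against zero.
  The generator's cohort means are set to BL (1.02, 1.25, 1.16) and ADE
  (1.58, 1.49, 1.59) g/kg/day per concentration — totals 3.43 and 4.66 —
  with a 0.3 g/kg rat-level random effect and 0.15 g/kg daily noise.

## Problem sizes and numerical choices

The full protocol (3 kHz, 10 subjects/group, 100 surrogates) is what the
defaults describe; the shipped analyses and the test suite run the `smoke`
profile — 600 Hz, 2 subjects per group, 2 blocks, 20 surrogates, reduced
ERSP time grid — which exercises identical code paths at desk scale and
completes in under two minutes.  All analysis windows are specified in
milliseconds so the sampling rate is free.  Every random draw descends from
a single seed via independent seed streams; reruns are byte-identical.
The SGD kernel is JIT-compiled (numba); its first invocation in a fresh
environment costs a few seconds of compilation.

Known limitations: connectivity values are in arbitrary sensitivity units
on the standardized scale, so only comparisons (between connections,
groups, or against surrogates) are meaningful; NC inherits a mild positive
bias against time-shifted surrogates when cross-channel structure dominates
autocorrelation; the MLP split is an estimator of the nMVAR's linear/
non-linear decomposition, not an identification of mechanism; and the
mixed ANOVA assumes the balanced complete (imputed) design.
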