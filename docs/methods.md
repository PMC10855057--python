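# Methods

This note documents the models, numerical choices, and limitations of
`respyre`.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signal model and the synthetic generator

A PPG record is modelled as a train of cardiac pulses plus respiratory
modulation and noise.  Each pulse is the sum of two Gaussians over one
cardiac cycle of period `T`: a systolic peak of unit amplitude centred at
`0.30 T` (width `0.10 T`) and a dicrotic-notch bump of relative amplitude
`notch_amplitude` (default 0.25) at `0.62 T` (width `0.14 T`).  The
respiratory oscillator has phase `φ(t) = 2π ∫ f_r dt` with `f_r` in
[4, 60]/60 Hz, possibly piecewise constant; respiration enters through
three routes:

* **BW** — `bw_depth · sin φ(t)` added to the assembled train;
* **AM** — each pulse scaled by `1 + am_depth · sin φ` at its onset;
* **FM** — each inter-beat interval scaled by `1 + fm_depth · sin φ`
  (floored at 20 % of the mean period so the train always advances).

White Gaussian noise of SD `noise_sd` is added last, then any
deterministic artifacts (half-sine *spike*, constant *step*, sample-hold
*dropout*).  Breath onsets are the upward zero crossings of `φ`, the same
convention the zero-crossing estimator uses, so generator annotations are
exact ground truth for it.  All randomness flows through one
`numpy.random.Generator(seed)`; identical configs give bit-identical
output.

Modulation depths default to 0.1 and noise to 5 % of the pulse amplitude.
These are conventions for a clearly readable but non-trivial modulation,
not measured values; clinical traces carry correlated (pink/motion)
noise, probe-dependent waveform shapes, and non-stationary rates that the
generator does not emulate.  Passing tests on this generator therefore
demonstrate correctness of the algorithms under controlled modulation,
not clinical-grade accuracy.

## Preprocessing

All filters are order-4 Butterworth applied forward–backward
(`sosfiltfilt`), which makes them zero-phase but squares the magnitude
response.  Cutoffs are therefore calibrated numerically (Brent root
finding per edge, seeded by the analytic shift `(√2−1)^(1/2N)`) so that
the **applied** response is −3 dB exactly at the named frequencies:
4 breaths/min for the very-low-frequency high-pass, 4–60 breaths/min for
the respiratory band-pass, 35 Hz for the PPG low-pass.  Signals shorter
than three pad lengths are rejected rather than silently filtered.

Resampling is polyphase and anti-aliased (`resample_poly` with the exact
rational rate ratio); output length is `round(n · target/source)`.
Z-scoring uses per-record population statistics and then hard-clips to
±2 — the reading of "rescaled between −2 and +2" adopted here; whether
the original procedure clipped or merely observed that range is unknown,
and the clip fraction for Gaussian data (≈ 4.6 %) is small either way.
Windowing is left-to-right, half-open `[start, end)`, trailing partial
windows dropped.

## Incremental-merge pulse segmentation

The IMS idea — merge monotone line segments until pulse-scale rises
remain — is realised as a single left-to-right scan with an amplitude
hysteresis of `merge_fraction` (default 0.25) times the running median
pulse amplitude: reversals inside the hysteresis band (noise ripples,
dicrotic bumps) are merged into the surrounding slope; a trough-to-peak
rise is accepted as a pulse when its extent reaches `slope_fraction`
(default 0.5) of the running median extent of accepted rises.  The
running median (window 11 beats) is seeded from the largest rises
(top-`K`, `K` = duration × 30 beats/min) so that ripples cannot drag the
initial threshold down.  Beats whose amplitude or duration deviates more
than 2.5× (either way) from a centred running median are artifact-flagged
but kept, and excluded only when feature series are formed.

Per beat the annotations store trough/onset, systolic peak, and a timing
fiducial: the mid-amplitude crossing of the systolic rise.  The rise is
the steepest part of the pulse, so additive noise moves this point by
roughly `noise_sd / slope` — a fraction of a sample — whereas the locally
flat pulse peak jitters by several samples.  Beat-interval (FM) series
are built from fiducial times for this reason.

## Surrogates and estimators

Feature series (pulse amplitude for AM, fiducial-to-fiducial interval for
FM, mean of peak and trough for BW, plus the peak-amplitude and
consecutive-trough-mean variants) are resampled onto a uniform grid from
the first to the last beat — 4 Hz for the classical chain, 30 Hz for the
deep chain — and band-passed to 4–60 breaths/min.  Berger resampling is
implemented as the local-window weighted count-rate method on the beat
event times (window of two output intervals, partial intervals weighted
by overlap); it yields a rate signal and is documented as approximate.
The filter-based surrogate downsamples the PPG to the surrogate rate
(anti-aliased) and band-passes there, where the order-4 design is far
better conditioned than at 125 Hz (normalised edge ≈ 1e-3); the band
content is identical because 1 Hz is well below the surrogate Nyquist.

Windowed estimators: zero crossings count `x[i] ≤ 0 < x[i+1]` on the
de-meaned window; trough-peak detection uses peak prominence with an
excursion floor of 0.2× the window's interquartile range (prominence
enforces both the floor and trough/peak alternation); the spectral
estimator takes the largest Welch peak in 4–60 breaths/min (Hann taper,
segments ≤ 32 s, 50 % overlap, zero-padded to a ≤ 0.5 breaths/min grid,
ties to the lowest frequency) and carries spectral-flatness
(`low_confidence` above 0.4) and `low_resolution` diagnostics.  Estimates
outside 4–60 breaths/min are invalid; invalidity propagates through
fusion and is counted, never dropped silently.

Fusion: smart fusion uses the sample (n−1) standard deviation of the
three modulation estimates against the 4 breaths/min threshold;
peak-conditioned averaging normalises each in-band spectrum to unit
power and includes it only if ≥ 0.33 of that power lies within ±0.1 Hz of
its own maximum (both configurable — the original description names a
concentration criterion without values); temporal fusion is a trailing
median of the last 3 valid estimates, chosen for robustness to isolated
outlier windows.

## CNN-LSTM breath-phase classifier

Architecture: 1–3 stages of (1-D convolution, `same` padding → max pool →
ReLU), an LSTM (tanh activation, forget-gate bias 1), and a
time-distributed softmax over {exhalation, inhalation}; plain SGD on
per-timestep cross-entropy, batch size 20, learning rate 0.01, up to 100
epochs with early stopping (patience 10), keeping the parameters of the
epoch with minimum validation loss.  Defaults: window 210 samples (7 s at
30 Hz), one conv stage with 8 filters of length 1, pool 2, 64 LSTM units,
50:50 train–test split with 80/20 train/validation inside the train
portion.  The network is small enough to live on numpy arrays with
hand-written backpropagation (verified against finite differences in the
test suite), which keeps training deterministic bit-for-bit under a fixed
seed.

Committed interpretations where the architecture description is open:

* Classification happens at the pooled resolution — the flatten step is
  read as time-distributed flattening of channel features, the only
  reading consistent with a per-sample label output.  Reference labels
  are max-pooled ("any inhale in the pool group") to that resolution for
  the loss.
* Odd windows are tolerated: pooled length is `floor(window/pool)` per
  stage with the tail timestep dropped (210 with pool 2 → 105).
* A sample of exactly zero labels as exhalation ("higher than zero" is
  strict); softmax ties break to exhalation for determinism.
* LSTM width (64) and learning rate (0.01) are package defaults; the
  source procedure does not state them.

RR is computed per one-minute segment: the minute's windows' predicted
labels are concatenated in time order and inhalation onsets (0→1
transitions, a leading 1 counting as one onset) are counted over the
covered duration (8 × 7 s = 56 s of a minute).  Counting within a single
7 s window would carry an intrinsic +0.5-breath (≈ +4.3 breaths/min)
bias from the leading-segment rule; the minute-level count reduces this
to ≈ +0.5 breaths/min, matching the one-minute evaluation unit the
pipelines use throughout.

Dataset splits are subject-disjoint by default (no leakage between train
and test); a window-level mode exists for exact count arithmetic.  Both
are deterministic under the config seed.

## Evaluation

MAE, RMSE, signed per-pair percentage error (aggregated as the mean of
absolute values), and CP2 with an inclusive ≤ 2 breaths/min boundary
(the common convention; the source uses CP2 without defining the
boundary).  Invalid estimates are excluded from the averages and
reported as `n_invalid`.  `mae ≤ rmse` is enforced as a report
invariant.

Fluctuation flagging automates a manual exclusion step: a window is
flagged when its SD exceeds 3× the subject's median window SD or when
more than 10 % of its samples sit at the ±2 clip rails.  Thresholds are
configurable and a manual exclusion list is accepted by the pipeline;
any automatic rule is a stand-in for visual inspection, and flagged
windows are always reported with reasons rather than silently dropped.

## Problem sizes in the tests and acceptance script

The packaged runs use synthetic conditions sized for a laptop-class CPU:
the classical chain is exercised on 6 rates × 32 one-minute windows
(8-minute records, HR 75, depths 0.1, 5 % noise); the deep chain on 200
one-minute 30 Hz respiratory signals (RR uniform in 8–30 breaths/min,
random phase, 5 % noise, labels taken from the noisy signal as the
labelling rule prescribes) with a 50:50 subject split and 30 training
epochs.  These sizes are the package's own scaled-down study conditions;
the dataset readers and pipeline entry points accept the full BIDMC and
CapnoBase recordings unchanged.

## Known limitations

* The generator's two-Gaussian pulse is not a physiological arterial
  waveform; SpO₂ and ECG are not simulated.
* Berger resampling is an event-rate approximation, not the original
  beat-by-beat spectral-preserving algorithm.
* IMS thresholds (0.5 slope fraction, 0.25 hysteresis, 2.5× artifact
  ratio) are package choices — the technique is named in the literature
  without parameter values — and are exposed as keyword arguments.
* Wavelet, centred-correntropy, autoregressive-spectral and
  detrend-variant extraction/estimation techniques are out of scope, as
  is any GPU path.
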