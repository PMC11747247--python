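# Methods

## The problem

In a dense-sampling behavioural experiment, the delay between a resetting
event (here: a subliminal, just-below-threshold visual ring) and a
two-image temporal-integration task is varied in steps of one video frame
(1/60 s ≈ 16.7 ms). Accuracy as a function of that delay becomes a short,
noisy time series sampled at 60 Hz. If perception rides on an underlying
neural rhythm, accuracy should be periodically modulated over delay, and
that modulation should appear as excess spectral power relative to a null
in which the temporal structure is destroyed.

`behavosc` implements the full inference chain — aggregation, detrending,
single-taper zero-padded FFT, three surrogate-data nulls, cluster-based
permutation testing — together with a synthetic experiment generator that
stands in for real data at every stage.

## Synthetic experiments

**Observer model.** Each synthetic subject is a logistic observer with two
psychometric functions: detection of the ring, increasing in Weber contrast
`(L − L_b)/L_b` around `contrast_threshold` (default 0.13, slope 60 per
contrast unit, i.e. a width of a few 0.01 grey steps); and integration
accuracy, *decreasing* in the stimulus offset asynchrony (SOA) between the
two task images around `soa_threshold_ms` (default 42 ms, slope 0.08/ms).
A lapse rate (default 0.02) caps the ceiling, and the guess rate is 1/16
(one of 4×4 grid locations). Cohorts are sampled with between-subject
threshold spread (SOA thresholds ≈ N(41, 28) ms clipped to [16.7, 144]).

**Staircases.** The contrast staircase starts at grey 0.47 on a 0.38
background with 0.01 steps: "yes" lowers the grey, 10 consecutive "no"
raise it once, 20 consecutive "no" terminate. The streak counter is *not*
reset by the increment at 10 — this is the only reading under which the
20-"no" termination is reachable, and it makes the always-"no" observer
terminate after exactly 20 evaluated trials at grey 0.48. Sham trials at
random grey values are interleaved (default 20 %) and never evaluated.
Simulated logistic observers terminate slightly *below* their detection
threshold (median within two 0.01 steps), which is the intended behaviour:
the procedure finds a grey value the observer reliably fails to report.

The SOA staircase is 2-up/2-down from 26 ms in one-frame steps (floor
0 ms), targeting the 50 %-accuracy SOA. Termination requires the variance
of the last 20 evaluated SOAs to fall below 0.5. Taken literally on SOAs
in ms — the default here — this requires 20 identical consecutive SOAs,
which a stochastic observer essentially never produces (simulations:
0/500 runs terminate in 2000 trials); the level nevertheless hovers within
two steps of the target. `variance_units="frames"` applies the same 0.5
bound to SOAs in frames, under which the staircase terminates readily at
the same level. Both readings are provided because the published rule does
not state its units; the ms reading is kept as the default.

**Trial generation.** Threshold-SOA trials at delay *t* (ms before the
first task stimulus) succeed with probability

```
p(t) = clamp( base + b1·t + b2·t² + Σᵢ aᵢ·cos(2π fᵢ t/1000 + φᵢ), 0, 1 )
```

drawn independently per trial; clamping events are counted and logged.
Control-SOA trials (short = 0 ms, intermediate ± one frame, long =
threshold + 48 ms) follow the observer's SOA psychometric function. Catch
trials are interspersed so each emitted trial is a catch with probability
`catch_rate` (default 10 %, real/fake 50:50): real catches query the
detection model at the calibrated subliminal contrast (two grey steps below
threshold) plus a false-alarm floor, fake catches use the false-alarm rate
alone (default 0.1; any value is defensible, none is canonical).

Defaults reproduce the reference study conditions: 19 subjects × 2
sessions, 19 delays of one frame each (frames 19–37, ≈ 317–617 ms before
the target; 312 ms is not an integer frame count, so the grid starts at
the first frame beyond it), 20 threshold trials per delay and session
(380 per session), base accuracy 0.5.

`simulate_delay_series` draws the per-delay number of correct threshold
trials directly as a binomial variate — the exact distribution of
aggregating trial-level records — and is the fast path for simulation
studies that never touch control or catch trials.

**What the generator does not emulate:** reaction times, response
timeouts, learning or fatigue across a session, sequential dependencies
between trials (each trial is an independent Bernoulli draw), and any
true oscillatory *neural* process — the cosine modulation is imposed on
the success probability directly. Passing tests therefore show that the
pipeline recovers a probability modulation of known frequency from
binomial noise at realistic sample sizes; they cannot show that real
behavioural data contain such modulations.

## Spectral analysis

Per subject and session, the fraction correct of threshold-SOA trials at
each delay is computed (control and catch trials excluded; a delay with
zero trials is an error, never interpolated). The series is detrended by
ordinary least squares — order 1 by default, order 2 as a control against
slow artefacts of the short window — which also demeans it. Fitting uses a
delay axis rescaled to [−1, 1]; residuals are identical to fitting raw
milliseconds (property-tested) but the normal equations stay conditioned.

The detrended 19-sample series is multiplied by a taper, zero-padded to
1 s (60 samples at 60 Hz) and Fourier-transformed; power is the squared
magnitude at the integer bins 1–29 Hz (the 30 Hz Nyquist bin is excluded).
The default taper is the first discrete prolate spheroidal sequence with a
3 Hz half-bandwidth, i.e. time-half-bandwidth 19/60 × 3 ≈ 0.95; "3 Hz
spectral smoothing" is read as a half-bandwidth and the taper family as
DPSS, both flagged as assumptions (a Hann window and no taper are
available). Tapers are normalized to unit RMS and applied *before*
padding; absolute power units are irrelevant because observed and
surrogate spectra share every setting. Power spectra are averaged across
sessions within subject, then across subjects.

Numerical notes: the frequency grid is computed as k/`pad_seconds`, so the
retained grid is exactly {1, …, 29} Hz; the FFT path agrees with a direct
O(N²) DFT to ~1e-13 relative error for all series lengths up to 64; a
two-point symmetric Hann window is identically zero and rejected.

## Surrogate nulls

Each method yields, per subject, the per-frequency *median* over
repetitions within session, then the mean over sessions (default 1000
repetitions; the calibration studies below use 500):

* **time_shuffle** — permutes the *raw* accuracies across delays, then
  detrends per repetition (the published order: raw values are shuffled,
  each repetition is then detrended and transformed);
* **random_accuracy** — per delay, draws the observed number of trials as
  fair coins, averages, and adds the offset `session mean accuracy − 0.5`
  ("session mean" is taken as the trial-weighted mean accuracy at the
  threshold SOA, the only level the spectra use). A `bernoulli_mean`
  variant draws trials directly at the session mean;
* **ar_model** — fits `X_t = c + Φ X_{t−1} + ε_t` to the *detrended*
  series and simulates Gaussian-innovation paths of the same length
  (burn-in 100 samples), detrending each repetition again, per the
  published order. The default estimator is closed-form conditional least
  squares; a Gaussian-MLE ARIMA(1,0,0) fit (statsmodels) is available via
  `method="mle"` and serves as the cross-check in the test suite. Fits are
  per subject and session; `|Φ| ≥ 1` is rejected as nonstationary.

All three run through the identical detrend/taper/pad/FFT code path as the
observed data. Note that this shared path shapes the surrogate spectra
too: detrending suppresses power below ~4 Hz, so even white-noise
surrogates are "flat" only above that band.

## Cluster-based permutation test

Per frequency, a paired t statistic across subjects compares observed and
surrogate power (df = n − 1 = 18 at the default cohort size). Values
exceeding the cluster-forming threshold — the one-sided Student-t critical
value, 1.734 for 18 df at α = 0.05 — are grouped into maximal runs of
adjacent frequency bins and summed. The null distribution of the largest
cluster statistic is built from 10,000 random per-subject swaps of
observed and surrogate spectra (sign flips of the paired differences;
because sign flips leave the per-frequency sum of squared differences
unchanged, permuted t values are computed in closed form). Monte-Carlo
p-values use the (1 + #{null ≥ stat})/(1 + n_perm) correction. The default
forms clusters on both tails with separate positive and negative nulls;
`one_sided_positive` reproduces a positive-clusters-only analysis exactly.

## Calibration of the procedure — an important caveat

The test suite measures the false-positive rate of the full pipeline on
null synthetic experiments (no oscillation, 19 × 2 × 20 trials/delay, 500
surrogate repetitions, 1000 permutations): the fraction of experiments
with *any* cluster at p < 0.05 is ≈ 0.95 for all three surrogate methods —
wildly above the nominal 5 %. This is not an implementation defect but a
property of the procedure itself, reproduced here faithfully:

* short-window power estimates are strongly right-skewed (approximately
  scaled χ² with few degrees of freedom), so the per-subject surrogate
  *median* over repetitions sits systematically below the *mean* of the
  observed power distribution even under the null (measured
  observed/surrogate ratio ≈ 1.3–1.5, per-frequency mean t ≈ +1.4 to
  +2.0);
* replacing the median with a mean removes that first-order bias but the
  sign-flip t test on skewed, non-symmetric differences remains
  miscalibrated (measured false-positive rates 0.15–0.7 depending on
  method).

Consequently, positive clusters from this procedure should be read as
"observed power exceeds the surrogate *median*", not as evidence
calibrated at the nominal α. The package reports the measured rates
(`scripts/acceptance.py`) rather than hiding them; users who need
calibrated inference should compare observed power against the full
surrogate *distribution* per subject (e.g. rank-based p-values), which is
outside the present scope.

Detection power, by contrast, is excellent: an injected 11 Hz component of
amplitude 0.12 on base accuracy 0.55 is recovered as a significant
positive cluster containing the 11 Hz bin in ~100 % of simulated
experiments.

## Problem sizes and determinism

Simulation studies in the tests and the acceptance script use 200 null
experiments and 100 recovery experiments with 500 surrogate repetitions
and 1000 permutations each — large enough for the reported rates to have
Monte-Carlo standard errors below 0.02 while the whole suite runs in a
couple of minutes on one core. Surrogate ensembles are generated and
transformed as vectorized stacks, and the permutation t statistics are
computed in closed form, which is what makes these sizes cheap.

All randomness flows from one master seed split into named child streams
(`generator`, one per surrogate method, `permutations`), so identical
configurations produce byte-identical result bundles, and each stage can
be reproduced in isolation.

## Known limitations

* The calibration caveat above: cluster p-values are anticonservative by
  construction of the surrogate comparison.
* Delay ranges shorter than ~300 ms cannot contain a full cycle below
  ~3.3–3.5 Hz; low-frequency clusters partly reflect window/detrending
  effects rather than resolved oscillations (the order-2 detrend option
  exists precisely to probe this).
* The published grey-value bookkeeping is internally ambiguous between
  simple Weber contrast `(L−L_b)/L_b` (a 0.01 step ≈ 2.6 %) and the
  symmetric convention `2(L−L_b)/(L+L_b)` (0.47 ≈ 21.2 %, 0.57 ≈ 40 %);
  both converters are provided and neither is asserted as canonical.
* No phase analysis, no multitaper averaging, no Welch segmentation, no
  phase-randomization or IAAFT surrogates, and no inferential statistics
  in the descriptive summaries.
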