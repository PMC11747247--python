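# behavosc

Spectral analysis of **behavioural oscillations** in dense-sampling
experiments — for cognitive/behavioural neuroscientists who measure task
accuracy as a fine-grained function of the delay between a (subliminal)
resetting stimulus and a task stimulus, and want to know whether that
accuracy time course is rhythmically modulated.

## What it computes

Given trial-level records (subject, session, subliminal-target delay, SOA
condition, correctness), the pipeline:

1. aggregates the fraction correct of threshold-SOA trials per delay into
   one series per subject and session (delays sampled every video frame,
   1/60 s, give a 60 Hz series);
2. removes an OLS polynomial trend (order 1 default, order 2 control),
   which also demeans the series;
3. applies a single DPSS taper (3 Hz half-bandwidth), zero-pads to 1 s and
   takes the FFT: power `|X(f)|²` on the integer grid 1–29 Hz;
4. builds three surrogate nulls — **time shuffle** (permute raw accuracies
   over delay), **random accuracy** (coin-flip trials with the observed
   trial counts plus a mean-performance offset), and an **AR(1) model**
   `X_t = c + Φ X_{t−1} + ε_t` fitted to the detrended series — each
   reduced per subject to the median over 1000 repetitions, averaged over
   sessions, and passed through the identical spectral path;
5. compares observed and surrogate power per frequency with a paired
   t statistic across subjects, thresholds at the critical value
   (t = 1.734 for 19 subjects at α = 0.05), sums t within runs of adjacent
   suprathreshold bins, and assigns each cluster a Monte-Carlo p-value
   from 10,000 per-subject observed/surrogate swaps (max-cluster null).

A synthetic-experiment module generates complete data sets for all of
this: logistic observers, the two adaptive staircases that calibrate them
(a yes/no contrast staircase with streak rules, a 2-up/2-down SOA
staircase), and trial generation with controllable cosine accuracy
modulations — so every stage is testable without real data. See
`docs/methods.md` for the model details, the numerical choices, and an
important caveat about the statistical calibration of the
median-surrogate comparison.

## Worked example

Inject an 11 Hz accuracy modulation (amplitude 0.12 on base accuracy
0.55) into a default-size synthetic experiment (19 subjects × 2 sessions ×
20 trials per delay) and run the full pipeline against all three
surrogate methods:

```python
from behavosc import (ExperimentConfig, OscillationComponent, RunConfig,
                      TestConfig, run_pipeline)

cfg = RunConfig(
    experiment=ExperimentConfig(
        base_accuracy=0.55,
        components=(OscillationComponent(frequency_hz=11.0, amplitude=0.12),),
    ),
    n_surrogate_reps=500,
    test=TestConfig(n_permutations=2000),
    seed=1,
)
result = run_pipeline(cfg)
for method, test in result.tests.items():
    for c in test.clusters:
        print(f"{method}: {c.sign} cluster {c.freq_lo_hz:g}-{c.freq_hi_hz:g} Hz  "
              f"stat={c.cluster_stat:.1f}  p={c.p_value:.4f}")
```

prints

```
time_shuffle: negative cluster 2-4 Hz  stat=-6.9  p=0.1144
time_shuffle: positive cluster 9-13 Hz  stat=39.8  p=0.0005
time_shuffle: negative cluster 15-15 Hz  stat=-2.4  p=0.4033
time_shuffle: negative cluster 20-21 Hz  stat=-3.9  p=0.3383
random_accuracy: positive cluster 1-1 Hz  stat=2.0  p=0.3048
random_accuracy: positive cluster 4-15 Hz  stat=65.3  p=0.0005
random_accuracy: positive cluster 18-19 Hz  stat=3.8  p=0.2484
random_accuracy: positive cluster 22-29 Hz  stat=23.7  p=0.0070
ar_model: negative cluster 2-4 Hz  stat=-6.6  p=0.1364
ar_model: positive cluster 8-13 Hz  stat=45.8  p=0.0005
ar_model: positive cluster 23-25 Hz  stat=6.6  p=0.1329
```

Every method recovers a highly significant positive cluster containing
the injected 11 Hz bin (9–13, 4–15 and 8–13 Hz); the remaining clusters
illustrate why the methods note discusses calibration before p-values
from this procedure are taken at face value. With `output_dir` set,
`run_pipeline` also writes the trial table, delay series, observed and
surrogate spectra, cluster JSON and a manifest with the seed and config
hash.

The same pipeline is available from the shell:

```bash
behavosc simulate --seed 1 --out trials.csv
behavosc staircase --kind contrast --seed 1
behavosc analyze --config run.yaml --outdir out/
behavosc summarize --trials trials.csv --outdir out/
```

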