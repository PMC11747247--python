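"""Synthetic dense-sampling experiments.

This module is the stand-in for a real behavioural data set.  It provides

* :class:`ObserverModel` — a logistic psychophysical observer with separate
  psychometric functions for detecting a low-contrast ring (increasing in
  Weber contrast) and for solving a two-image temporal-integration task
  (accuracy decreasing in the stimulus offset asynchrony, SOA);
* the two adaptive staircases used to calibrate each observer before the
  main experiment: a yes/no contrast staircase with streak rules and sham
  interleaves, and a 2-up/2-down SOA staircase with a variance-based
  stopping rule and random interleaves;
* :func:`generate_experiment` — full trial-level data sets in which the
  accuracy of threshold-SOA trials varies with the delay between a
  subliminal ring and the task stimuli: a base level, optional linear and
  quadratic trends, and any number of additive cosine components.  This is
  the signal the downstream spectral analysis is designed to detect.

All timing is frame-locked to a 60 Hz display: one frame is exactly 1/60 s
(the conventional "16.6 ms").  Delay grids are therefore specified in frames
internally and exposed in milliseconds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import expit

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

#: Duration of one video frame in seconds (60 Hz refresh).
FRAME_S = 1.0 / 60.0
#: Duration of one video frame in milliseconds (exactly 1000/60).
FRAME_MS = 1000.0 / 60.0

#: SOA condition labels, ordered from shortest to longest gap, plus catches.
SOA_CONDITIONS = ("short", "intermediate_minus", "threshold", "intermediate_plus", "long")
CATCH_CONDITIONS = ("catch_real", "catch_fake")

#: Background grey value of the display and the staircase grey-step.
BACKGROUND_GREY = 0.38
GREY_STEP = 0.01
GREY_MAX = 0.57


def weber_contrast(grey: float, background: float = BACKGROUND_GREY) -> float:
    """Simple Weber contrast (L - L_b) / L_b of a grey value against the background."""
    if background <= 0:
        raise InvalidArgumentError("background luminance must be positive")
    return (grey - background) / background


def symmetric_contrast(grey: float, background: float = BACKGROUND_GREY) -> float:
    """Michelson-like contrast 2(L - L_b)/(L + L_b).

    Provided alongside :func:`weber_contrast` because published grey-value
    bookkeeping is often ambiguous between the two conventions; nothing in
    this package asserts one of them as canonical.
    """
    if grey + background <= 0:
        raise InvalidArgumentError("luminances must be positive")
    return 2.0 * (grey - background) / (grey + background)


# ---------------------------------------------------------------------------
# Observer model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverModel:
    """A logistic observer for both the detection and the integration task.

    Parameters
    ----------
    contrast_threshold:
        Weber-contrast fraction at which the ring is detected with
        probability 0.5 (before lapses).
    contrast_slope:
        Logistic steepness of the detection function, per unit of Weber
        contrast.  The default corresponds to a psychometric width of a few
        0.01 grey-value steps, i.e. a fairly crisp detection threshold.
    soa_threshold_ms:
        SOA at which integration accuracy passes the midpoint between the
        guess rate and the lapse-limited ceiling (~50 % for the default
        rates); this is the quantity the SOA staircase estimates.
    soa_slope:
        Logistic steepness of the integration function, per millisecond of
        SOA.  Accuracy *decreases* with SOA: longer gaps make the two images
        harder to integrate.
    lapse_rate:
        Probability of an attentional lapse, in [0, 0.1].
    guess_rate:
        Chance level of the location report.  Reporting one of 4x4 grid
        locations gives 1/16.
    """

    contrast_threshold: float = 0.13
    contrast_slope: float = 60.0
    soa_threshold_ms: float = 42.0
    soa_slope: float = 0.08
    lapse_rate: float = 0.02
    guess_rate: float = 1.0 / 16.0

    def __post_init__(self):
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise InvalidArgumentError("lapse_rate must be in [0, 0.1]")
        if not (0.0 <= self.guess_rate <= 1.0):
            raise InvalidArgumentError("guess_rate must be a probability")
        if self.contrast_slope < 0 or self.soa_slope < 0:
            raise InvalidArgumentError("slopes must be nonnegative")
        if self.contrast_threshold < 0 or self.soa_threshold_ms < 0:
            raise InvalidArgumentError("thresholds must be nonnegative")

    def p_seen(self, contrast: float) -> float:
        """Probability of reporting the ring as seen at the given Weber contrast."""
        if contrast < 0:
            raise InvalidArgumentError("contrast must be nonnegative")
        if math.isinf(self.contrast_slope):
            core = 0.5 if contrast == self.contrast_threshold else float(contrast > self.contrast_threshold)
        else:
            core = expit(self.contrast_slope * (contrast - self.contrast_threshold))
        return (1.0 - self.lapse_rate) * float(core)

    def p_correct(self, soa_ms: float) -> float:
        """Probability of a correct location report at the given SOA (monotone decreasing)."""
        if soa_ms < 0:
            raise InvalidArgumentError("SOA must be nonnegative")
        core = expit(-self.soa_slope * (soa_ms - self.soa_threshold_ms))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * float(core)


def simulate_detection(observer: ObserverModel, contrast: float, rng: np.random.Generator) -> bool:
    """Draw a single yes/no detection response at the given Weber contrast."""
    return bool(rng.random() < observer.p_seen(contrast))


def make_observers(
    n_subjects: int,
    rng: np.random.Generator,
    soa_threshold_mean_ms: float = 41.0,
    soa_threshold_sd_ms: float = 28.0,
    contrast_threshold_mean: float = 0.13,
    contrast_threshold_sd: float = 0.03,
) -> list[ObserverModel]:
    """Sample a cohort of observers with between-subject threshold variability.

    Defaults place the cohort mean SOA threshold near 41 ms with a wide
    spread, matching the kind of variability adaptive staircases produce in
    practice; thresholds are clipped to physically sensible ranges.
    """
    observers = []
    for _ in range(n_subjects):
        soa_thr = float(np.clip(rng.normal(soa_threshold_mean_ms, soa_threshold_sd_ms), FRAME_MS, 144.0))
        c_thr = float(np.clip(rng.normal(contrast_threshold_mean, contrast_threshold_sd), 0.03, 0.45))
        observers.append(ObserverModel(contrast_threshold=c_thr, soa_threshold_ms=soa_thr))
    return observers


# ---------------------------------------------------------------------------
# Staircases
# ---------------------------------------------------------------------------


class StaircaseTrial(NamedTuple):
    level: float
    response: bool
    evaluated: bool


@dataclass
class StaircaseResult:
    """Full log of an adaptive staircase run.

    ``trial_log`` contains every presented trial, including the interleaved
    sham trials (``evaluated=False``) that never influence the staircase.
    ``terminal_level`` is the level of the last evaluated trial when the
    staircase terminated, otherwise the level the staircase would present
    next.
    """

    kind: str
    trial_log: list[StaircaseTrial]
    terminal_level: float
    terminated: bool

    @property
    def n_trials(self) -> int:
        return len(self.trial_log)

    @property
    def evaluated_levels(self) -> np.ndarray:
        return np.array([t.level for t in self.trial_log if t.evaluated])


def run_contrast_staircase(
    observer: ObserverModel,
    rng: np.random.Generator,
    start_grey: float = 0.47,
    background_grey: float = BACKGROUND_GREY,
    step: float = GREY_STEP,
    max_trials: int = 1000,
    sham_rate: float = 0.2,
    grey_max: float = GREY_MAX,
) -> StaircaseResult:
    """Yes/no staircase estimating the just-subliminal grey value of the ring.

    Rules (levels are grey values, evaluated trials only):

    * "yes" (seen): decrease the grey value by ``step`` (floored at the
      background grey) and reset the "no" streak;
    * 10 consecutive "no": increase the grey value by ``step``; the streak
      counter is deliberately *not* reset, so that
    * 20 consecutive "no": terminate; the momentary grey value is the
      terminal level.

    Sham trials at random grey values are interleaved with probability
    ``sham_rate``; their responses are logged but never evaluated.
    """
    if start_grey < background_grey:
        raise InvalidArgumentError("start_grey must not be below the background grey")
    if max_trials < 1:
        raise InvalidArgumentError("max_trials must be >= 1")
    level = float(start_grey)
    no_streak = 0
    log: list[StaircaseTrial] = []
    terminated = False
    terminal = level
    for _ in range(max_trials):
        if rng.random() < sham_rate:
            sham_grey = background_grey + step * int(rng.integers(0, round((grey_max - background_grey) / step) + 1))
            seen = simulate_detection(observer, weber_contrast(sham_grey, background_grey), rng)
            log.append(StaircaseTrial(sham_grey, seen, False))
            continue
        seen = simulate_detection(observer, weber_contrast(level, background_grey), rng)
        log.append(StaircaseTrial(level, seen, True))
        if seen:
            no_streak = 0
            level = max(background_grey, level - step)
        else:
            no_streak += 1
            if no_streak == 20:
                terminated = True
                terminal = level
                break
            if no_streak == 10:
                level = min(grey_max, level + step)
    if not terminated:
        terminal = level
    return StaircaseResult("contrast", log, terminal, terminated)


def run_soa_staircase(
    observer: ObserverModel,
    rng: np.random.Generator,
    start_soa_ms: float = 26.0,
    step_ms: float = FRAME_MS,
    max_trials: int = 1000,
    sham_rate: float = 0.2,
    stability_window: int = 20,
    stability_variance: float = 0.5,
    variance_units: str = "ms",
) -> StaircaseResult:
    """2-up/2-down staircase estimating the ~50 %-accuracy SOA.

    Two consecutive correct reports increase the SOA by one step (the task
    gets harder), two consecutive incorrect reports decrease it (floored at
    0 ms); streak counters reset after every move.  The staircase terminates
    once the variance of the last ``stability_window`` evaluated SOAs falls
    below ``stability_variance``.

    With the default threshold of 0.5 applied to SOAs measured in
    milliseconds and one-frame (~16.7 ms) steps, stability effectively
    requires the last 20 evaluated SOAs to be identical, which a stochastic
    observer rarely produces; ``variance_units="frames"`` applies the same
    threshold to SOAs expressed in frames, under which a staircase hovering
    within one step of its equilibrium terminates readily.

    Random-SOA sham trials (0–8 frames) are interleaved with probability
    ``sham_rate`` and never evaluated.
    """
    if start_soa_ms < 0:
        raise InvalidArgumentError("start_soa_ms must be nonnegative")
    if variance_units not in ("ms", "frames"):
        raise InvalidArgumentError("variance_units must be 'ms' or 'frames'")
    if max_trials < 1:
        raise InvalidArgumentError("max_trials must be >= 1")
    level = float(start_soa_ms)
    cc = ci = 0
    evaluated: list[float] = []
    log: list[StaircaseTrial] = []
    terminated = False
    terminal = level
    scale = 1.0 if variance_units == "ms" else 1.0 / step_ms
    for _ in range(max_trials):
        if rng.random() < sham_rate:
            sham_soa = float(rng.integers(0, 9)) * FRAME_MS
            correct = bool(rng.random() < observer.p_correct(sham_soa))
            log.append(StaircaseTrial(sham_soa, correct, False))
            continue
        correct = bool(rng.random() < observer.p_correct(level))
        log.append(StaircaseTrial(level, correct, True))
        evaluated.append(level)
        if len(evaluated) >= stability_window:
            window = np.array(evaluated[-stability_window:]) * scale
            if float(np.var(window)) < stability_variance:
                terminated = True
                terminal = level
                break
        if correct:
            cc += 1
            ci = 0
            if cc == 2:
                level += step_ms
                cc = 0
        else:
            ci += 1
            cc = 0
            if ci == 2:
                level = max(0.0, level - step_ms)
                ci = 0
    if not terminated:
        terminal = level
    return StaircaseResult("soa", log, terminal, terminated)


# ---------------------------------------------------------------------------
# Experiment generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OscillationComponent:
    """A cosine accuracy modulation a*cos(2*pi*f*t + phi) over delay t (seconds)."""

    frequency_hz: float
    amplitude: float
    phase_rad: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.frequency_hz < 30.0):
            raise InvalidArgumentError("frequency must be in (0, 30) Hz")
        if abs(self.amplitude) > 0.5:
            raise InvalidArgumentError("|amplitude| must be <= 0.5")


def default_delay_grid() -> np.ndarray:
    """Default subliminal-target delay grid: frames 19..37 before the target.

    19 delays, one per 60 Hz frame, spanning ~316.7–616.7 ms before the first
    task stimulus.  With 20 threshold-SOA trials per delay this yields the
    canonical 380 threshold trials per session.
    """
    return np.arange(19, 38) * FRAME_MS


@dataclass(frozen=True)
class ExperimentConfig:
    """Study-level configuration of a synthetic dense-sampling experiment.

    Defaults reproduce the reference study conditions: 19 subjects x 2
    sessions, a one-frame delay grid of 19 delays, 20 threshold-SOA trials
    per delay and session, base accuracy 0.5 with no trend and no
    oscillation, and a 10 % catch-trial rate split evenly between real and
    fake catches.
    """

    n_subjects: int = 19
    n_sessions: int = 2
    delay_grid_ms: tuple = field(default_factory=lambda: tuple(default_delay_grid()))
    trials_per_delay: int = 20
    control_trials_per_delay: int = 2
    base_accuracy: float = 0.5
    trend_linear: float = 0.0  # accuracy per ms of delay
    trend_quadratic: float = 0.0  # accuracy per ms^2
    components: tuple = ()
    catch_rate: float = 0.1
    false_alarm_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        grid = np.asarray(self.delay_grid_ms, dtype=float)
        if grid.size == 0:
            raise InvalidArgumentError("delay grid must not be empty")
        if grid.size > 1:
            d = np.diff(grid)
            if np.any(d <= 0):
                raise InvalidArgumentError("delay grid must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9):
                raise InvalidArgumentError("delay grid must be evenly spaced")
        if self.trials_per_delay < 1:
            raise InvalidArgumentError("trials_per_delay must be >= 1")
        if not (0.0 <= self.catch_rate < 1.0):
            raise InvalidArgumentError("catch_rate must be in [0, 1)")
        if not (0.0 <= self.base_accuracy <= 1.0):
            raise InvalidArgumentError("base_accuracy must be a probability")
        for comp in self.components:
            if not isinstance(comp, OscillationComponent):
                raise InvalidArgumentError("components must be OscillationComponent instances")

    @property
    def delays(self) -> np.ndarray:
        return np.asarray(self.delay_grid_ms, dtype=float)


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial of the main experiment."""

    subject: str
    session: int
    trial_index: int
    delay_ms: Optional[float]
    soa_condition: str
    soa_ms: Optional[float]
    correct: Optional[bool]
    reported_seen: Optional[bool]

    def __post_init__(self):
        is_catch = self.soa_condition in CATCH_CONDITIONS
        if is_catch:
            if self.reported_seen is None or self.correct is not None:
                raise InvalidArgumentError("catch trials carry reported_seen, not correct")
        else:
            if self.correct is None or self.reported_seen is not None:
                raise InvalidArgumentError("task trials carry correct, not reported_seen")
            if self.soa_condition not in SOA_CONDITIONS:
                raise InvalidArgumentError(f"unknown soa_condition {self.soa_condition!r}")


def accuracy_profile(config: ExperimentConfig, delays_ms: Optional[np.ndarray] = None):
    """Per-delay success probability of threshold-SOA trials.

    Returns ``(p, n_clamped)`` where ``p[d] = clamp(base + b1*t + b2*t^2 +
    sum_i a_i cos(2*pi*f_i*t + phi_i), 0, 1)`` with t the delay in ms (and
    seconds inside the cosines), and ``n_clamped`` counts the delays whose
    raw value fell outside [0, 1].
    """
    t_ms = config.delays if delays_ms is None else np.asarray(delays_ms, dtype=float)
    p = config.base_accuracy + config.trend_linear * t_ms + config.trend_quadratic * t_ms**2
    t_s = t_ms / 1000.0
    for comp in config.components:
        p = p + comp.amplitude * np.cos(2.0 * np.pi * comp.frequency_hz * t_s + comp.phase_rad)
    n_clamped = int(np.sum((p < 0.0) | (p > 1.0)))
    return np.clip(p, 0.0, 1.0), n_clamped


def _session_threshold_soa(observer: ObserverModel, start_soa_ms: float = 26.0) -> float:
    """Threshold SOA on the staircase lattice (start +/- whole frames, floored at 0)."""
    k = round((observer.soa_threshold_ms - start_soa_ms) / FRAME_MS)
    return max(0.0, start_soa_ms + k * FRAME_MS)


def _condition_soas(threshold_soa: float) -> dict[str, float]:
    return {
        "short": 0.0,
        "intermediate_minus": max(0.0, threshold_soa - FRAME_MS),
        "threshold": threshold_soa,
        "intermediate_plus": threshold_soa + FRAME_MS,
        "long": threshold_soa + 48.0,
    }


def subliminal_contrast(observer: ObserverModel, background: float = BACKGROUND_GREY) -> float:
    """Weber contrast of the calibrated subliminal ring: two grey steps below threshold."""
    return max(0.0, observer.contrast_threshold - 2.0 * GREY_STEP / background)


def generate_experiment(
    config: ExperimentConfig,
    observers: Sequence[ObserverModel],
) -> list[TrialRecord]:
    """Generate a full trial-level data set, deterministically given ``config.seed``.

    Threshold-SOA trials succeed with the delay-dependent probability of
    :func:`accuracy_profile`; control-SOA trials follow each observer's SOA
    psychometric function; real catch trials are "seen" according to the
    detection model at the calibrated subliminal contrast (plus false
    alarms) and fake catch trials at the false-alarm rate alone.  Catch
    trials are interspersed so that each emitted trial is a catch with
    probability ``catch_rate`` (real/fake with equal probability); per-delay
    threshold-trial counts are exact.
    """
    if len(observers) != config.n_subjects:
        raise InvalidArgumentError(
            f"need one observer per subject ({config.n_subjects}), got {len(observers)}"
        )
    rng = np.random.default_rng(config.seed)
    delays = config.delays
    p_threshold, n_clamped = accuracy_profile(config)
    if n_clamped:
        logger.info("accuracy profile clamped to [0, 1] at %d of %d delays", n_clamped, delays.size)

    trials: list[TrialRecord] = []
    width = len(str(config.n_subjects))
    for s_idx in range(config.n_subjects):
        subject = f"s{s_idx + 1:0{width}d}"
        observer = observers[s_idx]
        p_seen_real = observer.p_seen(subliminal_contrast(observer))
        p_seen_real = p_seen_real + (1.0 - p_seen_real) * config.false_alarm_rate
        for session in range(1, config.n_sessions + 1):
            thr_soa = _session_threshold_soa(observer)
            soas = _condition_soas(thr_soa)
            pool: list[tuple[float, str]] = []
            for d in delays:
                pool.extend([(d, "threshold")] * config.trials_per_delay)
                for cond in ("short", "intermediate_minus", "intermediate_plus", "long"):
                    pool.extend([(d, cond)] * config.control_trials_per_delay)
            order = rng.permutation(len(pool))
            trial_index = 0
            for j in order:
                # geometric interleave: every emitted slot is a catch trial
                # with probability catch_rate
                while rng.random() < config.catch_rate:
                    real = bool(rng.random() < 0.5)
                    p_seen = p_seen_real if real else config.false_alarm_rate
                    trials.append(
                        TrialRecord(
                            subject=subject,
                            session=session,
                            trial_index=trial_index,
                            delay_ms=None,
                            soa_condition="catch_real" if real else "catch_fake",
                            soa_ms=None,
                            correct=None,
                            reported_seen=bool(rng.random() < p_seen),
                        )
                    )
                    trial_index += 1
                delay, cond = pool[j]
                d_idx = int(np.searchsorted(delays, delay))
                p = p_threshold[d_idx] if cond == "threshold" else observer.p_correct(soas[cond])
                trials.append(
                    TrialRecord(
                        subject=subject,
                        session=session,
                        trial_index=trial_index,
                        delay_ms=float(delay),
                        soa_condition=cond,
                        soa_ms=float(soas[cond]),
                        correct=bool(rng.random() < p),
                        reported_seen=None,
                    )
                )
                trial_index += 1
    return trials


def simulate_delay_series(config: ExperimentConfig, rng: Optional[np.random.Generator] = None):
    """Directly simulate per-subject/session accuracy-by-delay series.

    Draws the per-delay number of correct threshold-SOA trials as a binomial
    variate, which is exactly the distribution obtained by generating
    trial-level records and aggregating them, but orders of magnitude
    faster.  Returns ``{(subject, session): DelaySeries}`` with raw
    (un-detrended) accuracies.  Useful for simulation studies that never
    touch control or catch trials.
    """
    from .preprocess import DelaySeries  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(config.seed)
    delays = config.delays
    p, _ = accuracy_profile(config)
    out = {}
    width = len(str(config.n_subjects))
    for s_idx in range(config.n_subjects):
        subject = f"s{s_idx + 1:0{width}d}"
        for session in range(1, config.n_sessions + 1):
            k = rng.binomial(config.trials_per_delay, p)
            out[(subject, session)] = DelaySeries(
                subject=subject,
                session=session,
                delays_ms=delays.copy(),
                accuracy=k / config.trials_per_delay,
                n_trials=np.full(delays.size, config.trials_per_delay),
            )
    return out
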