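"""Surrogate-data nulls for the accuracy power spectrum.

Three surrogate constructions, each destroying the temporal structure under
test while preserving a different aspect of the observed data:

* ``time_shuffle`` — permute the raw per-delay accuracies in time (the value
  multiset is preserved exactly);
* ``random_accuracy`` — redraw every trial as a fair coin, average per delay
  with the observed trial counts, and add the session's mean-performance
  offset (the binomial trial-count noise is preserved);
* ``ar_model`` — fit a first-order autoregression X_t = c + phi*X_{t-1} +
  eps_t to the detrended series and simulate it (the lag-1 autocorrelation
  is preserved).

Every repetition is pushed through the identical detrend/taper/pad/FFT path
as the observed data (:func:`behavosc.spectral.analyze_raw_series`).  Per
subject, the per-frequency median over repetitions is taken within session
and the session medians are then averaged, yielding one surrogate spectrum
per subject and method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import (
    DegenerateSeriesError,
    InvalidArgumentError,
    NonstationaryModelError,
)
from .preprocess import DelaySeries, detrend
from .spectral import SpectralSettings, analyze_raw_series

SURROGATE_METHODS = ("time_shuffle", "random_accuracy", "ar_model")


@dataclass(frozen=True)
class ARFit:
    """Estimated AR(1) parameters of a detrended accuracy series."""

    c: float
    phi: float
    resid_sd: float
    n_obs: int

    def __post_init__(self):
        if self.resid_sd < 0:
            raise InvalidArgumentError("resid_sd must be nonnegative")
        if self.n_obs < 3:
            raise InvalidArgumentError("n_obs must be >= 3")


@dataclass(frozen=True)
class SurrogateSpectrum:
    """Per-subject reduced surrogate spectrum: median over reps, mean over sessions."""

    subject: str
    method: str
    frequencies_hz: np.ndarray
    power: np.ndarray
    n_reps: int

    def __post_init__(self):
        if self.method not in SURROGATE_METHODS:
            raise InvalidArgumentError(f"unknown surrogate method {self.method!r}")
        if np.any(np.asarray(self.power) < 0):
            raise InvalidArgumentError("power must be nonnegative")


def surrogate_time_shuffle(
    series_raw: DelaySeries,
    settings: SpectralSettings,
    n_reps: int = 1000,
    rng: Optional[np.random.Generator] = None,
):
    """Spectra of ``n_reps`` random time-permutations of the raw accuracies.

    The *raw* (pre-detrend) values are shuffled; each repetition is then
    detrended, demeaned and Fourier-transformed with the observed settings.
    Returns ``(frequencies_hz, power)`` with power of shape ``(n_reps, F)``.
    """
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be >= 1")
    if series_raw.detrend_order is not None:
        raise InvalidArgumentError("time shuffling operates on the raw (un-detrended) series")
    if rng is None:
        rng = np.random.default_rng()
    stack = rng.permuted(np.tile(series_raw.accuracy, (n_reps, 1)), axis=1)
    return analyze_raw_series(stack, series_raw.delays_ms, settings)


def surrogate_random_accuracy(
    series_raw: DelaySeries,
    settings: SpectralSettings,
    n_reps: int = 1000,
    rng: Optional[np.random.Generator] = None,
    session_mean_accuracy: Optional[float] = None,
    bernoulli_mean: bool = False,
):
    """Spectra of coin-flip accuracies with the observed trial counts.

    Per repetition and delay, ``n_trials[d]`` fair Bernoulli outcomes are
    drawn and averaged, and the offset ``session_mean_accuracy - 0.5`` is
    added so the surrogate matches the subject's overall performance level
    (default: the trial-weighted mean accuracy of the series).  With
    ``bernoulli_mean=True`` the trials are instead drawn directly at the
    session mean and no offset is added.
    """
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be >= 1")
    if np.any(series_raw.n_trials < 1):
        raise InvalidArgumentError("every delay needs at least one trial")
    if rng is None:
        rng = np.random.default_rng()
    n = series_raw.n_trials
    if session_mean_accuracy is None:
        session_mean_accuracy = float(np.sum(series_raw.accuracy * n) / np.sum(n))
    if not (0.0 <= session_mean_accuracy <= 1.0):
        raise InvalidArgumentError("session_mean_accuracy must be in [0, 1]")
    shape = (n_reps, n.size)
    if bernoulli_mean:
        acc = rng.binomial(n[np.newaxis, :], session_mean_accuracy, size=shape) / n
    else:
        acc = rng.binomial(n[np.newaxis, :], 0.5, size=shape) / n
        acc = acc + (session_mean_accuracy - 0.5)
    return analyze_raw_series(acc, series_raw.delays_ms, settings)


def fit_ar1(series_detrended: DelaySeries, method: str = "cls") -> ARFit:
    """Fit X_t = c + phi*X_{t-1} + eps_t to a detrended series.

    ``method="cls"`` (default) uses closed-form conditional least squares:
    an OLS regression of X_t on X_{t-1} with intercept.  ``method="mle"``
    uses a Gaussian maximum-likelihood ARIMA(1,0,0) fit from statsmodels;
    its mean-form constant is converted to the intercept form above.
    """
    if series_detrended.detrend_order is None:
        raise InvalidArgumentError("fit the AR model to the detrended series")
    x = np.asarray(series_detrended.accuracy, dtype=float)
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 points to fit an AR(1) model")
    if np.ptp(x) < 1e-12:
        raise DegenerateSeriesError("constant series: AR(1) fit is degenerate")
    if method == "cls":
        y, z = x[1:], x[:-1]
        design = np.column_stack([np.ones_like(z), z])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        c, phi = float(coef[0]), float(coef[1])
        resid = y - design @ coef
        dof = max(1, y.size - 2)
        resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    elif method == "mle":
        import warnings

        from statsmodels.tsa.arima.model import ARIMA

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(x, order=(1, 0, 0), trend="c").fit()
        phi = float(res.arparams[0])
        mu = float(res.params[0])  # statsmodels parameterizes the mean
        c = mu * (1.0 - phi)
        resid_sd = float(np.sqrt(res.params[-1]))
    else:
        raise InvalidArgumentError("method must be 'cls' or 'mle'")
    return ARFit(c=c, phi=phi, resid_sd=resid_sd, n_obs=x.size)


def simulate_ar1(
    fit: ARFit,
    series_length: int,
    n_reps: int,
    rng: np.random.Generator,
    burn_in: int = 100,
) -> np.ndarray:
    """Simulate ``n_reps`` stationary AR(1) paths of ``series_length`` samples."""
    if abs(fit.phi) >= 1.0:
        raise NonstationaryModelError(f"|phi| = {abs(fit.phi):.3f} >= 1: process is not stationary")
    if series_length < 1 or n_reps < 1:
        raise InvalidArgumentError("series_length and n_reps must be >= 1")
    mean = fit.c / (1.0 - fit.phi)
    x = np.full(n_reps, mean)
    eps = rng.normal(0.0, fit.resid_sd, size=(burn_in + series_length, n_reps)) if fit.resid_sd > 0 else None
    out = np.empty((n_reps, series_length))
    for t in range(burn_in + series_length):
        innov = eps[t] if eps is not None else 0.0
        x = fit.c + fit.phi * x + innov
        if t >= burn_in:
            out[:, t - burn_in] = x
    return out


def surrogate_ar(
    fit: ARFit,
    delays_ms: np.ndarray,
    settings: SpectralSettings,
    n_reps: int = 1000,
    rng: Optional[np.random.Generator] = None,
    burn_in: int = 100,
):
    """Spectra of simulated AR(1) series matching the fitted autocorrelation.

    Each repetition has the length of the delay grid, discards ``burn_in``
    initial samples, and runs through the observed detrend/taper/pad/FFT
    path.
    """
    if rng is None:
        rng = np.random.default_rng()
    delays = np.asarray(delays_ms, dtype=float)
    stack = simulate_ar1(fit, delays.size, n_reps, rng, burn_in=burn_in)
    return analyze_raw_series(stack, delays, settings)


def reduce_surrogates(
    per_session_power: Mapping[object, np.ndarray],
    frequencies_hz: np.ndarray,
    subject: str,
    method: str,
) -> SurrogateSpectrum:
    """Median over repetitions within each session, then mean over sessions."""
    if not per_session_power:
        raise InvalidArgumentError("no surrogate repetitions to reduce")
    medians = []
    n_reps = None
    for power in per_session_power.values():
        power = np.atleast_2d(np.asarray(power, dtype=float))
        if power.shape[0] < 1:
            raise InvalidArgumentError("no surrogate repetitions to reduce")
        if n_reps is None:
            n_reps = power.shape[0]
        medians.append(np.median(power, axis=0))
    return SurrogateSpectrum(
        subject=subject,
        method=method,
        frequencies_hz=np.asarray(frequencies_hz, dtype=float),
        power=np.mean(medians, axis=0),
        n_reps=int(n_reps),
    )


def compute_surrogate_spectrum(
    subject: str,
    sessions: Mapping[object, DelaySeries],
    method: str,
    settings: SpectralSettings,
    n_reps: int = 1000,
    rng: Optional[np.random.Generator] = None,
    ar_fit_method: str = "cls",
) -> SurrogateSpectrum:
    """One subject's reduced surrogate spectrum for one method.

    ``sessions`` maps session identifiers to *raw* (un-detrended) series.
    """
    if method not in SURROGATE_METHODS:
        raise InvalidArgumentError(f"unknown surrogate method {method!r}")
    if rng is None:
        rng = np.random.default_rng()
    per_session = {}
    freqs = None
    for session, series in sessions.items():
        if method == "time_shuffle":
            freqs, power = surrogate_time_shuffle(series, settings, n_reps, rng)
        elif method == "random_accuracy":
            freqs, power = surrogate_random_accuracy(series, settings, n_reps, rng)
        else:
            fit = fit_ar1(detrend(series, settings.detrend_order), method=ar_fit_method)
            freqs, power = surrogate_ar(fit, series.delays_ms, settings, n_reps, rng)
        per_session[session] = power
    return reduce_surrogates(per_session, freqs, subject, method)
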