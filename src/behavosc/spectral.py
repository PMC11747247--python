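"""Single-taper, zero-padded power spectra of accuracy-by-delay series.

A delay grid sampled every video frame (1/60 s) gives a 60 Hz sampling rate
and a 30 Hz Nyquist frequency.  The raw series (19 samples by default, ~317
ms of data) is far too short for useful spectral resolution, so the tapered
series is zero-padded to 1 s before the FFT, producing a 1 Hz frequency grid
of which the bins 1..29 Hz are retained.

The taper is applied to the data samples *before* zero-padding — padding
zeros are never tapered — as in standard short-window multitaper practice.
The default taper is the first discrete prolate spheroidal sequence (DPSS)
with a half-bandwidth of 3 Hz, i.e. a time-half-bandwidth product of
n/fs * 3; a Hann window and no taper are available as alternatives.  Tapers
are normalized to unit root-mean-square, and power is the plain squared DFT
magnitude: absolute units are irrelevant because every inference in this
package compares observed against surrogate spectra computed with identical
settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import windows

from .errors import InvalidArgumentError
from .preprocess import DelaySeries, detrend_values


@dataclass(frozen=True)
class TaperSpec:
    """Taper family and (for DPSS) spectral half-bandwidth in Hz."""

    kind: str = "dpss_single"
    smoothing_hz: float = 3.0

    def __post_init__(self):
        if self.kind not in ("dpss_single", "hann", "none"):
            raise InvalidArgumentError("taper kind must be 'dpss_single', 'hann' or 'none'")
        if self.kind == "dpss_single" and self.smoothing_hz <= 0:
            raise InvalidArgumentError("smoothing_hz must be > 0 for a DPSS taper")


@dataclass(frozen=True)
class SpectralSettings:
    """The settings shared by the observed pipeline and every surrogate."""

    detrend_order: int = 1
    pad_seconds: float = 1.0
    taper: TaperSpec = field(default_factory=TaperSpec)
    fmin_hz: float = 1.0
    fmax_hz: float = 29.0


@dataclass(frozen=True)
class PowerSpectrum:
    """Power on a fixed frequency grid, with padding/taper metadata."""

    subject: str
    session: object
    frequencies_hz: np.ndarray
    power: np.ndarray
    pad_seconds: float
    taper: TaperSpec

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "power", p)
        if f.shape != p.shape or f.ndim != 1:
            raise InvalidArgumentError("frequencies and power must be 1-D and equal length")
        if np.any(p < 0):
            raise InvalidArgumentError("power must be nonnegative")


def make_taper(n_samples: int, sample_rate_hz: float, spec: TaperSpec) -> np.ndarray:
    """Length-``n_samples`` nonnegative window, normalized to unit RMS."""
    if n_samples < 2:
        raise InvalidArgumentError("need at least 2 samples")
    if spec.kind == "none":
        return np.ones(n_samples)
    if spec.kind == "hann":
        w = windows.hann(n_samples, sym=True)
    else:
        nw = n_samples / sample_rate_hz * spec.smoothing_hz
        if nw <= 0:
            raise InvalidArgumentError("DPSS time-half-bandwidth product must be > 0")
        w = windows.dpss(n_samples, nw, Kmax=1)[0]
        w = np.abs(w)  # first Slepian sequence is one-signed; fix scipy's sign convention
    rms = float(np.sqrt(np.mean(w**2)))
    if rms == 0:
        raise InvalidArgumentError("degenerate taper (all zeros); use more samples")
    return w / rms


def _uniform_spacing(delays_ms: np.ndarray) -> float:
    d = np.diff(np.asarray(delays_ms, dtype=float))
    if d.size == 0:
        raise InvalidArgumentError("need at least 2 delays")
    if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
        raise InvalidArgumentError("delays must be strictly increasing and evenly spaced")
    return float(d[0])


def power_from_values(
    values: np.ndarray,
    delays_ms: np.ndarray,
    pad_seconds: float = 1.0,
    taper: TaperSpec = TaperSpec(),
    fmin_hz: float = 1.0,
    fmax_hz: float = 29.0,
):
    """Taper, zero-pad and Fourier-transform one series (or a stack of series).

    ``values`` may be 1-D (one series) or 2-D with series along the last
    axis, in which case all series share the delay grid and settings — this
    is the vectorized path the surrogate ensembles use.  Returns
    ``(frequencies_hz, power)``.
    """
    values = np.asarray(values, dtype=float)
    delays = np.asarray(delays_ms, dtype=float)
    dt_ms = _uniform_spacing(delays)
    fs = 1000.0 / dt_ms
    n = delays.size
    if values.shape[-1] != n:
        raise InvalidArgumentError("values and delays have mismatched lengths")
    n_pad = int(round(pad_seconds * fs))
    if n_pad < n:
        raise InvalidArgumentError("pad_seconds must cover the duration of the series")
    w = make_taper(n, fs, taper)
    spec = np.fft.rfft(values * w, n=n_pad, axis=-1)
    power = np.abs(spec) ** 2
    # bin k sits at exactly k / pad_seconds Hz; avoid float drift from fs
    freqs = np.arange(n_pad // 2 + 1) / (n_pad / fs)
    if abs(pad_seconds * fs - n_pad) < 1e-9:
        freqs = np.arange(n_pad // 2 + 1) / pad_seconds
    mask = (freqs >= fmin_hz - 1e-9) & (freqs <= fmax_hz + 1e-9)
    return freqs[mask], power[..., mask]


def analyze_raw_series(values: np.ndarray, delays_ms: np.ndarray, settings: SpectralSettings):
    """Detrend/demean then compute the power spectrum — the single shared path.

    Every spectrum in this package, observed or surrogate, goes through this
    function with identical settings, so that inference compares like with
    like.  Accepts 2-D stacks of series for surrogate ensembles.
    """
    resid = detrend_values(values, delays_ms, settings.detrend_order)
    return power_from_values(
        resid,
        delays_ms,
        pad_seconds=settings.pad_seconds,
        taper=settings.taper,
        fmin_hz=settings.fmin_hz,
        fmax_hz=settings.fmax_hz,
    )


def compute_power_spectrum(
    series: DelaySeries,
    pad_seconds: float = 1.0,
    taper: TaperSpec = TaperSpec(),
    fmin_hz: float = 1.0,
    fmax_hz: float = 29.0,
) -> PowerSpectrum:
    """Power spectrum of one (already detrended) series."""
    freqs, power = power_from_values(
        series.accuracy, series.delays_ms, pad_seconds, taper, fmin_hz, fmax_hz
    )
    return PowerSpectrum(
        subject=series.subject,
        session=series.session,
        frequencies_hz=freqs,
        power=power,
        pad_seconds=pad_seconds,
        taper=taper,
    )


def average_spectra(spectra: Sequence[PowerSpectrum], over: str = "sessions") -> PowerSpectrum:
    """Element-wise mean of spectra sharing a frequency grid.

    ``over="sessions"`` averages one subject's session spectra (all inputs
    must share the subject); ``over="subjects"`` averages across subjects
    into a group spectrum.  The canonical order is sessions within subject
    first, then subjects.
    """
    if not spectra:
        raise InvalidArgumentError("no spectra to average")
    if over not in ("sessions", "subjects"):
        raise InvalidArgumentError("over must be 'sessions' or 'subjects'")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.frequencies_hz.shape != ref.frequencies_hz.shape or not np.allclose(
            s.frequencies_hz, ref.frequencies_hz
        ):
            raise InvalidArgumentError("frequency grids do not match")
    if over == "sessions":
        subjects = {s.subject for s in spectra}
        if len(subjects) != 1:
            raise InvalidArgumentError("session averaging requires a single subject")
        subject, session = ref.subject, "mean"
    else:
        subject, session = "group", "mean"
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(
        subject=subject,
        session=session,
        frequencies_hz=ref.frequencies_hz.copy(),
        power=power,
        pad_seconds=ref.pad_seconds,
        taper=ref.taper,
    )
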