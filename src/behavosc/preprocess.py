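"""Accuracy-by-delay series: aggregation from trials and polynomial detrending.

The unit of analysis downstream is one :class:`DelaySeries` per subject and
session: the fraction of correct threshold-SOA trials at each subliminal-
target delay.  Sessions are never pooled at the trial level — spectra are
averaged across sessions later, after the FFT.

Detrending removes an ordinary-least-squares polynomial (order 1 by default;
order 2 as a control against low-frequency artefacts of the short window)
and thereby also demeans the series.  Fits are performed on a delay axis
rescaled to [-1, 1]; because OLS residuals are invariant to invertible
reparameterizations of the design, the residuals are identical to fitting on
raw milliseconds while the normal equations stay well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from .errors import InvalidArgumentError, MissingDelayError
from .synthetic import TrialRecord


@dataclass(frozen=True)
class DelaySeries:
    """Accuracy as an ordered function of subliminal-target delay.

    ``detrend_order`` is ``None`` for raw accuracies and 1 or 2 once the
    series holds detrended residuals (which are then zero-mean and no longer
    confined to [0, 1]).
    """

    subject: str
    session: int
    delays_ms: np.ndarray
    accuracy: np.ndarray
    n_trials: np.ndarray
    detrend_order: Optional[int] = None

    def __post_init__(self):
        delays = np.asarray(self.delays_ms, dtype=float)
        acc = np.asarray(self.accuracy, dtype=float)
        n = np.asarray(self.n_trials, dtype=int)
        object.__setattr__(self, "delays_ms", delays)
        object.__setattr__(self, "accuracy", acc)
        object.__setattr__(self, "n_trials", n)
        if not (delays.shape == acc.shape == n.shape) or delays.ndim != 1:
            raise InvalidArgumentError("delays, accuracy and n_trials must be 1-D and equal length")
        if delays.size >= 2:
            d = np.diff(delays)
            if np.any(d <= 0):
                raise InvalidArgumentError("delays must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
                raise InvalidArgumentError("delays must be evenly spaced")
        if self.detrend_order is None and (np.any(acc < 0) or np.any(acc > 1)):
            raise InvalidArgumentError("raw accuracies must lie in [0, 1]")
        if self.detrend_order not in (None, 1, 2):
            raise InvalidArgumentError("detrend_order must be None, 1 or 2")

    @property
    def spacing_ms(self) -> float:
        if self.delays_ms.size < 2:
            raise InvalidArgumentError("spacing undefined for a single delay")
        return float(self.delays_ms[1] - self.delays_ms[0])

    @property
    def sample_rate_hz(self) -> float:
        return 1000.0 / self.spacing_ms


def aggregate_accuracy(
    trials: Iterable[TrialRecord],
    subject: str,
    session: int,
    delay_grid_ms: Optional[np.ndarray] = None,
) -> DelaySeries:
    """Fraction correct of threshold-SOA trials per delay for one subject/session.

    Control-SOA and catch trials are excluded.  If ``delay_grid_ms`` is
    given, every grid delay must carry at least one trial; otherwise the
    grid is the sorted set of observed delays.
    """
    counts: dict[float, list[int]] = {}
    for t in trials:
        if t.subject != subject or t.session != session or t.soa_condition != "threshold":
            continue
        c = counts.setdefault(float(t.delay_ms), [0, 0])
        c[0] += int(t.correct)
        c[1] += 1
    if delay_grid_ms is None:
        if not counts:
            raise InvalidArgumentError(f"no threshold-SOA trials for subject={subject}, session={session}")
        grid = np.array(sorted(counts))
    else:
        grid = np.asarray(delay_grid_ms, dtype=float)
    acc = np.empty(grid.size)
    n = np.empty(grid.size, dtype=int)
    for i, d in enumerate(grid):
        if float(d) not in counts:
            raise MissingDelayError(float(d), subject, session)
        k, m = counts[float(d)]
        acc[i] = k / m
        n[i] = m
    return DelaySeries(subject=subject, session=session, delays_ms=grid, accuracy=acc, n_trials=n)


def polynomial_residual_projection(delays_ms: np.ndarray, order: int) -> np.ndarray:
    """Projection matrix onto the orthogonal complement of polynomials of ``order``.

    Built from a QR decomposition of the Vandermonde basis on the delay axis
    rescaled to [-1, 1].  Applying it to a series returns the OLS residuals
    of a polynomial fit of that order (which include demeaning).
    """
    delays = np.asarray(delays_ms, dtype=float)
    if order < 1:
        raise InvalidArgumentError("order must be >= 1")
    if delays.size < order + 2:
        raise InvalidArgumentError(f"need at least {order + 2} points for order-{order} detrending")
    lo, hi = delays.min(), delays.max()
    x = (2.0 * delays - (lo + hi)) / (hi - lo)
    v = np.polynomial.polynomial.polyvander(x, order)
    q, _ = np.linalg.qr(v)
    return np.eye(delays.size) - q @ q.T


def detrend_values(values: np.ndarray, delays_ms: np.ndarray, order: int) -> np.ndarray:
    """OLS polynomial residuals of ``values`` (last axis = delay); supports 2-D stacks."""
    r = polynomial_residual_projection(delays_ms, order)
    return np.asarray(values, dtype=float) @ r.T


def detrend(series: DelaySeries, order: int = 1) -> DelaySeries:
    """Detrend (and thereby demean) a raw series with a polynomial of ``order`` 1 or 2."""
    if order not in (1, 2):
        raise InvalidArgumentError("detrend order must be 1 or 2")
    if series.detrend_order is not None:
        raise InvalidArgumentError("series is already detrended")
    resid = detrend_values(series.accuracy, series.delays_ms, order)
    return replace(series, accuracy=resid, detrend_order=order)
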