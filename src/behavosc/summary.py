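"""Descriptive control summaries: accuracy by SOA condition and catch-trial rates.

These tables mirror the control analyses a dense-sampling study reports
alongside the spectral analysis: group-level accuracy per SOA condition and
session (pooled across delays), and per-subject "seen" rates for real and
fake catch trials.  No inferential statistics are computed here; the tables
are the inputs one would hand to any standard ANOVA routine.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .synthetic import CATCH_CONDITIONS, SOA_CONDITIONS, TrialRecord


def _trials_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        (t.subject, t.session, t.soa_condition, t.correct, t.reported_seen) for t in trials
    ]
    return pd.DataFrame(rows, columns=["subject", "session", "soa_condition", "correct", "reported_seen"])


def accuracy_by_condition(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Group mean and SEM of subject-level accuracy per session and SOA condition.

    Accuracy is first computed per subject within each session and condition
    (pooled across delays), then averaged across subjects.  The SEM uses the
    ddof=1 sample standard deviation; with a single subject it is reported
    as 0.  Conditions with no trials are omitted with a warning.
    """
    df = _trials_frame(trials)
    df = df[~df.soa_condition.isin(CATCH_CONDITIONS)]
    if df.empty:
        raise InvalidArgumentError("no task trials to summarize")
    per_subject = (
        df.groupby(["session", "soa_condition", "subject"], sort=True)["correct"]
        .mean()
        .reset_index(name="accuracy")
    )
    rows = []
    for (session, cond), grp in per_subject.groupby(["session", "soa_condition"], sort=True):
        acc = grp["accuracy"].to_numpy(dtype=float)
        sem = float(acc.std(ddof=1) / np.sqrt(acc.size)) if acc.size > 1 else 0.0
        rows.append((session, cond, float(acc.mean()), sem, int(acc.size)))
    missing = set(SOA_CONDITIONS) - {r[1] for r in rows}
    if missing:
        warnings.warn(f"conditions absent from the trials and omitted: {sorted(missing)}")
    out = pd.DataFrame(rows, columns=["session", "soa_condition", "mean_accuracy", "sem", "n"])
    order = {c: i for i, c in enumerate(SOA_CONDITIONS)}
    return (
        out.sort_values(["session", "soa_condition"], key=lambda s: s.map(order) if s.name == "soa_condition" else s)
        .reset_index(drop=True)
    )


def catch_rates(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Fraction of "seen" reports per subject, session and catch type."""
    df = _trials_frame(trials)
    df = df[df.soa_condition.isin(CATCH_CONDITIONS)]
    if df.empty:
        raise InvalidArgumentError("no catch trials present")
    out = (
        df.groupby(["subject", "session", "soa_condition"], sort=True)["reported_seen"]
        .mean()
        .reset_index(name="seen_rate")
        .rename(columns={"soa_condition": "catch_type"})
    )
    out["catch_type"] = out["catch_type"].str.removeprefix("catch_")
    return out
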