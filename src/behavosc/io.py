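"""File formats, run configuration and the end-to-end pipeline driver.

The pipeline composes the stages in the order the analysis runs: aggregate
trial records into accuracy-by-delay series, detrend, compute the observed
spectra, build each requested surrogate null, and test observed against
surrogate power with the cluster permutation procedure.  All randomness
flows from a single master seed split into named child streams (experiment
generation, one per surrogate method, permutations), so each stage is
independently reproducible.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .cluster import ClusterTest, TestConfig, cluster_permutation_test
from .errors import InvalidArgumentError, SchemaError, TrialParseError
from .preprocess import DelaySeries, aggregate_accuracy
from .spectral import PowerSpectrum, SpectralSettings, TaperSpec, analyze_raw_series
from .summary import accuracy_by_condition, catch_rates
from .surrogates import SURROGATE_METHODS, compute_surrogate_spectrum
from .synthetic import (
    ExperimentConfig,
    OscillationComponent,
    TrialRecord,
    generate_experiment,
    make_observers,
)

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "subject",
    "session",
    "trial_index",
    "delay_ms",
    "soa_condition",
    "soa_ms",
    "correct",
    "reported_seen",
]

#: fixed order of the named child streams spawned from the master seed
SEED_STREAMS = ("generator", "time_shuffle", "random_accuracy", "ar_model", "permutations")


def seed_streams(master_seed: int) -> dict[str, np.random.Generator]:
    """Split a master seed into independently reproducible named streams."""
    children = np.random.SeedSequence(master_seed).spawn(len(SEED_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(SEED_STREAMS, children)}


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------


def _fmt_opt(value, bool_field: bool = False) -> str:
    if value is None:
        return ""
    if bool_field:
        return "1" if value else "0"
    return repr(float(value))


def write_trials(trials: Iterable[TrialRecord], path) -> None:
    """Write trial records as CSV with the canonical column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for t in trials:
            writer.writerow(
                [
                    t.subject,
                    t.session,
                    t.trial_index,
                    _fmt_opt(t.delay_ms),
                    t.soa_condition,
                    _fmt_opt(t.soa_ms),
                    _fmt_opt(t.correct, bool_field=True),
                    _fmt_opt(t.reported_seen, bool_field=True),
                ]
            )


def _parse_bool(text: str, column: str) -> Optional[bool]:
    if text == "":
        return None
    if text in ("0", "1"):
        return bool(int(text))
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    raise ValueError(f"{column} must be 0/1 or true/false, got {text!r}")


def _parse_float(text: str, column: str) -> Optional[float]:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"non-numeric {column}: {text!r}") from None


def read_trials(path) -> list[TrialRecord]:
    """Read and validate a trial-table CSV; malformed rows name their line."""
    trials = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: missing header") from None
        if header != TRIAL_COLUMNS:
            missing = set(TRIAL_COLUMNS) - set(header)
            raise SchemaError(
                f"unexpected header {header}; missing columns: {sorted(missing)}"
                if missing
                else f"unexpected column order {header}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TRIAL_COLUMNS):
                raise TrialParseError(line_no, f"expected {len(TRIAL_COLUMNS)} fields, got {len(row)}")
            try:
                trials.append(
                    TrialRecord(
                        subject=row[0],
                        session=int(row[1]),
                        trial_index=int(row[2]),
                        delay_ms=_parse_float(row[3], "delay_ms"),
                        soa_condition=row[4],
                        soa_ms=_parse_float(row[5], "soa_ms"),
                        correct=_parse_bool(row[6], "correct"),
                        reported_seen=_parse_bool(row[7], "reported_seen"),
                    )
                )
            except (ValueError, InvalidArgumentError) as exc:
                raise TrialParseError(line_no, str(exc)) from None
    return trials


def write_delay_series(series: Iterable[DelaySeries], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "session", "delay_ms", "accuracy", "n_trials"])
        for s in series:
            for d, a, n in zip(s.delays_ms, s.accuracy, s.n_trials):
                writer.writerow([s.subject, s.session, repr(float(d)), repr(float(a)), int(n)])


def write_spectra(spectra: Iterable[PowerSpectrum], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "session", "frequency_hz", "power"])
        for s in spectra:
            for f, p in zip(s.frequencies_hz, s.power):
                writer.writerow([s.subject, s.session, repr(float(f)), repr(float(p))])


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; serializable to/from YAML or JSON."""

    experiment: Optional[ExperimentConfig] = None
    input_path: Optional[str] = None
    spectral: SpectralSettings = field(default_factory=SpectralSettings)
    surrogate_methods: tuple = SURROGATE_METHODS
    n_surrogate_reps: int = 1000
    test: TestConfig = field(default_factory=TestConfig)
    ar_fit_method: str = "cls"
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.experiment is None and self.input_path is None:
            raise InvalidArgumentError("provide either an experiment config or an input path")
        for m in self.surrogate_methods:
            if m not in SURROGATE_METHODS:
                raise InvalidArgumentError(f"unknown surrogate method {m!r}")
        if self.n_surrogate_reps < 1:
            raise InvalidArgumentError("n_surrogate_reps must be >= 1")


def _config_to_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return [float(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(config)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON document mirroring the field names."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError("config document must be a mapping")
    exp = None
    if raw.get("experiment") is not None:
        e = dict(raw["experiment"])
        comps = tuple(OscillationComponent(**c) for c in e.pop("components", []))
        if "delay_grid_ms" in e and e["delay_grid_ms"] is not None:
            e["delay_grid_ms"] = tuple(float(v) for v in e["delay_grid_ms"])
        exp = ExperimentConfig(components=comps, **e)
    spectral_raw = dict(raw.get("spectral", {}))
    taper = TaperSpec(**spectral_raw.pop("taper")) if "taper" in spectral_raw else TaperSpec()
    spectral = SpectralSettings(taper=taper, **spectral_raw)
    test = TestConfig(**raw.get("test", {}))
    return RunConfig(
        experiment=exp,
        input_path=raw.get("input_path"),
        spectral=spectral,
        surrogate_methods=tuple(raw.get("surrogate_methods", SURROGATE_METHODS)),
        n_surrogate_reps=int(raw.get("n_surrogate_reps", 1000)),
        test=test,
        ar_fit_method=raw.get("ar_fit_method", "cls"),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir"),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, in memory."""

    trials: Optional[list[TrialRecord]]
    series: dict  # (subject, session) -> raw DelaySeries
    frequencies_hz: np.ndarray
    observed: np.ndarray  # (n_subjects, F) session-averaged observed power
    subjects: list[str]
    surrogates: dict  # method -> (n_subjects, F) reduced surrogate power
    tests: dict  # method -> ClusterTest
    manifest: dict


def analyze_series(
    series_by_key: dict,
    settings: SpectralSettings,
    methods: Sequence[str],
    n_reps: int,
    test_config: TestConfig,
    rngs: dict,
    ar_fit_method: str = "cls",
):
    """Observed spectra, surrogate reductions and cluster tests from raw series.

    ``series_by_key`` maps ``(subject, session)`` to raw :class:`DelaySeries`.
    Returns ``(frequencies, subjects, observed_matrix, surrogate_matrices,
    tests)``; the observed matrix holds session-averaged power per subject.
    """
    subjects = sorted({k[0] for k in series_by_key})
    sessions_of = {
        s: {k[1]: v for k, v in series_by_key.items() if k[0] == s} for s in subjects
    }
    freqs = None
    observed_rows = []
    for s in subjects:
        powers = []
        for session in sorted(sessions_of[s]):
            series = sessions_of[s][session]
            freqs, power = analyze_raw_series(series.accuracy, series.delays_ms, settings)
            powers.append(power)
        observed_rows.append(np.mean(powers, axis=0))
    observed = np.vstack(observed_rows)
    logger.info("observed spectra: %d subjects x %d frequencies", observed.shape[0], observed.shape[1])

    surrogate_matrices = {}
    tests = {}
    for method in methods:
        rng = rngs[method]
        rows = []
        for s in subjects:
            spec = compute_surrogate_spectrum(
                s, dict(sorted(sessions_of[s].items())), method, settings,
                n_reps=n_reps, rng=rng, ar_fit_method=ar_fit_method,
            )
            rows.append(spec.power)
        surrogate_matrices[method] = np.vstack(rows)
        tests[method] = cluster_permutation_test(
            observed, surrogate_matrices[method], freqs, test_config, rngs["permutations"]
        )
        logger.info(
            "%s: %d clusters (%d with p < 0.05)",
            method,
            len(tests[method].clusters),
            len(tests[method].significant),
        )
    return freqs, subjects, observed, surrogate_matrices, tests


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write the result bundle."""
    rngs = seed_streams(config.seed)
    if config.input_path is not None:
        logger.info("stage read_trials: %s", config.input_path)
        trials = read_trials(config.input_path)
        grid = None
    else:
        exp = dataclasses.replace(
            config.experiment,
            seed=int(rngs["generator"].integers(0, 2**31 - 1)),
        )
        observers = make_observers(exp.n_subjects, rngs["generator"])
        trials = generate_experiment(exp, observers)
        grid = exp.delays
    logger.info("stage aggregate: %d trials", len(trials))

    keys = sorted({(t.subject, t.session) for t in trials if t.soa_condition == "threshold"})
    series_by_key = {
        (s, sess): aggregate_accuracy(trials, s, sess, delay_grid_ms=grid) for s, sess in keys
    }
    freqs, subjects, observed, surrogate_matrices, tests = analyze_series(
        series_by_key,
        config.spectral,
        config.surrogate_methods,
        config.n_surrogate_reps,
        config.test,
        rngs,
        ar_fit_method=config.ar_fit_method,
    )

    manifest = {
        "package": "behavosc",
        "version": __version__,
        "seed": config.seed,
        "seed_streams": list(SEED_STREAMS),
        "config": _config_to_dict(config),
        "config_hash": config_hash(config),
        "n_trials": len(trials),
        "n_subjects": len(subjects),
        "n_series": len(series_by_key),
        "frequencies_hz": [float(f) for f in freqs],
        "clusters": {
            method: [dataclasses.asdict(c) for c in test.clusters]
            for method, test in tests.items()
        },
    }

    result = PipelineResult(
        trials=trials,
        series=series_by_key,
        frequencies_hz=freqs,
        observed=observed,
        subjects=subjects,
        surrogates=surrogate_matrices,
        tests=tests,
        manifest=manifest,
    )
    if config.output_dir is not None:
        _write_bundle(result, config)
    return result


def _write_bundle(result: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trials(result.trials, outdir / "trials.csv")
    write_delay_series(result.series.values(), outdir / "delay_series.csv")
    with open(outdir / "observed_spectra.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "frequency_hz", "power"])
        for i, s in enumerate(result.subjects):
            for f, p in zip(result.frequencies_hz, result.observed[i]):
                writer.writerow([s, repr(float(f)), repr(float(p))])
    with open(outdir / "surrogate_spectra.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "method", "frequency_hz", "power"])
        for method, mat in result.surrogates.items():
            for i, s in enumerate(result.subjects):
                for f, p in zip(result.frequencies_hz, mat[i]):
                    writer.writerow([s, method, repr(float(f)), repr(float(p))])
    clusters = {
        method: [dataclasses.asdict(c) for c in test.clusters]
        for method, test in result.tests.items()
    }
    (outdir / "clusters.json").write_text(json.dumps(clusters, indent=2) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    try:
        accuracy_by_condition(result.trials).to_csv(outdir / "condition_summary.csv", index=False)
        catch_rates(result.trials).to_csv(outdir / "catch_rates.csv", index=False)
    except InvalidArgumentError:
        logger.info("summaries skipped: no applicable trials")
    logger.info("result bundle written to %s", outdir)
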