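"""Observer models, staircases and experiment generation."""

import numpy as np
import pytest

from behavosc import (
    ExperimentConfig,
    FRAME_MS,
    InvalidArgumentError,
    ObserverModel,
    OscillationComponent,
    accuracy_profile,
    default_delay_grid,
    generate_experiment,
    run_contrast_staircase,
    run_soa_staircase,
    simulate_delay_series,
    simulate_detection,
    symmetric_contrast,
    weber_contrast,
)
from behavosc.synthetic import subliminal_contrast


class AlwaysNo(ObserverModel):
    def p_seen(self, contrast):
        return 0.0


class AlwaysYes(ObserverModel):
    def p_seen(self, contrast):
        return 1.0


class DeterministicSOA(ObserverModel):
    """Correct iff the SOA is at most the cutoff."""

    def p_correct(self, soa_ms):
        return 1.0 if soa_ms <= self.soa_threshold_ms else 0.0


class TestContrastConventions:
    def test_grey_step_is_2_6_percent_weber(self):
        assert round(100 * weber_contrast(0.39), 1) == 2.6

    def test_published_grey_values_match_symmetric_convention(self):
        # 0.47 -> ~21.2 % and 0.57 -> ~40 % only under 2(L-Lb)/(L+Lb)
        assert round(100 * symmetric_contrast(0.47), 1) == 21.2
        assert round(100 * symmetric_contrast(0.57), 1) == 40.0


class TestDetection:
    def test_midpoint_probability_is_half_without_lapses(self):
        obs = ObserverModel(contrast_threshold=0.13, lapse_rate=0.0)
        assert obs.p_seen(0.13) == pytest.approx(0.5)

    def test_step_function_limit_sees_with_one_minus_lapse(self):
        obs = ObserverModel(contrast_threshold=0.13, contrast_slope=np.inf, lapse_rate=0.05)
        assert obs.p_seen(0.4) == pytest.approx(0.95)
        assert obs.p_seen(0.01) == 0.0

    def test_negative_contrast_rejected(self):
        obs = ObserverModel()
        with pytest.raises(InvalidArgumentError):
            simulate_detection(obs, -0.1, np.random.default_rng(0))

    def test_monte_carlo_rate_matches_closed_form(self):
        obs = ObserverModel(contrast_threshold=0.13, contrast_slope=40.0, lapse_rate=0.02)
        contrast = 0.15
        p = obs.p_seen(contrast)
        rng = np.random.default_rng(11)
        n = 100_000
        hits = sum(simulate_detection(obs, contrast, rng) for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_psychometric_monotonicity(self):
        obs = ObserverModel()
        contrasts = np.linspace(0, 0.4, 30)
        seen = [obs.p_seen(c) for c in contrasts]
        assert np.all(np.diff(seen) >= 0)
        soas = np.linspace(0, 150, 30)
        correct = [obs.p_correct(s) for s in soas]
        assert np.all(np.diff(correct) <= 0)


class TestContrastStaircase:
    def test_always_no_terminates_after_exactly_20_evaluated_trials(self):
        rng = np.random.default_rng(0)
        result = run_contrast_staircase(AlwaysNo(), rng, sham_rate=0.0)
        assert result.terminated
        evaluated = [t for t in result.trial_log if t.evaluated]
        assert len(evaluated) == 20
        # one increment applied at trial 10: levels 1..10 at 0.47, 11..20 at 0.48
        levels = [t.level for t in evaluated]
        assert levels[:10] == pytest.approx([0.47] * 10)
        assert levels[10:] == pytest.approx([0.48] * 10)
        assert result.terminal_level == pytest.approx(0.48)

    def test_always_yes_floors_at_background_and_never_terminates(self):
        rng = np.random.default_rng(1)
        result = run_contrast_staircase(AlwaysYes(), rng, max_trials=200, sham_rate=0.0)
        assert not result.terminated
        levels = result.evaluated_levels
        assert np.all(np.diff(levels) <= 1e-12)  # monotone non-increasing
        assert levels.min() == pytest.approx(0.38)
        assert result.terminal_level == pytest.approx(0.38)

    def test_logistic_observer_converges_near_threshold(self):
        thr_grey = 0.43
        obs = ObserverModel(contrast_threshold=weber_contrast(thr_grey))
        rng = np.random.default_rng(2)
        terminals = []
        for _ in range(500):
            r = run_contrast_staircase(obs, rng)
            if r.terminated:
                terminals.append(r.terminal_level)
        assert len(terminals) > 250
        assert abs(np.median(terminals) - thr_grey) <= 0.02 + 1e-12

    def test_sham_trials_logged_but_never_evaluated(self):
        rng = np.random.default_rng(3)
        result = run_contrast_staircase(AlwaysNo(), rng, sham_rate=0.5)
        evaluated = [t for t in result.trial_log if t.evaluated]
        shams = [t for t in result.trial_log if not t.evaluated]
        assert len(evaluated) == 20  # shams do not feed the streak rule
        assert shams, "expected interleaved sham trials at 50% rate"

    def test_evaluated_levels_change_by_one_step_at_most(self):
        obs = ObserverModel(contrast_threshold=weber_contrast(0.43))
        rng = np.random.default_rng(4)
        for _ in range(20):
            r = run_contrast_staircase(obs, rng)
            diffs = np.diff(r.evaluated_levels)
            assert np.all(np.isclose(np.abs(diffs), 0.01) | np.isclose(diffs, 0.0))


class TestSOAStaircase:
    def test_deterministic_observer_cycles_forever(self):
        obs = DeterministicSOA(soa_threshold_ms=30.0)  # correct at 26 ms, wrong one step up
        rng = np.random.default_rng(0)
        result = run_soa_staircase(obs, rng, max_trials=300, sham_rate=0.0)
        assert not result.terminated
        levels = result.evaluated_levels
        assert set(np.round(levels, 6)) == {26.0, round(26.0 + FRAME_MS, 6)}

    def test_perfect_observer_diverges_monotonically(self):
        obs = DeterministicSOA(soa_threshold_ms=np.inf)
        rng = np.random.default_rng(1)
        result = run_soa_staircase(obs, rng, max_trials=100, sham_rate=0.0)
        assert not result.terminated
        levels = result.evaluated_levels
        assert np.all(np.diff(levels) >= 0)
        assert levels[-1] > 26.0 + 40 * FRAME_MS * 0.9  # ~one step per two trials

    def test_logistic_observer_hovers_near_target_level(self):
        obs = ObserverModel(soa_threshold_ms=50.0)
        rng = np.random.default_rng(2)
        finals, terminals = [], []
        for _ in range(200):
            r = run_soa_staircase(obs, rng, max_trials=2000)
            finals.append(r.terminal_level)
            if r.terminated:
                terminals.append(r.terminal_level)
        # among terminated runs (if any) and at max_trials the staircase sits
        # within two steps of the ~50%-accuracy level
        for values in (terminals, finals):
            if values:
                assert abs(np.median(values) - 50.0) <= 2 * FRAME_MS

    def test_frames_variance_units_allow_termination(self):
        obs = ObserverModel(soa_threshold_ms=50.0)
        rng = np.random.default_rng(3)
        results = [
            run_soa_staircase(obs, rng, max_trials=2000, variance_units="frames")
            for _ in range(50)
        ]
        frac = np.mean([r.terminated for r in results])
        assert frac > 0.8
        terms = [r.terminal_level for r in results if r.terminated]
        assert abs(np.median(terms) - 50.0) <= 2 * FRAME_MS

    def test_soa_floor_at_zero(self):
        class NeverCorrect(ObserverModel):
            def p_correct(self, soa_ms):
                return 0.0

        obs = NeverCorrect()
        rng = np.random.default_rng(4)
        result = run_soa_staircase(obs, rng, start_soa_ms=10.0, max_trials=100, sham_rate=0.0)
        assert result.evaluated_levels.min() >= 0.0


class TestAccuracyProfile:
    def test_flat_null_profile(self):
        cfg = ExperimentConfig()
        p, clamped = accuracy_profile(cfg)
        assert np.allclose(p, 0.5)
        assert clamped == 0

    def test_cosine_component_modulates_at_its_frequency(self):
        comp = OscillationComponent(frequency_hz=11.0, amplitude=0.15, phase_rad=0.3)
        cfg = ExperimentConfig(base_accuracy=0.55, components=(comp,))
        p, _ = accuracy_profile(cfg)
        t = cfg.delays / 1000.0
        expected = 0.55 + 0.15 * np.cos(2 * np.pi * 11.0 * t + 0.3)
        assert np.allclose(p, expected)

    def test_clamping_counts_out_of_range_delays(self):
        comp = OscillationComponent(frequency_hz=2.0, amplitude=0.5)
        cfg = ExperimentConfig(base_accuracy=0.9, components=(comp,))
        p, clamped = accuracy_profile(cfg)
        assert clamped > 0
        assert np.all((p >= 0) & (p <= 1))


class TestGenerateExperiment:
    def test_null_generator_accuracy_near_half(self):
        cfg = ExperimentConfig(
            n_subjects=2, n_sessions=1, trials_per_delay=400,
            control_trials_per_delay=0, catch_rate=0.0, seed=5,
        )
        observers = [ObserverModel() for _ in range(2)]
        trials = generate_experiment(cfg, observers)
        correct = np.array([t.correct for t in trials if t.soa_condition == "threshold"])
        se = np.sqrt(0.25 / correct.size)
        assert abs(correct.mean() - 0.5) < 3 * se

    def test_injected_cosine_recovered_in_per_delay_accuracy(self):
        comp = OscillationComponent(frequency_hz=11.0, amplitude=0.15)
        cfg = ExperimentConfig(
            n_subjects=1, n_sessions=1, base_accuracy=0.55, components=(comp,),
            trials_per_delay=200, control_trials_per_delay=0, catch_rate=0.0, seed=6,
        )
        trials = generate_experiment(cfg, [ObserverModel()])
        delays = cfg.delays
        acc = np.array([
            np.mean([t.correct for t in trials if t.soa_condition == "threshold" and t.delay_ms == d])
            for d in delays
        ])
        cosine = np.cos(2 * np.pi * 11.0 * delays / 1000.0)
        r = np.corrcoef(acc, cosine)[0, 1]
        assert r > 0.8

    def test_catch_fraction_and_real_fake_split(self):
        cfg = ExperimentConfig(
            n_subjects=4, n_sessions=2, trials_per_delay=180,
            control_trials_per_delay=0, catch_rate=0.1, seed=7,
        )
        observers = [ObserverModel() for _ in range(4)]
        trials = generate_experiment(cfg, observers)
        n = len(trials)
        assert n > 20_000
        n_catch = sum(t.soa_condition.startswith("catch") for t in trials)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(n_catch / n - 0.1) < 3 * se
        n_real = sum(t.soa_condition == "catch_real" for t in trials)
        se_split = np.sqrt(0.25 / n_catch)
        assert abs(n_real / n_catch - 0.5) < 3 * se_split

    def test_exact_per_delay_threshold_counts(self, small_config, small_trials):
        for d in small_config.delays:
            count = sum(
                1 for t in small_trials
                if t.soa_condition == "threshold" and t.delay_ms == d and t.subject == "s1"
                and t.session == 1
            )
            assert count == small_config.trials_per_delay

    def test_identical_seeds_give_identical_records(self, small_config, small_observers):
        a = generate_experiment(small_config, small_observers)
        b = generate_experiment(small_config, small_observers)
        assert a == b

    def test_soa_values_consistent_with_conditions(self, small_trials):
        by_cond = {}
        for t in small_trials:
            if t.soa_condition.startswith("catch"):
                assert t.soa_ms is None and t.delay_ms is None
                continue
            by_cond.setdefault((t.subject, t.session, t.soa_condition), set()).add(t.soa_ms)
        for (subj, sess, cond), soas in by_cond.items():
            assert len(soas) == 1
            thr = next(iter(by_cond[(subj, sess, "threshold")]))
            soa = next(iter(soas))
            expected = {
                "short": 0.0,
                "intermediate_minus": max(0.0, thr - FRAME_MS),
                "threshold": thr,
                "intermediate_plus": thr + FRAME_MS,
                "long": thr + 48.0,
            }[cond]
            assert soa == pytest.approx(expected)

    def test_observer_count_mismatch_rejected(self, small_config):
        with pytest.raises(InvalidArgumentError):
            generate_experiment(small_config, [ObserverModel()])

    def test_empty_delay_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ExperimentConfig(delay_grid_ms=())


class TestSimulateDelaySeries:
    def test_matches_trial_level_distribution(self):
        """The fast binomial path has the same per-delay mean as aggregation."""
        comp = OscillationComponent(frequency_hz=8.0, amplitude=0.1)
        cfg = ExperimentConfig(
            n_subjects=30, n_sessions=2, base_accuracy=0.55, components=(comp,),
            trials_per_delay=50, seed=8,
        )
        series = simulate_delay_series(cfg)
        acc = np.mean([s.accuracy for s in series.values()], axis=0)
        p, _ = accuracy_profile(cfg)
        n_total = 30 * 2 * 50
        se = np.sqrt(p * (1 - p) / n_total)
        assert np.all(np.abs(acc - p) < 4 * se)

    def test_default_grid_geometry(self):
        grid = default_delay_grid()
        assert grid.size == 19
        assert np.allclose(np.diff(grid), FRAME_MS)
        assert grid.min() > 312.0
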