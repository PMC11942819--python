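"""Sugeno fuzzy inference: construction, evaluation, calibration, categories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from liftpattern.exceptions import CalibrationError, ValidationError
from liftpattern.fuzzy import (
    DEFAULT_CATEGORIES,
    FISConfig,
    GaussianMF,
    build_default_fis,
    calibrate_output_constants,
    classify,
    evaluate_fis,
    fis_fit_metrics,
)


def _trend(x):
    return 1.0013 - 4.1535e-4 * x - 3.1026e-5 * x**2


def brute_force_sugeno(config, dev, load):
    """Independent evaluation: explicit sum over all 18 rules."""
    dev = min(max(dev, config.dev_domain[0]), config.dev_domain[1])
    num = den = 0.0
    for j, dmf in enumerate(config.dev_mfs):
        for k, lmf in enumerate(config.load_mfs):
            w = np.exp(-((dev - dmf.center) ** 2) / (2 * dmf.sigma**2)) * np.exp(
                -((load - lmf.center) ** 2) / (2 * lmf.sigma**2)
            )
            num += w * config.constants[j, k]
            den += w
    return num / den


class TestDefaultConfig:
    def test_structure(self):
        cfg = build_default_fis()
        assert cfg.n_rules == 18
        assert len(cfg.dev_mfs) == 6
        assert len(cfg.load_mfs) == 3
        assert len(cfg.rules()) == 18
        # constants nonincreasing in deviation center at full load
        col = cfg.constants[:, 2]
        assert np.all(np.diff(col) <= 0)

    def test_zero_deviation_constant_clamped_to_one(self):
        cfg = build_default_fis()
        assert cfg.constants[0, 0] == 1.0
        assert cfg.constants[0, 2] == 1.0  # trend intercept 1.0013 clamped

    def test_full_load_constants_follow_trend(self):
        cfg = build_default_fis()
        assert cfg.constants[5, 2] == pytest.approx(_trend(25.0), abs=1e-12)

    def test_membership_peaks_at_center(self):
        mf = GaussianMF(center=10.0, sigma=2.0)
        assert mf(10.0) == 1.0

    def test_json_round_trip(self, tmp_path):
        cfg = build_default_fis()
        path = tmp_path / "fis.json"
        cfg.to_json(path)
        back = FISConfig.from_json(path)
        np.testing.assert_allclose(back.constants, cfg.constants)
        assert back.dev_mfs == cfg.dev_mfs
        assert back.category_thresholds == cfg.category_thresholds


class TestEvaluate:
    def test_constant_consensus(self):
        cfg = build_default_fis()
        cfg = FISConfig(
            dev_mfs=cfg.dev_mfs, load_mfs=cfg.load_mfs,
            constants=np.full((6, 3), 0.99),
        )
        for dev, load in [(0, 0), (12.3, 25), (25, 50), (40, 80)]:
            assert evaluate_fis(cfg, dev, load).similarity == pytest.approx(0.99, abs=1e-12)

    def test_midpoint_between_adjacent_centers(self):
        # isolate two deviation rules with a near-crisp load MF
        base = build_default_fis()
        load_mfs = (GaussianMF(0, 0.1, "L0"), GaussianMF(25, 0.1, "L25"), GaussianMF(50, 0.1, "L50"))
        cfg = FISConfig(dev_mfs=base.dev_mfs, load_mfs=load_mfs, constants=base.constants)
        s = evaluate_fis(cfg, 17.5, 50.0).similarity  # between centers 15 and 20
        midpoint = 0.5 * (cfg.constants[3, 2] + cfg.constants[4, 2])
        assert s == pytest.approx(midpoint, abs=1e-3)

    def test_matches_brute_force_on_default(self):
        cfg = build_default_fis()
        s = evaluate_fis(cfg, 10.0, 50.0).similarity
        assert s == pytest.approx(brute_force_sugeno(cfg, 10.0, 50.0), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 100_000))
    def test_matches_brute_force_on_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        dev_mfs = tuple(
            GaussianMF(c, rng.uniform(0.5, 6.0)) for c in np.linspace(0, 25, 6)
        )
        load_mfs = tuple(GaussianMF(c, rng.uniform(2, 20)) for c in (0, 25, 50))
        constants = rng.uniform(0.965, 1.0, (6, 3))
        cfg = FISConfig(dev_mfs=dev_mfs, load_mfs=load_mfs, constants=constants)
        dev, load = rng.uniform(0, 30), rng.uniform(0, 60)
        s = evaluate_fis(cfg, dev, load)
        assert s.similarity == pytest.approx(brute_force_sugeno(cfg, dev, load), abs=1e-12)
        # convex-combination bound
        assert constants.min() - 1e-12 <= s.similarity <= constants.max() + 1e-12

    def test_monotone_in_deviation_at_fixed_load(self):
        cfg = build_default_fis()
        grid = np.linspace(0, 25, 101)
        vals = [evaluate_fis(cfg, d, 50.0).similarity for d in grid]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_clamps_large_deviation(self):
        cfg = build_default_fis()
        assert (
            evaluate_fis(cfg, 80.0, 50.0).similarity
            == evaluate_fis(cfg, 25.0, 50.0).similarity
        )

    def test_nan_input_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_fis(build_default_fis(), float("nan"), 50.0)


class TestClassify:
    @pytest.mark.parametrize(
        "score,label",
        [
            (1.0, "Total Accuracy"),
            (0.95, "Total Error"),
            (0.985, "Average Execution"),  # 0.97 + 2*0.006 <= 0.985 < 0.97 + 3*0.006
            (0.9765, "Medium Error"),
            (0.9905, "Medium Accuracy"),
        ],
    )
    def test_default_bins(self, score, label):
        assert classify(score) == label

    def test_categories_ordered(self):
        cfg = build_default_fis()
        assert cfg.categories == DEFAULT_CATEGORIES
        assert np.all(np.diff(cfg.category_thresholds) > 0)


class TestCalibration:
    def test_recovers_generating_constants(self):
        cfg = build_default_fis()
        devs = np.linspace(0.5, 24.5, 12)
        pairs = [(d, evaluate_fis(cfg, d, 50.0).similarity) for d in devs]
        cal = calibrate_output_constants(cfg, pairs)
        np.testing.assert_allclose(cal.constants, cfg.constants, atol=1e-6)

    def test_constant_target_gives_consensus(self):
        cfg = build_default_fis()
        pairs = [(d, 0.99) for d in np.linspace(0, 25, 10)]
        cal = calibrate_output_constants(cfg, pairs)
        np.testing.assert_allclose(cal.constants[:, 2], 0.99, atol=2e-3)

    def test_beats_quadratic_fit_on_reference_pairs(self, pairs30):
        from liftpattern.stats import quadratic_fit

        x, y = pairs30
        quad_r2 = quadratic_fit(x, y).r2
        cal = calibrate_output_constants(build_default_fis(), np.column_stack([x, y]))
        fis_r2, _ = fis_fit_metrics(cal, np.column_stack([x, y]))
        assert fis_r2 >= quad_r2 - 1e-6

    def test_calibration_is_least_squares_optimum(self, pairs30):
        x, y = pairs30
        cal = calibrate_output_constants(build_default_fis(), np.column_stack([x, y]))

        def sse(cfg):
            pred = np.array([evaluate_fis(cfg, d, 50.0).similarity for d in x])
            return ((y - pred) ** 2).sum()

        base_sse = sse(cal)
        for j in range(6):
            for delta in (-1e-3, 1e-3):
                # perturb the load-50 constant, carrying its row's
                # proportional ties to the other load levels
                perturbed = cal.constants.copy()
                perturbed[j, :] *= (perturbed[j, 2] + delta) / perturbed[j, 2]
                try:
                    cfg = FISConfig(
                        dev_mfs=cal.dev_mfs, load_mfs=cal.load_mfs, constants=perturbed
                    )
                except ValidationError:
                    continue  # perturbation leaves the admissible constant band
                assert sse(cfg) >= base_sse - 1e-14

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            calibrate_output_constants(build_default_fis(), [(1.0, 0.99)] * 5)

    def test_singular_basis_raises(self):
        cfg = build_default_fis()
        # all deviations identical: only one MF region excited
        pairs = [(10.0, 0.99)] * 8
        with pytest.raises(CalibrationError):
            calibrate_output_constants(cfg, pairs)


class TestFitMetrics:
    def test_self_generated_pairs_fit_perfectly(self):
        cfg = build_default_fis()
        pairs = [(d, evaluate_fis(cfg, d, 50.0).similarity) for d in np.linspace(0, 25, 9)]
        r2, r = fis_fit_metrics(cfg, pairs)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_constant_predictor_never_beats_mean(self):
        cfg = build_default_fis()
        flat = FISConfig(
            dev_mfs=cfg.dev_mfs, load_mfs=cfg.load_mfs, constants=np.full((6, 3), 0.99)
        )
        pairs = [(d, m) for d, m in zip([0, 5, 10, 20], [1.0, 0.99, 0.985, 0.97])]
        r2, r = fis_fit_metrics(flat, pairs)
        assert r2 <= 0.0
        assert np.isnan(r)

    def test_zero_variance_target_flagged(self):
        cfg = build_default_fis()
        r2, r = fis_fit_metrics(cfg, [(0.0, 0.99), (10.0, 0.99)])
        assert np.isnan(r2) and np.isnan(r)
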