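import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from strikerisk._rng import substream
from strikerisk.algebraic import (
    GaussianKernel,
    KernelMix,
    SigmoidBump,
    ThresholdRule,
    classify_day,
    eval_bump,
    eval_gaussian,
    eval_mix,
    fit_mix,
    fit_threshold_rule,
    oversample_minority,
)
from strikerisk.seasonal import SeasonalitySpec


class TestKernels:
    def test_gaussian_peak_and_half_maximum(self):
        g = GaussianKernel(a=3.0, b=0.5, c=0.2)
        assert eval_gaussian(g, 0.5) == pytest.approx(3.0)
        x_half = g.b + g.c * math.sqrt(2 * math.log(2))
        assert eval_gaussian(g, x_half) == pytest.approx(1.5, abs=1e-12)

    def test_gaussian_zero_height_is_zero_everywhere(self):
        g = GaussianKernel(a=0.0, b=0.0, c=1.0)
        assert np.all(eval_gaussian(g, np.linspace(-5, 5, 11)) == 0.0)

    def test_bump_centre_closed_form(self):
        s = SigmoidBump(a=2.0, b=0.1, c=0.3, k=0.05)
        expected = 2.0 * (2 * expit(0.3 / 0.05) - 1)
        assert eval_bump(s, 0.1) == pytest.approx(expected, abs=1e-12)

    def test_bump_symmetry_about_centre(self):
        s = SigmoidBump(a=1.0, b=-0.2, c=0.4, k=0.1)
        for t in (0.05, 0.3, 1.0, 5.0):
            assert eval_bump(s, s.b + t) == pytest.approx(eval_bump(s, s.b - t), abs=1e-12)

    def test_bump_saturates_to_plateau_as_k_shrinks(self):
        s = SigmoidBump(a=4.0, b=0.0, c=0.5, k=1e-4)
        assert eval_bump(s, 0.2) == pytest.approx(4.0, abs=1e-6)
        assert eval_bump(s, 0.9) == pytest.approx(0.0, abs=1e-6)

    def test_bump_overflow_safe_far_from_centre(self):
        s = SigmoidBump(a=1.0, b=0.0, c=0.5, k=0.01)
        val = eval_bump(s, 1e6)
        assert np.isfinite(val) and val == pytest.approx(0.0, abs=1e-12)

    def test_mix_is_componentwise_sum(self):
        g = GaussianKernel(2.0, 0.0, 0.5)
        s = SigmoidBump(1.0, 0.3, 0.2, 0.05)
        mix = KernelMix([g], [s])
        x = np.linspace(-1, 1, 41)
        np.testing.assert_allclose(eval_mix(mix, x), eval_gaussian(g, x) + eval_bump(s, x))

    def test_empty_mix_is_zero(self):
        assert eval_mix(KernelMix(), 0.3) == 0.0

    def test_mix_nonnegative_with_nonnegative_heights(self):
        rng = substream(7, "mixtest")
        for _ in range(20):
            mix = KernelMix(
                [GaussianKernel(rng.uniform(0, 5), rng.uniform(-1, 1), rng.uniform(0.05, 1))],
                [SigmoidBump(rng.uniform(0, 5), rng.uniform(-1, 1), rng.uniform(0.05, 1), rng.uniform(0.01, 0.5))],
            )
            assert np.all(eval_mix(mix, np.linspace(-2, 2, 101)) >= 0)

    def test_invalid_kernel_parameters_rejected(self):
        with pytest.raises(ValueError):
            GaussianKernel(-1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            GaussianKernel(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            SigmoidBump(1.0, 0.0, 0.5, 0.0)


class TestFitMix:
    def test_recovers_single_gaussian_from_noiseless_data(self):
        truth = GaussianKernel(a=50.0, b=-0.4, c=0.15)
        x = np.linspace(-1, 1, 120)
        pts = np.column_stack([x, eval_gaussian(truth, x)])
        mix, diag = fit_mix(pts, m=1, n=0, restarts=16, seed=3)
        g = mix.gaussians[0]
        assert g.a == pytest.approx(truth.a, rel=1e-3)
        assert g.b == pytest.approx(truth.b, abs=1e-3)
        assert g.c == pytest.approx(truth.c, rel=1e-3)

    def test_recovers_single_bump_from_noiseless_data(self):
        truth = SigmoidBump(a=30.0, b=0.2, c=0.4, k=0.08)
        x = np.linspace(-1, 1, 200)
        pts = np.column_stack([x, eval_bump(truth, x)])
        mix, _ = fit_mix(pts, m=0, n=1, restarts=24, seed=5)
        s = mix.bumps[0]
        assert s.a == pytest.approx(truth.a, rel=0.02)
        assert s.b == pytest.approx(truth.b, abs=0.02)
        assert s.c == pytest.approx(truth.c, rel=0.02)

    def test_best_of_restarts_contract(self):
        x = np.linspace(-1, 1, 60)
        y = eval_gaussian(GaussianKernel(10, 0.1, 0.3), x) + 0.1 * np.sin(9 * x)
        _, diag = fit_mix(np.column_stack([x, y]), m=1, n=0, restarts=8, seed=1)
        assert diag["sse"] <= min(diag["tried_sse"]) + 1e-12

    def test_too_few_points_rejected(self):
        pts = [(0.0, 1.0), (0.5, 2.0)]
        with pytest.raises(ValueError, match="at least"):
            fit_mix(pts, m=1, n=0)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_mix(np.empty((0, 2)), m=1, n=0)

    def test_yaml_round_trip(self, tmp_path):
        mix = KernelMix(
            [GaussianKernel(45.0, -0.49, 0.17)],
            [SigmoidBump(7.0, 0.25, 0.35, 0.08)],
            SeasonalitySpec(dt.date(2017, 5, 1), "linear"),
        )
        path = tmp_path / "mix.yaml"
        mix.to_yaml(path, species="Cattle Egret")
        again = KernelMix.from_yaml(path)
        assert again.gaussians == mix.gaussians
        assert again.bumps == mix.bumps
        assert again.seasonality == mix.seasonality


class TestOversample:
    def test_balanced_input_unchanged(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        Xo, yo = oversample_minority(X, y, seed=0)
        np.testing.assert_array_equal(Xo, X)
        np.testing.assert_array_equal(yo, y)

    def test_synthetic_points_interpolate_minority(self):
        # minority {0, 1} in one dimension: everything synthetic lies in [0, 1]
        X = np.concatenate([[0.0, 1.0], np.linspace(5, 6, 20)])[:, None]
        y = np.array([1, 1] + [0] * 20)
        Xo, yo = oversample_minority(X, y, seed=2)
        assert (yo == 1).sum() == (yo == 0).sum()
        synth = Xo[len(X):]
        assert np.all((synth >= 0.0) & (synth <= 1.0))

    def test_single_minority_point_duplicates_with_warning(self):
        X = np.array([[0.0], [5.0], [6.0], [7.0]])
        y = np.array([1, 0, 0, 0])
        with pytest.warns(UserWarning, match="duplication"):
            Xo, yo = oversample_minority(X, y, seed=0)
        assert np.all(Xo[len(X):] == 0.0)
        assert (yo == 1).sum() == (yo == 0).sum()

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            oversample_minority(np.zeros((3, 1)), np.array([0, 1, 2]))


def _planted_table(threshold: float, seed: int, n_days: int = 761) -> pd.DataFrame:
    """Days whose strike odds jump at a planted abundance threshold."""
    rng = substream(seed, "planted")
    abundance = rng.gamma(2.0, 30.0, n_days)
    p = expit(0.4 * (abundance - threshold))
    # rare-event scaling keeps strike days a small minority, as on a real airfield
    strike = rng.random(n_days) < p * 0.15
    if strike.sum() < 2:  # ensure a fittable table at any seed
        strike[np.argsort(abundance)[-2:]] = True
    return pd.DataFrame(
        {
            "abundance": abundance,
            "seasonality": rng.uniform(-1, 1, n_days),
            "expected_abundance": rng.gamma(2.0, 30.0, n_days),
            "strike": strike,
        }
    )


class TestThresholdRule:
    def test_planted_abundance_rule_recovered(self):
        table = _planted_table(90.0, seed=11)
        rule = fit_threshold_rule(table, seed=1)
        assert rule.attribute == "abundance"
        assert 80.0 <= rule.threshold <= 100.0
        assert 0.0 <= rule.accuracy <= 1.0
        assert 0.0 <= rule.f_score <= 1.0

    def test_all_strike_labels_rejected(self):
        table = pd.DataFrame({"abundance": [1.0, 2.0], "strike": [True, True]})
        with pytest.raises(ValueError, match="degenerate"):
            fit_threshold_rule(table, attributes=("abundance",))

    def test_zero_variance_attribute_excluded_with_warning(self):
        table = _planted_table(90.0, seed=3)
        table["seasonality"] = 0.5
        with pytest.warns(UserWarning, match="seasonality"):
            rule = fit_threshold_rule(table, seed=0)
        assert rule.attribute != "seasonality"

    def test_rule_json_round_trip(self, tmp_path):
        rule = ThresholdRule(
            attribute="",
            threshold=0.0,
            split_attribute="seasonality",
            split_at=-0.6,
            low_branch=ThresholdRule("expected_abundance", 7.9, "above"),
            high_branch=ThresholdRule("abundance", 0.0, "above"),
        )
        p = tmp_path / "rule.json"
        rule.to_json(p)
        again = ThresholdRule.from_json(p)
        assert again.low_branch.threshold == 7.9
        assert again.split_at == -0.6


class TestClassifyDay:
    IBIS_RULE = ThresholdRule("abundance", 90.0, "above")
    EGRET_RULE = ThresholdRule("seasonality", -0.78, "below")
    KESTREL_RULE = ThresholdRule(
        attribute="",
        threshold=0.0,
        split_attribute="seasonality",
        split_at=-0.6,
        low_branch=ThresholdRule("expected_abundance", 7.9, "above"),
        high_branch=ThresholdRule("abundance", 0.0, "above"),
    )

    def test_above_direction(self):
        assert classify_day(self.IBIS_RULE, {"abundance": 95.0}) == "elevated"
        assert classify_day(self.IBIS_RULE, {"abundance": 10.0}) == "low"

    def test_boundary_value_is_low(self):
        assert classify_day(self.IBIS_RULE, {"abundance": 90.0}) == "low"

    def test_below_direction(self):
        assert classify_day(self.EGRET_RULE, {"seasonality": -0.9}) == "elevated"
        assert classify_day(self.EGRET_RULE, {"seasonality": 0.2}) == "low"

    def test_seasonality_split_dispatches_to_branch(self):
        cool = {"seasonality": -0.7, "expected_abundance": 8.0, "abundance": 0.0}
        warm = {"seasonality": 0.0, "expected_abundance": 0.0, "abundance": 1.0}
        quiet = {"seasonality": 0.0, "expected_abundance": 50.0, "abundance": 0.0}
        assert classify_day(self.KESTREL_RULE, cool) == "elevated"
        assert classify_day(self.KESTREL_RULE, warm) == "elevated"
        assert classify_day(self.KESTREL_RULE, quiet) == "low"

    def test_monotone_in_attribute(self):
        rng = substream(5, "mono")
        vals = np.sort(rng.uniform(0, 200, 50))
        flags = [classify_day(self.IBIS_RULE, {"abundance": v}) == "elevated" for v in vals]
        # once elevated, increasing abundance never drops back to low
        first = flags.index(True) if True in flags else len(flags)
        assert all(flags[first:])

    def test_missing_attribute_error(self):
        with pytest.raises(KeyError, match="abundance"):
            classify_day(self.IBIS_RULE, {"seasonality": 0.1})
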