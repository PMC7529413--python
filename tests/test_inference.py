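"""Model comparison statistics and the causality decision rule."""

import numpy as np
import pytest

from stgranger import (
    InferenceConfig,
    SyntheticFieldSpec,
    adjusted_r_squared,
    causality_maps,
    central_region,
    decision_rule,
    diebold_mariano,
    ellipse_mask,
    generate_var_fields,
    r_squared,
)
from stgranger import test_pixel as granger_pixel_test


class TestRSquared:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_example(self):
        assert r_squared(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_constant_target_undefined(self):
        assert np.isnan(r_squared(np.ones(5), np.ones(5)))


class TestAdjustedRSquared:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r_squared(1.0, 156, 31) == pytest.approx(1.0)

    def test_zero_r2_study_dimensions(self):
        assert adjusted_r_squared(0.0, 156, 31) == pytest.approx(-0.25)

    def test_no_coefficients_reduces_to_r2(self):
        assert adjusted_r_squared(0.37, 50, 0) == pytest.approx(0.37)

    def test_never_exceeds_r2(self):
        rng = np.random.default_rng(0)
        for r2 in rng.uniform(-1, 1, 20):
            assert adjusted_r_squared(r2, 100, 5) <= r2 + 1e-12

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            adjusted_r_squared(0.5, 10, 9)


class TestDieboldMariano:
    def test_identical_residuals_degenerate(self):
        e = np.random.default_rng(1).standard_normal(50)
        stat, p = diebold_mariano(e, e)
        assert stat == 0.0
        assert p == 1.0

    def test_uniformly_larger_base_errors_detected(self):
        e = np.random.default_rng(2).standard_normal(156)
        e[np.abs(e) < 0.05] = 0.1  # keep every loss differential non-zero
        stat, p = diebold_mariano(e, 2 * e, hac_lags=10)
        assert stat > 0
        assert p < 0.05

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            diebold_mariano(np.ones(5), np.ones(5))

    def test_batched_matches_scalar(self):
        rng = np.random.default_rng(3)
        ef = rng.standard_normal((4, 60))
        eb = rng.standard_normal((4, 60))
        stat, p = diebold_mariano(ef, eb, hac_lags=5)
        s1, p1 = diebold_mariano(ef[2], eb[2], hac_lags=5)
        assert stat[2] == pytest.approx(s1)
        assert p[2] == pytest.approx(p1)

    def test_df_correction_centres_nested_insample_comparison(self):
        # in-sample nested fits favour the larger model; the N/(N-k)
        # rescaling removes that systematic advantage
        from stgranger import build_lagged_design, fit_ols

        rng = np.random.default_rng(4)
        plain, corrected = [], []
        for _ in range(100):
            y, x1, x2 = rng.standard_normal((3, 166))
            base = build_lagged_design(y, x2, P=10, model_kind="base")
            full = build_lagged_design(y, x2, x1, P=10)
            _, fb, _ = fit_ols(base)
            _, ff, _ = fit_ols(full)
            plain.append(diebold_mariano(ff.resid, fb.resid)[0])
            corrected.append(
                diebold_mariano(ff.resid, fb.resid, k_full=31, k_base=21)[0]
            )
        assert np.mean(plain) > 1.0  # strong upward bias without correction
        assert abs(np.mean(corrected)) < 0.3


class TestDecisionRule:
    def test_each_violated_condition_blocks_causality(self):
        assert decision_rule(0.3, 0.1, 0.001) is True
        assert decision_rule(-0.1, -0.2, 0.001) is False  # adjR2_full <= 0
        assert decision_rule(0.3, 0.4, 0.001) is False  # full not better
        assert decision_rule(0.3, 0.1, 0.2) is False  # DM not significant
        assert not decision_rule(np.nan, 0.1, 0.001)

    def test_vectorized_decisions(self):
        dec = decision_rule(
            np.array([0.3, -0.1]), np.array([0.1, -0.2]), np.array([0.001, 0.001])
        )
        np.testing.assert_array_equal(dec, [True, False])


class TestPixelTest:
    def test_null_series_rarely_flagged(self):
        rng = np.random.default_rng(5)
        hits = sum(
            granger_pixel_test(*rng.standard_normal((3, 166)))[0] for _ in range(100)
        )
        assert hits / 100 <= 0.10  # 2 * alpha

    def test_strong_coupling_detected(self):
        # y driven by x1 at lag 2 with coefficient 0.8 over sd-0.5 noise
        detections = 0
        for rep in range(100):
            rng = np.random.default_rng(600 + rep)
            T = 216
            x1 = np.empty(T)
            y = np.empty(T)
            x2 = rng.standard_normal(T)
            e1 = rng.standard_normal(T)
            ey = 0.5 * rng.standard_normal(T)
            x1[0] = e1[0]
            y[0] = ey[0]
            for t in range(1, T):
                x1[t] = 0.5 * x1[t - 1] + e1[t]
                y[t] = 0.5 * y[t - 1] + ey[t] + (0.8 * x1[t - 2] if t >= 2 else 0.0)
            decision, _, _ = granger_pixel_test(y[50:], x1[50:], x2[50:])
            detections += decision
        assert detections / 100 >= 0.9

    def test_constant_cause_reported_degenerate(self):
        rng = np.random.default_rng(6)
        decision, _, reason = granger_pixel_test(
            rng.standard_normal(166), np.ones(166), rng.standard_normal(166)
        )
        assert not decision
        assert reason == "degenerate predictor"


@pytest.fixture(scope="module")
def small_run():
    mask = ellipse_mask((14, 14))
    region = central_region(mask, 40)
    spec = SyntheticFieldSpec(
        grid_shape=(14, 14), coupling_coeff=0.8, causal_region=region, seed=21
    )
    stacks, gt = generate_var_fields(spec)
    maps = causality_maps(stacks, InferenceConfig())
    return spec, gt, maps


class TestCausalityMaps:

    def test_direction_asymmetry(self, small_run):
        spec, gt, maps = small_run
        region = gt.causal_mask("flow", "nnd")
        fwd = maps[("flow", "nnd")].decision[region].mean()
        rev = maps[("nnd", "flow")].decision[region].mean()
        assert fwd > rev

    def test_delta_adjr2_positive_exactly_where_condition_two_holds(self, small_run):
        _, _, maps = small_run
        m = maps[("flow", "nnd")]
        delta = m.delta_adjr2[m.mask]
        full = m.comparison.adjr2_full
        base = m.comparison.adjr2_base
        np.testing.assert_array_equal(delta > 0, full > base)

    def test_decision_false_outside_mask(self, small_run):
        _, _, maps = small_run
        for m in maps.values():
            assert not m.decision[~m.mask].any()

    def test_pairs_restriction_matches_full_run(self, small_run):
        spec, _, maps = small_run
        stacks, _ = generate_var_fields(spec)
        only = causality_maps(stacks, InferenceConfig(), pairs=[("flow", "nnd")])
        np.testing.assert_array_equal(
            only[("flow", "nnd")].decision, maps[("flow", "nnd")].decision
        )

    def test_empty_mask_rejected(self):
        from stgranger import FieldStack

        rng = np.random.default_rng(7)
        stacks = {
            v: FieldStack(v, rng.standard_normal((60, 4, 4)), np.zeros((4, 4), bool))
            for v in ("flow", "nnd", "area")
        }
        with pytest.raises(ValueError, match="mask"):
            causality_maps(stacks, InferenceConfig())
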