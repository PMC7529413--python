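"""Spatial summary statistics over causality maps and parameter fields."""

import numpy as np
import pytest

from stgranger import (
    causal_fraction,
    fraction_vs_periphery,
    lagged_xcorr,
    loop_diagram,
    mean_abs_xcorr,
    region_comparison,
    weight_profiles,
)
from stgranger.inference import CausalityMap, ModelComparison
from stgranger.regression import MTLWeights


def make_map(decision, mask, cause="flow", effect="nnd"):
    dummy = ModelComparison(*(np.zeros(np.count_nonzero(mask)),) * 6, N=100, k_base=21, k_full=31)
    return CausalityMap(
        cause=cause, effect=effect, conditional="area",
        decision=decision, mask=mask, alpha=0.05, comparison=dummy,
    )


class TestCausalFraction:
    def test_simple_percentages(self):
        mask = np.ones((10, 10), dtype=bool)
        dec = np.zeros((10, 10), dtype=bool)
        dec.ravel()[:15] = True
        assert causal_fraction(dec, mask) == pytest.approx(15.0)
        assert causal_fraction(np.zeros((10, 10), bool), mask) == 0.0

    def test_only_masked_pixels_counted(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        dec = np.zeros((10, 10), dtype=bool)
        dec[0] = True  # 10 causal of 50 masked
        assert causal_fraction(dec, mask) == pytest.approx(20.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            causal_fraction(np.zeros((4, 4), bool), np.zeros((4, 4), bool))


class TestPeripheryProfile:
    def test_single_bin_equals_causal_fraction(self):
        rng = np.random.default_rng(0)
        mask = np.ones((12, 12), dtype=bool)
        dec = rng.random((12, 12)) < 0.3
        dist = rng.uniform(0, 2, (12, 12))
        prof = fraction_vs_periphery(dec, dist, n_bins=1, mask=mask)
        assert prof.fraction[0] == pytest.approx(causal_fraction(dec, mask))

    def test_weighted_bin_average_reconstructs_total(self):
        rng = np.random.default_rng(1)
        mask = np.ones((20, 20), dtype=bool)
        dec = rng.random((20, 20)) < 0.25
        dist = rng.uniform(0, 3, (20, 20))
        prof = fraction_vs_periphery(dec, dist, n_bins=7, mask=mask)
        good = prof.counts > 0
        total = np.sum(prof.fraction[good] * prof.counts[good]) / prof.counts.sum()
        assert total == pytest.approx(causal_fraction(dec, mask))

    def test_central_causal_region_enriches_interior_bins(self):
        from stgranger import central_region, distance_to_periphery, ellipse_mask

        mask = ellipse_mask((30, 30))
        dec = central_region(mask, 60)
        dist = distance_to_periphery(mask, 1000.0)
        prof = fraction_vs_periphery(dec, dist, n_bins=4, mask=mask)
        assert np.nanargmax(prof.fraction) >= 2  # deepest bins carry the causality
        assert prof.fraction[0] == pytest.approx(0.0)


class TestLoopDiagram:
    def test_empty_maps_display_nothing(self):
        mask = np.ones((8, 8), dtype=bool)
        maps = {
            (a, b): make_map(np.zeros((8, 8), bool), mask, a, b)
            for a in ("flow", "nnd") for b in ("flow", "nnd") if a != b
        }
        loop = loop_diagram(maps)
        assert all(p == 0 for p in loop.percentages.values())
        assert loop.displayed == []

    def test_single_edge_above_threshold_displayed(self):
        mask = np.ones((10, 10), dtype=bool)
        dec = np.zeros((10, 10), dtype=bool)
        dec.ravel()[:15] = True
        maps = {
            ("flow", "nnd"): make_map(dec, mask),
            ("nnd", "flow"): make_map(np.zeros((10, 10), bool), mask, "nnd", "flow"),
        }
        loop = loop_diagram(maps, threshold_pct=2.0)
        assert loop.displayed == [("flow", "nnd", 15.0)]
        # sub-threshold entries stay in the data
        assert loop.percentages[("nnd", "flow")] == 0.0


class TestRegionComparison:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(2)
        calm = 0
        for seed in range(10):
            field = rng.standard_normal((30, 30))
            mask = np.ones((30, 30), dtype=bool)
            dec = np.zeros((30, 30), dtype=bool)
            dec.ravel()[rng.choice(900, 200, replace=False)] = True
            rc = region_comparison(field, dec, mask=mask, n_tests=50, subsample=100, seed=seed)
            calm += rc.median_p > 0.05
        assert calm >= 8

    def test_one_sd_mean_shift_significant(self):
        rng = np.random.default_rng(3)
        field = rng.standard_normal((30, 30))
        mask = np.ones((30, 30), dtype=bool)
        dec = np.zeros((30, 30), dtype=bool)
        dec.ravel()[:200] = True
        field[dec] += 1.0
        rc = region_comparison(field, dec, mask=mask, n_tests=100, subsample=100, seed=0)
        assert rc.median_p < 0.01
        assert rc.stats_causal["mean"] > rc.stats_noncausal["mean"]

    def test_constant_field_p_one_by_convention(self):
        field = np.ones((20, 20))
        mask = np.ones((20, 20), dtype=bool)
        dec = np.zeros((20, 20), dtype=bool)
        dec.ravel()[:150] = True
        rc = region_comparison(field, dec, mask=mask, n_tests=20, subsample=100, seed=0)
        assert rc.median_p == 1.0

    def test_small_group_shrinks_subsample(self):
        rng = np.random.default_rng(4)
        field = rng.standard_normal((10, 10))
        mask = np.ones((10, 10), dtype=bool)
        dec = np.zeros((10, 10), dtype=bool)
        dec.ravel()[:8] = True
        rc = region_comparison(field, dec, mask=mask, n_tests=10, subsample=100, seed=0)
        assert rc.subsample == 8


class TestLaggedXcorr:
    def test_self_correlation_unity_at_lag_zero(self):
        a = np.random.default_rng(5).standard_normal(100)
        corr = lagged_xcorr(a, a, max_lag=5)
        assert corr[0] == pytest.approx(1.0)

    def test_shifted_copy_peaks_at_shift(self):
        rng = np.random.default_rng(6)
        b = rng.standard_normal(166)
        a = np.roll(b, 3)  # a_t = b_{t-3}
        corr = lagged_xcorr(a, b, max_lag=10)
        assert int(np.argmax(corr)) == 3
        assert corr[3] > 0.95

    def test_white_noise_within_fisher_bound(self):
        rng = np.random.default_rng(7)
        T = 166
        inside = 0
        n_rep = 100
        for _ in range(n_rep):
            c = lagged_xcorr(rng.standard_normal(T), rng.standard_normal(T), max_lag=10)
            inside += np.all(np.abs(c) <= 2.5 / np.sqrt(T))
        assert inside / n_rep >= 0.6  # joint bound over 11 lags

    def test_correlations_bounded(self):
        rng = np.random.default_rng(8)
        c = lagged_xcorr(rng.standard_normal(60), rng.standard_normal(60), max_lag=10)
        assert np.all(np.abs(c) <= 1.0)


class TestMeanAbsXcorr:
    def test_single_regime_without_decisions(self):
        rng = np.random.default_rng(9)
        out = mean_abs_xcorr(rng.standard_normal((80, 5)), rng.standard_normal((80, 5)))
        assert set(out) == {"all"}
        assert np.all((out["all"] >= 0) & (out["all"] <= 1))

    def test_coupled_pixels_dominate_at_coupling_lag(self):
        rng = np.random.default_rng(10)
        T, L, tau = 166, 40, 3
        A = rng.standard_normal((T, L))
        B = rng.standard_normal((T, L))
        dec = np.zeros(L, dtype=bool)
        dec[:20] = True
        B[tau:, dec] += 0.8 * A[:-tau, dec]
        # effect series first: entries correlate B_t with A_{t-lag}
        out = mean_abs_xcorr(B, A, dec, max_lag=6)
        assert out["causal"][tau] > out["noncausal"][tau] + 0.2


class TestWeightProfiles:
    @staticmethod
    def weights(W, columns):
        return MTLWeights(
            W=W, U=W, V=np.zeros((W.shape[0], 1)), Theta=np.zeros((1, W.shape[1])),
            lam=0.1, h=1, columns=columns,
        )

    def test_zero_weights_zero_profile(self):
        cols = ["intercept", "y_lag1", "y_lag2", "flow_lag1", "flow_lag2"]
        prof = weight_profiles(self.weights(np.zeros((4, 5)), cols))
        assert (prof["mean_abs_weight"] == 0).all()

    def test_base_model_has_no_cause_entries(self):
        cols = ["intercept"] + [f"y_lag{p}" for p in (1, 2)] + [f"area_lag{p}" for p in (1, 2)]
        prof = weight_profiles(self.weights(np.ones((3, 5)), cols))
        assert set(prof["variable"]) == {"y", "area"}

    def test_injected_lag_peaks_in_profile(self):
        cols = ["intercept"] + [f"flow_lag{p}" for p in range(1, 6)]
        W = np.zeros((10, 6))
        W[:, 3] = 0.7  # flow_lag3
        prof = weight_profiles(self.weights(W, cols))
        top = prof.loc[prof["mean_abs_weight"].idxmax()]
        assert top["variable"] == "flow" and top["lag"] == 3
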