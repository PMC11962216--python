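"""MR estimators: Wald ratio, IVW, Egger, weighted median/mode, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr import (
    MRModel,
    ivw,
    mr_egger,
    sensitivity,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from targetmr.mr import _weighted_median_point

from conftest import pair, strong_instrument_pairs


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        assert wald_ratio(pair(beta_out=0.0)).beta == 0.0

    def test_direct_formula(self):
        est = wald_ratio(pair(beta_exp=0.25, beta_out=0.05, se_out=0.02))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.08)
        assert est.nsnp == 1

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ValueError):
            wald_ratio(pair(beta_exp=0.0))

    def test_first_order_se_agrees_with_second_order_for_strong_instruments(self):
        p = pair(beta_exp=0.2, se_exp=0.01, beta_out=0.04, se_out=0.01)  # F=400
        first = wald_ratio(p).se
        second = wald_ratio(p, second_order=True).se
        assert abs(first - second) / second < 0.05


class TestIVW:
    def test_hand_evaluated_weighted_sum(self):
        pairs = [
            pair("s1", beta_exp=0.1, beta_out=0.05, se_out=0.01),
            pair("s2", beta_exp=0.2, beta_out=0.10, se_out=0.02),
        ]
        est = ivw(pairs)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(1 / np.sqrt(200))

    def test_equal_ratios_returned_exactly(self):
        r = 0.37
        pairs = [pair(f"s{i}", beta_exp=b, beta_out=r * b, se_out=0.01) for i, b in enumerate((0.1, 0.15, 0.2))]
        assert ivw(pairs).beta == pytest.approx(r)

    def test_single_pair_directed_to_wald(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw([pair()])

    def test_invariant_to_joint_sign_flip(self):
        pairs = strong_instrument_pairs(seed=42)
        flipped = [
            pair(
                p.snp_id, -p.beta_exp, p.se_exp, p.pval_exp, p.n_exp,
                -p.beta_out, p.se_out, p.pval_out, p.n_out, p.eaf,
            )
            for p in pairs[:5]
        ] + list(pairs[5:])
        assert ivw(flipped).beta == pytest.approx(ivw(pairs).beta)
        assert ivw(flipped).se == pytest.approx(ivw(pairs).se)

    def test_random_effects_se_never_smaller(self):
        pairs = strong_instrument_pairs(seed=7)
        assert ivw(pairs, random_effects=True).se >= ivw(pairs).se

    def test_or_ci_ordering(self):
        est = ivw(strong_instrument_pairs(seed=3))
        assert est.ci_low < est.or_ < est.ci_high


class TestEgger:
    def test_exact_linear_fit_recovers_intercept_and_slope(self):
        pairs = [
            pair(f"s{i}", beta_exp=b, beta_out=0.01 + 0.5 * b, se_out=0.01)
            for i, b in enumerate((0.1, 0.2, 0.3, 0.4))
        ]
        est, icpt, _, _ = mr_egger(pairs)
        assert icpt == pytest.approx(0.01, abs=1e-10)
        assert est.beta == pytest.approx(0.5, abs=1e-10)

    def test_slope_matches_ivw_without_pleiotropy(self):
        """Mean Egger slope equals mean IVW within 2 Monte-Carlo SEs."""
        diffs = []
        for s in range(150):
            pairs = strong_instrument_pairs(seed=5000 + s, n_exp=500000)
            diffs.append(mr_egger(pairs)[0].beta - ivw(pairs).beta)
        mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * mc_se + 1e-3

    def test_too_few_instruments_raises(self):
        with pytest.raises(ValueError):
            mr_egger([pair("a"), pair("b")])


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        pairs = [
            pair(f"s{i}", beta_exp=0.1, beta_out=0.1 * r, se_out=0.01)
            for i, r in enumerate((0.4, 0.5, 0.6))
        ]
        assert weighted_median(pairs, n_boot=0).beta == pytest.approx(0.5)

    def test_duplicated_snp_pulls_median_like_bruteforce(self):
        base = [(0.1, 0.02), (0.1, 0.05), (0.1, 0.08)]
        pairs = [
            pair(f"s{i}", beta_exp=b, beta_out=o, se_out=0.01) for i, (b, o) in enumerate(base)
        ]
        dup = pairs + [pair("s1dup", 0.1, 0.01, 1e-10, 30000, 0.02, 0.01, 0.05, 200000)]
        ratio = np.array([p.ratio for p in dup])
        w = np.array([p.beta_exp**2 / p.se_out**2 for p in dup])
        assert weighted_median(dup, n_boot=0).beta == pytest.approx(_weighted_median_point(ratio, w))
        # doubling the weight of the smallest ratio moves the median down
        assert weighted_median(dup, n_boot=0).beta < weighted_median(pairs, n_boot=0).beta

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_bruteforce_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        ratio = rng.normal(0.2, 0.3, n)
        w = rng.uniform(0.5, 5.0, n)
        # brute-force: scan the weighted cdf at ratio midpoints
        order = np.argsort(ratio)
        r, ww = ratio[order], w[order]
        cum = (np.cumsum(ww) - 0.5 * ww) / ww.sum()
        expected = float(np.interp(0.5, cum, r))
        assert _weighted_median_point(ratio, w) == pytest.approx(expected)

    def test_robust_to_minority_invalid_instruments(self):
        ests = []
        for s in range(60):
            pairs = strong_instrument_pairs(
                seed=6000 + s,
                theta=0.2,
                pleiotropy_mode="directional",
                pleiotropy_effect=0.02,
                pleiotropy_frac=0.3,
            )
            ests.append(weighted_median(pairs, n_boot=0).beta)
        assert abs(np.mean(ests) - 0.2) < 0.05


class TestWeightedMode:
    def test_identical_ratios(self):
        pairs = [pair(f"s{i}", beta_exp=0.1, beta_out=0.02, se_out=0.01) for i in range(4)]
        est = weighted_mode(pairs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, abs=1e-6)

    def test_majority_cluster_wins_bimodal(self):
        ratios = [0.2] * 6 + [0.8] * 3
        pairs = [
            pair(f"s{i}", beta_exp=0.1, beta_out=0.1 * r, se_out=0.01) for i, r in enumerate(ratios)
        ]
        assert weighted_mode(pairs, n_boot=0).beta == pytest.approx(0.2, abs=0.05)

    def test_mode_within_ratio_range(self):
        for s in range(10):
            pairs = strong_instrument_pairs(seed=s)
            est = weighted_mode(pairs, n_boot=0)
            ratios = [p.ratio for p in pairs]
            assert min(ratios) <= est.beta <= max(ratios)


class TestSensitivity:
    def test_identical_ratios_give_zero_q(self):
        pairs = [
            pair(f"s{i}", beta_exp=b, beta_out=0.3 * b, se_out=0.01)
            for i, b in enumerate((0.1, 0.2, 0.3))
        ]
        rep = sensitivity(pairs)
        assert rep.q == pytest.approx(0.0, abs=1e-20)
        assert rep.q_pval == pytest.approx(1.0)
        assert rep.q_df == 2

    def test_q_mean_close_to_df_under_homogeneity(self):
        qs = [sensitivity(strong_instrument_pairs(seed=7000 + s, n_exp=500000)).q for s in range(300)]
        assert np.mean(qs) == pytest.approx(19, rel=0.08)

    def test_loo_length_and_leverage_ordering(self):
        pairs = strong_instrument_pairs(seed=9)
        rep = sensitivity(pairs)
        assert len(rep.loo) == len(pairs)
        base = ivw(pairs).beta
        shifts = {snp: abs(est.beta - base) for snp, est in rep.loo}
        w = {p.snp_id: p.beta_exp**2 / p.se_out**2 for p in pairs}
        heaviest = max(w, key=w.get)
        # removing the heaviest-weight SNP moves the estimate at least as much
        # as removing the median-leverage SNP on average across seeds; here we
        # just check the report is internally consistent
        assert set(shifts) == set(w)


class TestModelResults:
    def test_auto_method_selection(self):
        pairs = strong_instrument_pairs(seed=21)
        res1 = MRModel(pairs[:1]).fit()
        assert res1.primary.method == "wald_ratio"
        res2 = MRModel(pairs[:2]).fit()
        assert res2.primary.method == "ivw"
        res_many = MRModel(pairs).fit(n_boot=20)
        assert set(res_many.estimates) == {"ivw", "egger", "weighted_median", "weighted_mode"}
        assert res_many.primary.method == "ivw"

    def test_summary_reports_all_methods_and_diagnostics(self):
        res = MRModel(strong_instrument_pairs(seed=22)).fit(n_boot=20)
        text = res.summary()
        for token in ("ivw", "egger", "weighted_median", "weighted_mode", "Cochran Q", "Egger intercept"):
            assert token in text

    def test_from_dataframe_round_trip(self):
        import pandas as pd

        pairs = strong_instrument_pairs(seed=23)
        rebuilt = MRModel.from_dataframe(pd.DataFrame([vars(p) for p in pairs]))
        assert ivw(rebuilt.pairs).beta == pytest.approx(ivw(pairs).beta)
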