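"""Endpoint statistics: transforms, test battery, binning, contingency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from phagekit import (
    ExplantEndpoint,
    chi_square_contingency,
    dunn_multiple_comparison,
    ldh_bin,
    ldh_contingency,
    log10_transform,
    simulate_explant_endpoint,
    summarize_endpoints,
    two_sample_test,
)
from tests._oracles import brute_force_mean_ranks


class TestLog10Transform:
    def test_positive_value(self):
        assert log10_transform(1e7) == pytest.approx(7.0)

    def test_censored_half_lod(self):
        assert log10_transform(0.0, lod=100.0) == pytest.approx(math.log10(50.0))

    def test_censored_at_lod(self):
        assert log10_transform(0.0, lod=100.0, policy="lod") == pytest.approx(2.0)

    def test_censored_drop(self):
        assert log10_transform(0.0, policy="drop") is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log10_transform(-1.0)

    def test_half_lod_needs_lod(self):
        with pytest.raises(ValueError):
            log10_transform(0.0)


class TestTwoSampleTest:
    def test_identical_samples_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_test(x, x)
        assert res.p_value > 0.9
        assert not res.significant

    def test_all_tied_degenerate(self):
        res = two_sample_test([5.0] * 4, [5.0] * 4)
        assert res.p_value == 1.0
        assert res.method == "degenerate_all_tied"

    def test_separated_normals_significant(self):
        # a 3-sigma location shift at n=30 has power ~ 1 whichever path runs
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(3, 1, 30)
        res = two_sample_test(x, y)
        assert res.significant
        assert res.method in ("welch_t", "mann_whitney_u")

    def test_normal_samples_route_to_welch(self):
        rng = np.random.default_rng(2)  # both samples pass Shapiro-Wilk here
        x = rng.normal(0, 1, 30)
        y = rng.normal(3, 1, 30)
        res = two_sample_test(x, y)
        assert res.significant
        assert res.method == "welch_t"

    def test_nonnormal_routes_to_rank_sum(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 2, 40)  # heavily skewed
        y = rng.lognormal(0, 2, 40)
        res = two_sample_test(x, y)
        assert res.method == "mann_whitney_u"

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_null_type_one_error_calibrated(self):
        """Rejection rate ~ alpha on 1000 null normal datasets."""
        rejections = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 1, 10)
            rejections += two_sample_test(x, y).significant
        assert 0.03 <= rejections / n_rep <= 0.07


class TestDunn:
    def test_identical_groups_nothing_significant(self):
        g = {"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5], "c": [1, 2, 3, 4, 5]}
        results = dunn_multiple_comparison(g)
        assert len(results) == 3
        assert not any(r.significant for r in results)

    def test_single_shifted_group_detected(self):
        rng = np.random.default_rng(7)
        groups = {
            "g1": rng.normal(0, 1, 15),
            "g2": rng.normal(0, 1, 15),
            "g3": rng.normal(5, 1, 15),
        }
        results = dunn_multiple_comparison(groups)
        by_pair = {tuple(r.detail["pair"]): r for r in results}
        assert by_pair[("g1", "g3")].significant
        assert by_pair[("g2", "g3")].significant
        assert not by_pair[("g1", "g2")].significant

    def test_z_sign_matches_brute_force_mean_ranks(self):
        groups = {"a": [1.0, 3.0, 3.0, 7.0], "b": [2.0, 8.0, 9.0, 10.0]}
        (res,) = dunn_multiple_comparison(groups, adjustment="none")
        ranks = brute_force_mean_ranks(groups)
        assert np.sign(res.statistic) == np.sign(ranks["a"] - ranks["b"])

    def test_bonferroni_never_below_raw_p(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(0, 1, 8) for k in "abcd"}
        for r in dunn_multiple_comparison(groups, adjustment="bonferroni"):
            assert r.adjusted_p >= r.p_value - 1e-15

    def test_holm_never_below_raw_p(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(0, 1, 8) for k in "abc"}
        for r in dunn_multiple_comparison(groups, adjustment="holm"):
            assert r.adjusted_p >= r.p_value - 1e-15

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_multiple_comparison({"a": [1.0], "b": []})

    def test_null_familywise_error_calibrated(self):
        """Two-group Dunn rejects ~ alpha under the null (1000 sims)."""
        rejections = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15)}
            (res,) = dunn_multiple_comparison(groups)
            rejections += res.significant
        assert 0.03 <= rejections / n_rep <= 0.07


class TestLdhBin:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, "lt50"), (42.0, "lt50"), (49.999, "lt50"), (50.0, "b50_100"),
         (75.0, "b50_100"), (100.0, "b50_100"), (100.001, "gt100"),
         (150.0, "gt100")],
    )
    def test_boundaries(self, value, expected):
        assert ldh_bin(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ldh_bin(-1.0)

    @given(value=hst.floats(min_value=0, max_value=1e4))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, value):
        assert ldh_bin(value) in ("lt50", "b50_100", "gt100")


class TestChiSquare:
    def test_identical_rows_null(self):
        res = chi_square_contingency([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_2x2(self):
        # Sum (O-E)^2/E with all E = 5 -> 4 * 25/5 = 20
        res = chi_square_contingency([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        # every expected count is exactly 5: the < 5 warning must not fire
        assert not res.detail["low_expected_warning"]
        res_small = chi_square_contingency([[4, 0], [0, 4]])
        assert res_small.detail["low_expected_warning"]

    def test_permutation_invariance(self):
        table = np.array([[8, 2, 5], [1, 9, 4]])
        base = chi_square_contingency(table).statistic
        assert chi_square_contingency(table[:, [2, 0, 1]]).statistic == pytest.approx(base)
        assert chi_square_contingency(table[[1, 0], :]).statistic == pytest.approx(base)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_contingency([[10, 0], [5, 0]])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_square_contingency([[0, 0], [0, 0]])


class TestExplantEndpoints:
    def _endpoints(self):
        return [
            ExplantEndpoint("u1", "positive_control", None, 1.7e7, None, 40.0, 60.0),
            ExplantEndpoint("u1", "moi1", "p", 9.9e6, 4.9e5, 55.0, 120.0),
            ExplantEndpoint("u1", "moi10", "p", 1.3e7, 6.2e5, 45.0, 80.0),
            ExplantEndpoint("u2", "positive_control", None, 2.0e7, None, 30.0, 110.0),
            ExplantEndpoint("u2", "moi1", "p", 1.1e7, 5.5e5, 60.0, 95.0),
            ExplantEndpoint("u2", "moi10", "p", 1.6e7, 7.0e5, 20.0, 150.0),
        ]

    def test_summary_scales(self):
        summary = summarize_endpoints(self._endpoints()).set_index("group")
        assert summary.loc["positive_control", "n"] == 2
        assert summary.loc["moi1", "cfu_mean"] == pytest.approx((9.9e6 + 1.1e7) / 2)
        assert summary.loc["moi1", "log10_cfu_mean"] == pytest.approx(
            (math.log10(9.9e6) + math.log10(1.1e7)) / 2
        )
        assert "pfu_mean" in summary.columns

    def test_ldh_contingency_counts(self):
        table = ldh_contingency(self._endpoints(), timepoint="combined")
        # 12 readings total across 3 groups
        assert table.to_numpy().sum() == 12
        assert table.loc["gt100", "moi10"] == 1

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            ExplantEndpoint("u", "weird", None, 1.0, None, None, None)


class TestSimulatedEndpoints:
    def test_zero_spread_is_deterministic(self):
        vals = simulate_explant_endpoint(7.0, 0.0, 3, seed=0)
        assert np.allclose(vals, 1e7)

    def test_log_mean_recovery(self):
        vals = simulate_explant_endpoint(7.0, 0.5, 10_000, seed=1)
        se = 0.5 / math.sqrt(10_000)
        assert abs(np.mean(np.log10(vals)) - 7.0) < 3 * se

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_explant_endpoint(7.0, 0.5, 0, seed=0)

    def test_null_comparison_rarely_rejects(self):
        """Identical-parameter endpoint sets pass the two-sample gate in
        >= 90% of 200 seeded replicates (type-I control end to end)."""
        non_rejections = 0
        for seed in range(200):
            x = np.log10(simulate_explant_endpoint(7.0, 0.5, 8, seed=2 * seed))
            y = np.log10(simulate_explant_endpoint(7.0, 0.5, 8, seed=2 * seed + 1))
            non_rejections += not two_sample_test(x, y).significant
        assert non_rejections / 200 >= 0.90
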