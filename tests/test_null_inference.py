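"""Per-bin logistic fitting, prediction, and null reconstruction."""

import numpy as np
import pytest
from scipy.special import expit, logit

from permfdr import (
    CoefficientTable,
    build_null,
    cum_prob,
    fit_bin,
    fit_coefficient_table,
    infer_null,
    predict_cum_prob,
    simulate_null_family,
)


def family_beta(K, intercept_span=(-4.0, 4.0), slope_span=(0.5, 1.5)):
    """Per-bin (intercept, slope) pairs giving CDFs monotone in k for r >= 0."""
    k = np.arange(1, K)
    b0 = intercept_span[0] + (intercept_span[1] - intercept_span[0]) * k / K
    b1 = slope_span[0] + (slope_span[1] - slope_span[0]) * k / K
    return np.column_stack([b0, b1])


class TestCumProb:
    def test_last_bin_is_one(self, toy_null):
        assert cum_prob(toy_null, toy_null.K) == 1.0

    @pytest.mark.parametrize("k,expected", [(1, 0.5), (2, 0.5), (3, 0.75)])
    def test_cumulative_hand_counts(self, toy_null, k, expected):
        assert cum_prob(toy_null, k) == pytest.approx(expected)

    def test_out_of_range(self, toy_null):
        with pytest.raises(ValueError):
            cum_prob(toy_null, 0)
        with pytest.raises(ValueError):
            cum_prob(toy_null, toy_null.K + 1)


class TestFitBin:
    def test_exact_two_point_solve(self):
        beta = fit_bin(np.array([[0.0], [1.0]]), np.array([0.2, 0.5]))
        assert beta[0] == pytest.approx(logit(0.2), abs=1e-9)
        assert beta[1] == pytest.approx(logit(0.5) - logit(0.2), abs=1e-9)

    def test_constant_probability_gives_zero_slope(self):
        beta = fit_bin(np.array([[0.0], [0.5], [1.0]]), np.full(3, 0.3))
        assert beta[1] == pytest.approx(0.0, abs=1e-12)
        assert beta[0] == pytest.approx(logit(0.3))

    def test_probability_one_is_clipped_to_finite_target(self):
        beta = fit_bin(np.array([[0.0], [1.0]]), np.array([0.5, 1.0]), clip_eps=1e-6)
        assert np.all(np.isfinite(beta))
        assert beta[0] + beta[1] == pytest.approx(logit(1 - 1e-6))

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_bin(np.array([[0.3]]), np.array([0.5]))

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_bin(np.array([[0.3], [0.3], [0.3]]), np.array([0.2, 0.5, 0.8]))

    def test_huber_matches_l2_on_clean_logit_linear_data(self):
        r = np.linspace(0, 1, 8).reshape(-1, 1)
        pr = expit(-1.0 + 2.0 * r.ravel())
        b_l2 = fit_bin(r, pr, loss="l2")
        b_hub = fit_bin(r, pr, loss="huber")
        assert b_hub == pytest.approx(b_l2, abs=1e-6)

    def test_huber_resists_a_gross_outlier(self):
        r = np.linspace(0, 1, 12).reshape(-1, 1)
        pr = expit(-1.0 + 2.0 * r.ravel())
        pr[0] = 0.999  # corrupted sample
        b_hub = fit_bin(r, pr, loss="huber")
        b_l2 = fit_bin(r, pr, loss="l2")
        truth = np.array([-1.0, 2.0])
        assert np.abs(b_hub - truth).max() < np.abs(b_l2 - truth).max()

    def test_unknown_loss(self):
        with pytest.raises(ValueError):
            fit_bin(np.array([[0.0], [1.0]]), np.array([0.2, 0.5]), loss="l1")


class TestFitCoefficientTable:
    def test_row_count_is_k_minus_one(self):
        nulls, fvs = simulate_null_family(
            I=5, feature_values=[0, 0.1, 0.2, 0.3, 0.4], beta=family_beta(20), K=20
        )
        table = fit_coefficient_table(nulls, fvs)
        assert table.beta.shape == (19, 2)
        assert table.K == 20 and table.J == 1

    def test_identical_nulls_give_zero_slopes(self):
        nulls, fvs = simulate_null_family(
            I=2, feature_values=[0.1, 0.9], beta=family_beta(10, slope_span=(0, 0)), K=10
        )
        table = fit_coefficient_table(nulls, fvs)
        assert np.abs(table.beta[:, 1]).max() == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_round_trip_recovers_beta(self):
        beta = family_beta(30)
        nulls, fvs = simulate_null_family(
            I=6, feature_values=np.linspace(0, 1, 6), beta=beta, K=30
        )
        table = fit_coefficient_table(nulls, fvs)
        assert np.abs(table.beta - beta).max() <= 1e-6

    def test_mismatched_bin_structure_rejected(self):
        nulls_a, fvs = simulate_null_family(
            I=2, feature_values=[0.0, 1.0], beta=family_beta(10), K=10
        )
        nulls_b, _ = simulate_null_family(
            I=2, feature_values=[0.0, 1.0], beta=family_beta(12), K=12
        )
        with pytest.raises(ValueError):
            fit_coefficient_table([nulls_a[0], nulls_b[0]], fvs)

    def test_noisy_fit_correlates_with_generating_beta(self):
        """sd-0.1 logit noise leaves fitted slopes/intercepts highly correlated."""
        beta = family_beta(40)
        nulls, fvs = simulate_null_family(
            I=10,
            feature_values=np.linspace(0, 1, 10),
            beta=beta,
            K=40,
            seed=5,
            noise_sd=0.1,
        )
        table = fit_coefficient_table(nulls, fvs)
        for j in (0, 1):
            corr = np.corrcoef(table.beta[:, j], beta[:, j])[0, 1]
            assert corr > 0.95


class TestPredict:
    def test_zero_coefficients_give_half(self):
        assert predict_cum_prob(np.zeros(2), np.array([3.7])) == 0.5

    def test_printed_reference_coefficients(self):
        # intercept -6.0539, feature coefficient -18.607, feature 0
        val = predict_cum_prob(np.array([-6.0539, -18.607]), np.array([0.0]))
        assert val == pytest.approx(1 / (1 + np.exp(6.0539)))

    def test_monotone_in_linear_term(self):
        vals = [
            predict_cum_prob(np.array([0.0, b1]), np.array([1.0]))
            for b1 in (-2, 0, 2)
        ]
        assert vals == sorted(vals)

    def test_extreme_linear_term_stays_in_open_interval(self):
        lo = predict_cum_prob(np.array([-1e9, 0.0]), np.array([0.0]))
        hi = predict_cum_prob(np.array([1e9, 0.0]), np.array([0.0]))
        assert 0.0 <= lo < 1e-12 and 1.0 - 1e-12 < hi <= 1.0

    def test_feature_length_mismatch(self):
        with pytest.raises(ValueError):
            predict_cum_prob(np.array([0.0, 1.0]), np.array([1.0, 2.0]))


class TestInferNull:
    def test_first_differences_of_predicted_cdf(self):
        # coefficients whose logistic values are exactly 0.2 and 0.5
        beta = np.array([[logit(0.2), 0.0], [logit(0.5), 0.0]])
        table = CoefficientTable(beta=beta, bin_width=1 / 3)
        null = infer_null(table, np.array([0.0]))
        assert null.density == pytest.approx([0.2, 0.3, 0.5])

    def test_zero_coefficients(self):
        table = CoefficientTable(beta=np.zeros((2, 2)), bin_width=1 / 3)
        null = infer_null(table, np.array([0.7]))
        assert null.density == pytest.approx([0.5, 0.0, 0.5])

    def test_density_sums_to_one_and_non_negative(self, rng):
        for _ in range(20):
            beta = rng.normal(0, 3, size=(9, 2))  # deliberately non-monotone
            table = CoefficientTable(beta=beta, bin_width=0.1)
            null = infer_null(table, rng.uniform(0, 1, size=1))
            assert np.all(null.density >= -1e-12)
            assert null.density.sum() == pytest.approx(1.0)
            assert np.all(np.diff(null.cum) >= -1e-12)

    def test_held_out_inference_matches_generating_density(self):
        beta = family_beta(50)
        nulls, fvs = simulate_null_family(
            I=5, feature_values=[0.0, 0.1, 0.2, 0.3, 0.4], beta=beta, K=50
        )
        table = fit_coefficient_table(nulls, fvs)
        r0 = 0.25  # held-out, inside the training range
        inferred = infer_null(table, np.array([r0]))
        cum = np.append(expit(beta[:, 0] + beta[:, 1] * r0), 1.0)
        truth = np.diff(cum, prepend=0.0)
        corr = np.corrcoef(inferred.density, truth)[0, 1]
        assert corr > 0.99

    def test_inferred_null_feeds_pvalue_machinery(self):
        table = CoefficientTable(
            beta=np.array([[logit(0.2), 0.0], [logit(0.5), 0.0]]), bin_width=1 / 3
        )
        null = infer_null(table, np.array([0.0]))
        from permfdr import pvalue

        assert pvalue(null, 0.5) == pytest.approx(0.8)


def test_coefficient_table_tsv_round_trip(tmp_path):
    beta = family_beta(12)
    table = CoefficientTable(beta=beta, bin_width=1 / 12, loss="huber", clip_eps=1e-5)
    path = tmp_path / "coeffs.tsv"
    table.to_tsv(path)
    back = CoefficientTable.from_tsv(path)
    assert np.allclose(back.beta, table.beta)
    assert back.loss == "huber"
    assert back.clip_eps == 1e-5
    assert back.bin_width == table.bin_width
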