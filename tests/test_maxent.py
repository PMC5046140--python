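"""Maximum-entropy SDM: fitting, prediction, AUC, contributions, ranges."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pinehab.maxent import (
    ResponseCurve,
    auc,
    auc_score,
    fit_maxent,
    load_model,
    optimal_range,
    percent_contribution,
    predict_values,
    response_curve,
    save_model,
    select_factors,
    split_presence,
)


def brute_force_auc(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def gibbs_sample():
    """Presence drawn from a known one-feature Gibbs model, lambda = 2."""
    rng = np.random.default_rng(11)
    bg = rng.uniform(0, 1, (5000, 1))
    q = np.exp(2 * bg[:, 0])
    q /= q.sum()
    pres = bg[rng.choice(5000, 2000, p=q)]
    return pres, bg


class TestFit:
    def test_empty_feature_set_is_uniform(self, gibbs_sample):
        pres, bg = gibbs_sample
        m = fit_maxent(pres, bg, names=("v",), classes=())
        raw = predict_values(m, bg, output="raw")
        np.testing.assert_allclose(raw, 1.0 / len(bg))

    def test_empty_feature_set_logistic_half(self, gibbs_sample):
        pres, bg = gibbs_sample
        m = fit_maxent(pres, bg, names=("v",), classes=())
        np.testing.assert_allclose(
            predict_values(m, bg[:5], output="logistic"), 0.5
        )

    def test_linear_coefficient_recovery(self, gibbs_sample):
        pres, bg = gibbs_sample
        m = fit_maxent(pres, bg, names=("v",), classes=("linear",), beta=0.0)
        assert m.coefficients[0] == pytest.approx(2.0, abs=0.2)

    def test_background_duplication_invariance(self, gibbs_sample):
        pres, bg = gibbs_sample
        m1 = fit_maxent(pres, bg[:500], names=("v",), classes=("linear",))
        m2 = fit_maxent(pres, np.vstack([bg[:500], bg[:500]]), names=("v",),
                        classes=("linear",))
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-4)

    def test_constant_variable_dropped_with_warning(self, gibbs_sample):
        pres, bg = gibbs_sample
        pres2 = np.column_stack([pres, np.ones(len(pres))])
        bg2 = np.column_stack([bg, np.ones(len(bg))])
        with pytest.warns(UserWarning, match="constant"):
            m = fit_maxent(pres2, bg2, names=("v", "const"))
        assert m.feature_set.names == ("v",)

    def test_objective_monotone_nonincreasing(self, gibbs_sample):
        """The regularized log-likelihood never worsens across iterations."""
        pres, bg = gibbs_sample
        m = fit_maxent(pres, bg, names=("v",), beta=0.01)
        path = np.array(m.objective_path)
        assert (np.diff(path) <= 1e-9).all()

    def test_predictions_invariant_to_affine_variable_rescaling(self, gibbs_sample):
        """Min-max feature scaling makes predictions invariant to affine
        rescaling of a raw variable."""
        pres, bg = gibbs_sample
        m1 = fit_maxent(pres, bg, names=("v",))
        m2 = fit_maxent(3.0 * pres + 7.0, 3.0 * bg + 7.0, names=("v",))
        np.testing.assert_allclose(
            predict_values(m2, 3.0 * bg[:100] + 7.0),
            predict_values(m1, bg[:100]),
            atol=1e-8,
        )
        assert auc(m1, pres, bg) == pytest.approx(auc(m2, 3 * pres + 7, 3 * bg + 7), abs=1e-9)

    def test_raw_sums_to_one_over_background(self, gibbs_sample):
        pres, bg = gibbs_sample
        m = fit_maxent(pres, bg, names=("v",))
        assert predict_values(m, bg, output="raw").sum() == pytest.approx(1.0, abs=1e-9)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_hand_counted_case(self):
        # pairs: (.8,.5)+ (.8,.2)+ (.3,.5)- (.3,.2)+  -> 3/4
        assert auc_score([0.8, 0.3], [0.5, 0.2]) == 0.75

    def test_identical_scores_give_half(self):
        assert auc_score([0.4, 0.4], [0.4, 0.4]) == 0.5

    def test_empty_background_error(self):
        with pytest.raises(ValueError):
            auc_score([0.5], [])

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = rng.integers(1, 100)
        n_neg = rng.integers(1, 100)
        # coarse grid of scores to force ties
        pos = rng.integers(0, 10, n_pos) / 10
        neg = rng.integers(0, 10, n_neg) / 10
        assert auc_score(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)


class TestContributions:
    def test_sum_to_100(self, gibbs_sample):
        pres, bg = gibbs_sample
        rng = np.random.default_rng(0)
        pres2 = np.column_stack([pres, rng.uniform(0, 1, len(pres))])
        bg2 = np.column_stack([bg, rng.uniform(0, 1, len(bg))])
        m = fit_maxent(pres2[:500], bg2, names=("v", "noise"))
        contrib = percent_contribution(m, pres2[:500], bg2)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.1)

    def test_noise_variable_below_informative(self, gibbs_sample):
        pres, bg = gibbs_sample
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pres2 = np.column_stack([pres[:300], rng.uniform(0, 1, 300)])
            bg2 = np.column_stack([bg[:2000], rng.uniform(0, 1, 2000)])
            m = fit_maxent(pres2, bg2, names=("v", "noise"))
            contrib = percent_contribution(m, pres2, bg2, seed=seed)
            if contrib["v"] > contrib["noise"]:
                wins += 1
        assert wins >= 18

    def test_duplicate_variables_share_equally(self, gibbs_sample):
        pres, bg = gibbs_sample
        pres2 = np.column_stack([pres, pres])
        bg2 = np.column_stack([bg, bg])
        m = fit_maxent(pres2[:500], bg2, names=("v1", "v2"))
        contrib = percent_contribution(m, pres2[:500], bg2)
        assert abs(contrib["v1"] - contrib["v2"]) < 5.0

    def test_single_variable_gets_100(self, gibbs_sample):
        pres, bg = gibbs_sample
        m = fit_maxent(pres[:500], bg, names=("v",))
        contrib = percent_contribution(m, pres[:500], bg)
        assert contrib["v"] == pytest.approx(100.0)


class TestResponseCurves:
    def test_zero_coefficient_flat_curve(self, gibbs_sample):
        pres, bg = gibbs_sample
        rng = np.random.default_rng(1)
        pres2 = np.column_stack([pres[:500], rng.uniform(0, 1, 500)])
        bg2 = np.column_stack([bg, rng.uniform(0, 1, len(bg))])
        m = fit_maxent(pres2, bg2, names=("v", "noise"), beta=0.5)
        # the heavily penalized noise variable keeps zero coefficients
        labels = m.feature_set.feature_labels
        noise_coef = [c for lbl, c in zip(labels, m.coefficients) if "noise" in lbl]
        if not np.allclose(noise_coef, 0):
            pytest.skip("noise picked up a coefficient at this seed")
        curve = response_curve(m, "noise")
        assert np.ptp(curve.response) == pytest.approx(0.0, abs=1e-12)

    def test_negative_quadratic_is_unimodal(self):
        rng = np.random.default_rng(4)
        bg = rng.uniform(-1, 1, (4000, 1))
        center = np.exp(-8 * (bg[:, 0]) ** 2)
        pres = bg[rng.choice(4000, 1500, p=center / center.sum())]
        m = fit_maxent(pres, bg, names=("v",), beta=0.01)
        curve = response_curve(m, "v")
        peak = np.argmax(curve.response)
        assert (np.diff(curve.response[: peak + 1]) >= -1e-9).all()
        assert (np.diff(curve.response[peak:]) <= 1e-9).all()

    def test_endpoints_match_range_predictions(self, gibbs_sample):
        pres, bg = gibbs_sample
        m = fit_maxent(pres, bg, names=("v",))
        curve = response_curve(m, "v")
        assert curve.grid[0] == m.feature_set.mins[0]
        assert curve.grid[-1] == m.feature_set.maxs[0]


class TestOptimalRange:
    def test_flat_curve_full_range(self):
        curve = ResponseCurve("v", np.linspace(0, 1, 11), np.full(11, 0.4))
        assert optimal_range(curve, 0.8) == (0.0, 1.0)

    def test_kt_plateau_recovered_as_fraction_to_one(self, april_precip_params):
        from pinehab.membership import kt_membership

        grid = np.linspace(-63.9, 191.3, 2001)
        curve = ResponseCurve("p", grid, kt_membership(grid, april_precip_params))
        lo, hi = optimal_range(curve, 0.999999)
        step = grid[1] - grid[0]
        assert abs(lo - 98.8) <= step
        assert abs(hi - 113.8) <= step

    def test_symmetric_unimodal_range_symmetric(self):
        grid = np.linspace(-1, 1, 801)
        curve = ResponseCurve("v", grid, np.exp(-4 * grid**2))
        lo, hi = optimal_range(curve, 0.8)
        assert abs((lo + hi) / 2) <= (grid[1] - grid[0])

    def test_noncontiguous_warns(self):
        grid = np.linspace(0, 1, 101)
        resp = np.where((grid < 0.2) | (grid > 0.8), 1.0, 0.1)
        with pytest.warns(UserWarning, match="non-contiguous"):
            optimal_range(ResponseCurve("v", grid, resp), 0.8)


class TestSelection:
    def test_k_equals_all_returns_all(self):
        contrib = {"a": 50.0, "b": 30.0, "c": 20.0}
        assert set(select_factors(contrib, k=3)) == {"a", "b", "c"}

    def test_top_k(self):
        contrib = {"A": 50.0, "B": 30.0, "C": 20.0}
        assert select_factors(contrib, k=2) == ["A", "B"]

    def test_tie_broken_by_name(self):
        contrib = {"b": 10.0, "a": 10.0, "c": 80.0}
        assert select_factors(contrib, k=2) == ["c", "a"]

    def test_informative_factors_found_among_many_candidates(self):
        """5 informative + 50 noise candidates: the informative are selected."""
        rng = np.random.default_rng(8)
        n_bg, n_pres = 3000, 1000
        informative = rng.uniform(0, 1, (n_bg, 5))
        noise = rng.uniform(0, 1, (n_bg, 50))
        bg = np.column_stack([informative, noise])
        eta = informative @ np.array([3.0, 2.5, 2.0, 2.5, 3.0])
        q = np.exp(eta)
        pres = bg[rng.choice(n_bg, n_pres, p=q / q.sum())]
        names = tuple(f"inf{j}" for j in range(5)) + tuple(f"noise{j}" for j in range(50))
        m = fit_maxent(pres, bg, names=names, classes=("linear",))
        contrib = percent_contribution(m, pres, bg, n_permutations=3)
        assert set(select_factors(contrib, k=5)) == {f"inf{j}" for j in range(5)}


class TestSplitAndSerialization:
    def test_split_fractions(self):
        train, test = split_presence(np.arange(40).reshape(20, 2), 0.25, seed=0)
        assert len(test) == 5 and len(train) == 15

    def test_model_round_trip(self, tmp_path, gibbs_sample):
        pres, bg = gibbs_sample
        m = fit_maxent(pres[:200], bg, names=("v",))
        path = tmp_path / "model.json"
        save_model(m, path)
        back = load_model(path)
        np.testing.assert_allclose(
            predict_values(back, bg[:50]), predict_values(m, bg[:50])
        )
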