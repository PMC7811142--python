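"""PLS1/NIPALS fit, LOOCV, permutation test, VIP scores, overlap z-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from viroflux.errors import DataError, ParameterError, UndefinedStatisticError
from viroflux.pls import (
    assess,
    compare_predictor_overlap,
    explained_variance,
    fit_pls,
    loocv,
    permutation_test,
    run_response_models,
    vip_scores,
)


def _random_xy(rng, n=20, p=5, noise=0.1):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFitPls:
    def test_noiseless_rank_one_signal_recovered(self, rng):
        """With orthogonal predictors, a single component reproduces a
        response carried entirely by one column."""
        X = np.linalg.qr(rng.normal(size=(12, 4)))[0][:, :4]
        X -= X.mean(axis=0)  # keep columns uncorrelated after centering
        X = np.linalg.qr(X)[0]
        y = 3.0 * X[:, 1] + 1.0
        m = fit_pls(X, y, 1)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)

    def test_full_rank_equals_least_squares(self, rng):
        """Oracle: with A = p and n > p, PLS reproduces the OLS fit."""
        for _ in range(5):
            X, y = _random_xy(rng, n=20, p=5)
            m = fit_pls(X, y, 5)
            Xd = np.column_stack([np.ones(len(y)), X])
            ols_pred = Xd @ np.linalg.lstsq(Xd, y, rcond=None)[0]
            np.testing.assert_allclose(m.predict(X), ols_pred, atol=1e-6)

    def test_matches_reference_pls_implementation(self, rng):
        """Independent cross-check against scikit-learn's PLS regression."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_xy(rng, n=30, p=8)
        m = fit_pls(X, y, 3)
        sk = PLSRegression(n_components=3, scale=True).fit(X, y)
        np.testing.assert_allclose(
            m.predict(X), sk.predict(X).ravel(), atol=1e-8
        )

    def test_duplicated_columns_share_weight(self, rng):
        X, y = _random_xy(rng, n=15, p=3)
        Xdup = np.column_stack([X, X[:, 0]])
        m = fit_pls(Xdup, y, 2)
        np.testing.assert_allclose(
            m.weights[0], m.weights[3], atol=1e-10
        )

    def test_score_orthogonality(self, rng):
        X, y = _random_xy(rng, n=25, p=10)
        m = fit_pls(X, y, 4)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.all(np.abs(off) < 1e-8 * np.outer(norms, norms) + 1e-12)

    def test_unit_norm_weights(self, rng):
        X, y = _random_xy(rng, n=25, p=10)
        m = fit_pls(X, y, 4)
        np.testing.assert_allclose(
            np.linalg.norm(m.weights, axis=0), 1.0, atol=1e-10
        )

    def test_too_many_components_rejected(self, rng):
        X, y = _random_xy(rng, n=6, p=10)
        with pytest.raises(ParameterError):
            fit_pls(X, y, 6)

    def test_zero_variance_column_named(self, rng):
        X, y = _random_xy(rng, n=10, p=3)
        X[:, 2] = 7.0
        with pytest.raises(DataError, match="m2"):
            fit_pls(X, y, 2, marker_ids=["m0", "m1", "m2"])


class TestLoocv:
    def test_matches_hand_rolled_loop(self, rng):
        """Oracle: an explicit leave-one-out loop around the reference
        PLS implementation, fold by fold."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_xy(rng, n=6, p=4, noise=0.3)
        ours = loocv(X, y, 1)
        for i in range(6):
            tr = np.arange(6) != i
            sk = PLSRegression(n_components=1, scale=True).fit(X[tr], y[tr])
            expected = sk.predict(X[i][None, :]).ravel()[0]
            assert ours[i] == pytest.approx(expected, abs=1e-8)

    def test_null_loocv_r2_negative_on_average(self, rng):
        """Out-of-sample R2 is negatively biased when y is independent of X."""
        r2s = []
        for _ in range(50):
            X = rng.normal(size=(20, 15))
            y = rng.normal(size=20)
            r2s.append(assess(y, loocv(X, y, 2)).r2)
        assert np.mean(r2s) <= 0.0

    def test_strong_planted_signal_recovered(self):
        """Survey-scale recovery: planted population R2 of 0.9 yields a
        strongly positive LOOCV correlation through the full filter+fit
        pipeline (rates frozen from the recovery simulation)."""
        import viroflux as vf

        rs = []
        for seed in range(10):
            sc = vf.SyntheticScenario(
                n_samples=59, n_markers=300, n_true_predictors=10,
                target_r2=0.9, seed=seed,
            )
            ab, meta, _ = vf.simulate_survey(sc)
            rel, table = vf.select_markers(ab, meta["CEE"])
            X = rel.values.loc[table.index[table["kept"]]].to_numpy().T
            y = meta["CEE"].to_numpy()
            rs.append(assess(y, loocv(X, y, 2)).r)
        assert min(rs) > 0.6
        assert np.mean(rs) > 0.75


class TestAssess:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        a = assess(y, y)
        assert a.r == pytest.approx(1.0)
        assert a.r2 == pytest.approx(1.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        a = assess(y, np.full(4, y.mean()))
        assert a.r2 == pytest.approx(0.0)

    def test_r2_unbounded_below(self, rng):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        a = assess(y, -5 * y)
        assert a.r2 < 0

    def test_identity_r2_equals_one_minus_sse_over_sst(self, rng):
        y = rng.normal(size=30)
        y_hat = y + rng.normal(size=30)
        a = assess(y, y_hat)
        assert a.r2 == pytest.approx(1 - a.sse / a.sst, abs=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            assess([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPermutationTest:
    def test_add_one_rule_floor(self, rng):
        """With a strong signal no permutation beats the observed statistic,
        so p attains its floor 1/(n_perm + 1)."""
        X = rng.normal(size=(25, 4))
        y = 5.0 * X[:, 0] + 0.05 * rng.normal(size=25)
        pr = permutation_test(X, y, 1, n_perm=99, seed=0)
        assert pr.p_value == pytest.approx(1.0 / 100.0)

    def test_deterministic_under_seed(self, rng):
        X, y = _random_xy(rng, n=12, p=4)
        p1 = permutation_test(X, y, 2, n_perm=49, seed=11).p_value
        p2 = permutation_test(X, y, 2, n_perm=49, seed=11).p_value
        assert p1 == p2

    def test_batching_does_not_change_result(self, rng):
        X, y = _random_xy(rng, n=12, p=4)
        p1 = permutation_test(X, y, 2, n_perm=60, seed=3, batch_size=7)
        p2 = permutation_test(X, y, 2, n_perm=60, seed=3, batch_size=60)
        np.testing.assert_allclose(p1.null, p2.null, atol=1e-12)

    def test_r2_statistic_selectable(self, rng):
        X, y = _random_xy(rng, n=12, p=4)
        pr = permutation_test(X, y, 1, n_perm=30, seed=5, statistic="r2")
        assert pr.statistic == "r2"
        assert 0 < pr.p_value <= 1

    def test_invalid_n_perm_rejected(self, rng):
        X, y = _random_xy(rng, n=10, p=3)
        with pytest.raises(ParameterError):
            permutation_test(X, y, 1, n_perm=0)


class TestVipScores:
    def test_single_marker_vip_is_one(self, rng):
        X = rng.normal(size=(10, 1))
        y = 2 * X[:, 0] + 0.1 * rng.normal(size=10)
        v = vip_scores(fit_pls(X, y, 1))
        assert v["vip"].iloc[0] == pytest.approx(1.0)

    def test_exchangeable_markers_get_equal_vip(self, rng):
        x = rng.normal(size=15)
        X = np.column_stack([x, x, rng.normal(size=15)])
        y = x + 0.1 * rng.normal(size=15)
        v = vip_scores(fit_pls(X, y, 2))
        assert v["vip"].iloc[0] == pytest.approx(v["vip"].iloc[1], abs=1e-8)

    def test_matches_direct_formula_transcription(self, rng):
        """Oracle: the VIP formula evaluated with explicit loops from the
        fitted matrices, outside the model class."""
        X, y = _random_xy(rng, n=20, p=6)
        m = fit_pls(X, y, 3)
        p, A = m.weights.shape
        ss = [
            m.y_loadings[a] ** 2 * float(m.scores[:, a] @ m.scores[:, a])
            for a in range(A)
        ]
        for j in range(p):
            acc = 0.0
            for a in range(A):
                wnorm = m.weights[:, a] / np.linalg.norm(m.weights[:, a])
                acc += ss[a] * wnorm[j] ** 2
            expected = np.sqrt(p * acc / sum(ss))
            assert vip_scores(m)["vip"].iloc[j] == pytest.approx(
                expected, abs=1e-10
            )

    def test_sum_of_squared_vip_equals_p(self, rng):
        for p in (3, 8, 20):
            X, y = _random_xy(rng, n=25, p=p)
            v = vip_scores(fit_pls(X, y, 2))
            assert (v["vip"] ** 2).sum() == pytest.approx(p, abs=1e-8)

    def test_threshold_strict(self, rng):
        X, y = _random_xy(rng, n=15, p=4)
        m = fit_pls(X, y, 2)
        v = vip_scores(m, threshold=float(vip_scores(m)["vip"].max()))
        assert not v["is_vip"].any()  # the maximum itself is excluded

    def test_sign_comes_from_coefficient(self, rng):
        X = rng.normal(size=(20, 2))
        y = X[:, 0] - X[:, 1] + 0.05 * rng.normal(size=20)
        v = vip_scores(fit_pls(X, y, 2))
        assert v["sign"].tolist() == ["+", "-"]


class TestExplainedVariance:
    def test_noiseless_rank_one_signal(self, rng):
        """A response aligned with a single orthogonal column is fully
        captured by the first component."""
        X = np.linalg.qr(rng.normal(size=(15, 4)))[0]
        X -= X.mean(axis=0)
        X = np.linalg.qr(X)[0]
        y = 2.0 * X[:, 0]
        fr = explained_variance(fit_pls(X, y, 2), y)
        assert fr[0] == pytest.approx(1.0, abs=1e-6)
        # an exact one-component fit truncates; any further fraction is 0
        assert fr[1:].sum() == pytest.approx(0.0, abs=1e-6)

    def test_fractions_bounded_by_one(self, rng):
        for _ in range(10):
            X, y = _random_xy(rng, n=20, p=6, noise=1.0)
            fr = explained_variance(fit_pls(X, y, 3), y)
            assert np.all(fr >= 0)
            assert fr.sum() <= 1 + 1e-8

    def test_dominant_scale_component_first(self, rng):
        hits = 0
        for _ in range(20):
            X = rng.normal(size=(30, 6))
            y = 5 * X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=30)
            fr = explained_variance(fit_pls(X, y, 2), y)
            hits += fr[0] > fr[1]
        assert hits == 20


class TestCompareOverlap:
    def test_equal_proportions_give_zero_z(self):
        z, p = compare_predictor_overlap(5, 10, 50, 100)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_z(self):
        """Oracle: pooled two-proportion z evaluated by hand for 9/10 vs 1/10:
        pooled = 0.5, se = sqrt(0.5*0.5*(2/10)), z = 0.8/se."""
        z, p = compare_predictor_overlap(9, 1, 10, 10)
        se = np.sqrt(0.25 * 0.2)
        assert z == pytest.approx(0.8 / se, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(0.8 / se), abs=1e-12)

    def test_swapping_groups_flips_sign(self):
        z1, p1 = compare_predictor_overlap(9, 1, 10, 10)
        z2, p2 = compare_predictor_overlap(1, 9, 10, 10)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_accepts_sets(self):
        z, p = compare_predictor_overlap({"a", "b"}, {"c"}, 4, 4)
        z2, _ = compare_predictor_overlap(2, 1, 4, 4)
        assert z == pytest.approx(z2)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ParameterError):
            compare_predictor_overlap(1, 1, 0, 10)


class TestRunResponseModels:
    def test_shared_predictors_increase_vip_overlap(self):
        """Responses generated from the same planted predictors share more
        VIPs than a response of independent noise."""
        import viroflux as vf

        sc = vf.SyntheticScenario(
            n_samples=59, n_markers=200, n_true_predictors=6,
            target_r2=0.85, shared_responses=("NPP",), seed=5,
        )
        ab, meta, _ = vf.simulate_survey(sc)
        results, overlap = run_response_models(
            ab, meta, responses=("CEE", "NPP", "CE150"),
            n_components=2, vip_threshold=1.5,
        )
        pair = {
            (r["response_a"], r["response_b"]): r["n_shared"]
            for _, r in overlap.iterrows()
        }
        assert pair[("CEE", "NPP")] > pair[("CEE", "CE150")]

    def test_single_response_degenerate_overlap(self, toy_abundance, toy_cee):
        import viroflux as vf

        sc = vf.SyntheticScenario(
            n_samples=30, n_markers=60, n_true_predictors=4,
            target_r2=0.8, seed=2,
        )
        ab, meta, _ = vf.simulate_survey(sc)
        _, overlap = run_response_models(ab, meta, responses=("CEE",))
        assert overlap.empty

    def test_missing_response_column_named(self):
        import viroflux as vf

        sc = vf.SyntheticScenario(
            n_samples=20, n_markers=40, n_true_predictors=3,
            target_r2=0.8, seed=3,
        )
        ab, meta, _ = vf.simulate_survey(sc)
        with pytest.raises(DataError, match="T100"):
            run_response_models(
                ab, meta.drop(columns=["T100"]), responses=("T100",)
            )
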