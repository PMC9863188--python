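"""BCH correction, weighted multinomial regression, IP weighting."""

import numpy as np
import pandas as pd
import pytest

from symptomlca import (
    BCHMultinomialLogit,
    bch_distal,
    bch_multinomial_regression,
    bch_weights,
    classification_matrix,
    ip_weights,
    modal_assignment,
)
from symptomlca.three_step import _distal_percents


class TestModalAssignment:
    @pytest.mark.parametrize(
        "row, expected",
        [([0.2, 0.5, 0.3], 1), ([0.5, 0.5], 0), ([0.0, 0.0, 1.0], 2)],
    )
    def test_argmax_with_tie_to_lowest(self, row, expected):
        assert modal_assignment(np.array([row]))[0] == expected


class TestClassificationMatrix:
    def test_one_hot_gives_identity(self):
        post = np.eye(3)[np.array([0, 1, 2, 0, 1])]
        assert np.allclose(classification_matrix(post), np.eye(3))

    def test_hand_computed_weighted_shares(self):
        post = np.array([[0.7, 0.3], [0.4, 0.6]])
        D = classification_matrix(post)
        assert np.allclose(D[0], [0.7 / 1.1, 0.4 / 1.1])
        assert np.allclose(D[1], [0.3 / 0.9, 0.6 / 0.9])

    def test_uniform_posteriors_give_modal_shares(self):
        post = np.full((4, 2), 0.5)
        # tie rule sends everyone to class 0
        D = classification_matrix(post)
        assert np.allclose(D, [[1.0, 0.0], [1.0, 0.0]])

    def test_rows_sum_to_one(self, high_sep_fit):
        model, _, _ = high_sep_fit
        D = classification_matrix(model.posteriors_)
        assert np.allclose(D.sum(axis=1), 1.0, atol=1e-12)


class TestBCHWeights:
    def test_identity_gives_one_hot(self):
        modal = np.array([0, 1, 1, 0])
        u = bch_weights(np.eye(2), modal)
        assert np.allclose(u, np.eye(2)[modal])

    def test_two_by_two_hand_inverse(self):
        D = np.array([[0.9, 0.1], [0.2, 0.8]])
        u = bch_weights(D, np.array([0]))
        assert np.allclose(u[0], [0.8 / 0.7, -0.1 / 0.7])
        assert u[0, 0] == pytest.approx(1.1429, abs=2e-4)
        assert u[0, 1] == pytest.approx(-0.1429, abs=2e-4)

    def test_row_sums_always_one(self, high_sep_fit):
        model, _, _ = high_sep_fit
        post = model.posteriors_
        modal = modal_assignment(post)
        u = bch_weights(classification_matrix(post, modal), modal)
        assert np.allclose(u.sum(axis=1), 1.0, atol=1e-10)

    def test_column_sums_estimate_class_sizes(self, high_sep_fit):
        model, _, _ = high_sep_fit
        post = model.posteriors_
        modal = modal_assignment(post)
        u = bch_weights(classification_matrix(post, modal), modal)
        assert np.allclose(u.sum(axis=0), post.sum(axis=0), atol=1e-6)

    def test_near_singular_D_is_error(self):
        D = np.array([[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(np.linalg.LinAlgError, match="entropy"):
            bch_weights(D, np.array([0, 1]))


class TestBCHDistal:
    def test_perfect_classification_gives_raw_proportions(self):
        modal = np.array([0] * 6 + [1] * 4)
        u = np.eye(2)[modal]
        y = pd.Series(["a", "a", "b", "b", "b", "b", "a", "b", "b", "b"])
        tab = bch_distal(u, y, n_bootstrap=0)
        got = tab.set_index(["class", "category"])["percent"]
        assert got.loc[(0, "a")] == pytest.approx(100 * 2 / 6)
        assert got.loc[(1, "a")] == pytest.approx(25.0)

    def test_single_category_outcome(self):
        u = np.eye(2)[np.array([0, 1, 0])]
        tab = bch_distal(u, pd.Series(["only"] * 3), n_bootstrap=0)
        assert (tab["percent"] == 100.0).all()

    def test_percentages_sum_to_100_per_class(self, high_sep_fit):
        model, _, cohort = high_sep_fit
        post = model.posteriors_
        modal = modal_assignment(post)
        u = bch_weights(classification_matrix(post, modal), modal)
        y = cohort.outcome_categories["gp_category"].astype(str)
        tab = bch_distal(u, y, n_bootstrap=20, seed=0)
        sums = tab.groupby("class")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_negative_cells_clipped(self):
        u = np.array([[1.2, -0.2], [1.2, -0.2], [-0.1, 1.1]])
        pct = _distal_percents(u, np.array([0, 0, 1]), 2)
        assert (pct >= 0).all()
        assert np.allclose(pct.sum(axis=1), 100.0)

    def test_nonpositive_class_weight_is_error(self):
        u = np.array([[1.5, -0.5], [1.5, -0.5]])
        with pytest.raises(ValueError, match="non-positive"):
            _distal_percents(u, np.array([0, 1]), 2)


class TestBCHMultinomialRegression:
    def test_perfect_classification_matches_crosstab_ors(self):
        """With one-hot weights the weighted MLE is the closed-form 2xC table OR."""
        rng = np.random.default_rng(4)
        n = 1200
        z = rng.integers(0, 3, n)
        x = (rng.random(n) < np.where(z == 0, 0.3, np.where(z == 1, 0.5, 0.6))).astype(int)
        u = np.eye(3)[z]
        cov = pd.DataFrame({"x": pd.Categorical(np.where(x == 1, "yes", "no"),
                                                categories=["no", "yes"])})
        table, model = bch_multinomial_regression(cov, u, reference=0, n_bootstrap=0)
        tab = pd.crosstab(pd.Series(z), pd.Series(x))
        for c in (1, 2):
            or_hand = (tab.loc[c, 1] * tab.loc[0, 0]) / (tab.loc[c, 0] * tab.loc[0, 1])
            got = table.loc[table["class"] == c, "OR"].iloc[0]
            assert got == pytest.approx(or_hand, rel=1e-4)

    def test_reference_class_or_is_implicitly_one(self):
        rng = np.random.default_rng(1)
        u = np.eye(2)[rng.integers(0, 2, 300)]
        cov = pd.DataFrame({"x": rng.integers(0, 2, 300).astype(float)})
        table, model = bch_multinomial_regression(cov, u, reference="largest", n_bootstrap=0)
        assert model.reference_class_ == int(np.argmax(u.sum(axis=0)))
        assert model.reference_class_ not in set(table["class"])

    def test_agrees_with_sklearn_on_nonnegative_weights(self):
        """Independent cross-check against sklearn's multinomial logit."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(7)
        n = 800
        x = rng.normal(size=n)
        logits = np.stack([np.zeros(n), 0.8 * x - 0.2, -0.5 * x + 0.1], axis=1)
        p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        z = np.array([rng.choice(3, p=pi) for pi in p])
        u = np.eye(3)[z]
        cov = pd.DataFrame({"x": x})
        model = BCHMultinomialLogit(reference=0).fit(cov, u)
        sk = LogisticRegression(C=np.inf, max_iter=2000).fit(x[:, None], z)
        # sklearn uses a symmetric parameterization; compare contrasts vs class 0
        sk_beta = sk.coef_[:, 0] - sk.coef_[0, 0]
        sk_int = sk.intercept_ - sk.intercept_[0]
        ours = model.coef_
        assert ours[:, 1] == pytest.approx(sk_beta[1:], abs=1e-3)
        assert ours[:, 0] == pytest.approx(sk_int[1:], abs=1e-3)

    def test_missing_covariates_rejected(self):
        u = np.eye(2)[np.array([0, 1, 0])]
        cov = pd.DataFrame({"x": [1.0, np.nan, 0.0]})
        with pytest.raises(ValueError, match="complete-case"):
            BCHMultinomialLogit().fit(cov, u)

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        n = 500
        z = rng.integers(0, 2, n)
        x = (rng.random(n) < np.where(z == 0, 0.3, 0.6)).astype(float)
        u = np.eye(2)[z]
        table, _ = bch_multinomial_regression(
            pd.DataFrame({"x": x}), u, reference=0, n_bootstrap=60, seed=2
        )
        r = table.iloc[0]
        assert r["ci_low"] <= r["OR"] <= r["ci_high"]


class TestIPWeights:
    def _fit_ipw(self, rng, n=1500, confounded=False):
        z = rng.integers(0, 2, n)
        p_yes = np.where(z == 1, 0.7, 0.3) if confounded else np.full(n, 0.5)
        x = np.where(rng.random(n) < p_yes, "yes", "no")
        cov = pd.DataFrame({"x": pd.Categorical(x, categories=["no", "yes"])})
        u = np.eye(2)[z]
        _, model = bch_multinomial_regression(cov, u, reference=0, n_bootstrap=0)
        return ip_weights(model, cov, u), cov, u, z

    def test_independent_covariates_give_unit_weights(self):
        ipw, _, u, _ = self._fit_ipw(np.random.default_rng(3), confounded=False)
        active = u > 0.5
        assert np.abs(ipw.weights[active] - 1.0).max() < 0.15
        mean_w = (u * ipw.weights).sum() / u.sum()
        assert mean_w == pytest.approx(1.0, abs=0.05)

    def test_confounded_covariates_balance_after_weighting(self):
        ipw, _, _, _ = self._fit_ipw(np.random.default_rng(8), confounded=True)
        assert (ipw.smd_before["smd"] > 0.5).all()  # strongly imbalanced before
        assert (ipw.smd_after["smd"] < 0.1).all()

    def test_weighted_distribution_matches_marginal(self):
        """After IP weighting each class's covariate distribution is the marginal."""
        ipw, cov, u, z = self._fit_ipw(np.random.default_rng(12), confounded=True)
        x = (cov["x"] == "yes").to_numpy(float)
        marginal = x.mean()
        w = np.clip(u * ipw.weights, 0, None)
        for c in range(2):
            weighted_mean = (w[:, c] * x).sum() / w[:, c].sum()
            assert weighted_mean == pytest.approx(marginal, abs=0.03)
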