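"""Latent class model: likelihood, EM steps, multi-start fitting, df arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomlca import (
    LatentClassModel,
    LCAParams,
    count_parameters,
    degrees_of_freedom,
    e_step,
    fit_em,
    log_likelihood,
    m_step,
)
from symptomlca.lca import DegenerateClassError, canonical_order
from symptomlca.synthetic import generate_cohort, implied_rho, scenario_library
from symptomlca import build_indicator_matrix

from conftest import align_classes


def make_params(gamma, rho_list):
    """Build LCAParams from per-item (C, K_j) tables."""
    C = len(gamma)
    K = [r.shape[1] for r in rho_list]
    rho = np.zeros((C, len(rho_list), max(K)))
    for j, r in enumerate(rho_list):
        rho[:, j, : K[j]] = r
    return LCAParams(gamma=np.asarray(gamma, float), rho=rho, K=K)


def enumerate_loglik(gamma, rho_list, patterns, counts):
    """Independent oracle: brute-force mixture probability per response pattern."""
    total = 0.0
    for pat, cnt in zip(patterns, counts):
        prob = 0.0
        for c, g in enumerate(gamma):
            p = g
            for j, level in enumerate(pat):
                if level >= 0:
                    p *= rho_list[j][c, level]
            prob += p
        total += cnt * math.log(prob)
    return total


class TestLogLikelihood:
    def test_one_class_single_binary_item(self):
        params = make_params([1.0], [np.array([[0.5, 0.5]])])
        data = pd.DataFrame({"x": [0, 1, 0, 1]})
        assert log_likelihood(params, data) == pytest.approx(4 * math.log(0.5), abs=1e-12)

    def test_matches_enumeration_oracle(self, toy_binary_data):
        data, patterns, counts = toy_binary_data
        gamma = [0.3, 0.7]
        rho_list = [
            np.array([[0.8, 0.2], [0.3, 0.7]]),
            np.array([[0.6, 0.4], [0.1, 0.9]]),
            np.array([[0.55, 0.45], [0.25, 0.75]]),
        ]
        params = make_params(gamma, rho_list)
        expected = enumerate_loglik(gamma, rho_list, patterns, counts)
        assert log_likelihood(params, data) == pytest.approx(expected, abs=1e-10)

    def test_all_missing_row_contributes_zero(self):
        params = make_params([0.4, 0.6], [np.array([[0.8, 0.2], [0.3, 0.7]])])
        base = pd.DataFrame({"x": [0.0, 1.0]})
        with_missing = pd.DataFrame({"x": [0.0, 1.0, np.nan]})
        assert log_likelihood(params, with_missing) == pytest.approx(
            log_likelihood(params, base), abs=1e-12
        )

    def test_invariant_under_class_relabelling(self, toy_binary_data):
        data, _, _ = toy_binary_data
        rng = np.random.default_rng(5)
        for _ in range(5):
            gamma = rng.dirichlet(np.ones(3))
            rho_list = [rng.dirichlet(np.ones(2), size=3) for _ in range(3)]
            params = make_params(gamma, rho_list)
            perm = rng.permutation(3)
            permuted = make_params(gamma[perm], [r[perm] for r in rho_list])
            assert log_likelihood(params, data) == pytest.approx(
                log_likelihood(permuted, data), abs=1e-10
            )


class TestESte:
    def test_single_class_posterior_is_one(self):
        params = make_params([1.0], [np.array([[0.7, 0.3]])])
        post = e_step(params, pd.DataFrame({"x": [0, 1, 1]}))
        assert np.allclose(post, 1.0)

    def test_all_missing_row_returns_prior(self):
        params = make_params([0.25, 0.75], [np.array([[0.8, 0.2], [0.3, 0.7]])])
        post = e_step(params, pd.DataFrame({"x": [np.nan]}))
        assert np.allclose(post[0], [0.25, 0.75], atol=1e-12)

    def test_matches_hand_bayes_rule(self):
        # Two classes, one binary item, response 1:
        # p(c=0|1) = .5*.2 / (.5*.2 + .5*.9)
        params = make_params([0.5, 0.5], [np.array([[0.8, 0.2], [0.1, 0.9]])])
        post = e_step(params, pd.DataFrame({"x": [1]}))
        assert post[0, 0] == pytest.approx(0.1 / 0.55, abs=1e-12)

    def test_rows_sum_to_one(self, toy_binary_data):
        data, _, _ = toy_binary_data
        rng = np.random.default_rng(2)
        params = make_params(
            rng.dirichlet(np.ones(3)), [rng.dirichlet(np.ones(2), size=3) for _ in range(3)]
        )
        post = e_step(params, data)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_one_hot_posteriors_give_sample_shares(self):
        data = pd.DataFrame({"x": [0, 0, 1, 1, 1, 0]})
        post = np.zeros((6, 2))
        post[:3, 0] = 1
        post[3:, 1] = 1
        params = m_step(post, data, eps=0)
        assert np.allclose(params.gamma, [0.5, 0.5])
        assert np.allclose(params.rho[0, 0, :2], [2 / 3, 1 / 3])
        assert np.allclose(params.rho[1, 0, :2], [1 / 3, 2 / 3])

    def test_uniform_posteriors_give_marginals(self):
        data = pd.DataFrame({"x": [0, 0, 0, 1]})
        post = np.full((4, 2), 0.5)
        params = m_step(post, data, eps=0)
        assert np.allclose(params.rho[:, 0, :2], [[0.75, 0.25], [0.75, 0.25]])

    def test_empty_class_mass_is_error(self):
        data = pd.DataFrame({"x": [0, 1]})
        post = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateClassError):
            m_step(post, data)

    def test_em_fixed_point(self, toy_binary_data):
        """At the MLE, one more EM cycle changes nothing."""
        data, _, _ = toy_binary_data
        fit = fit_em(data, C=2, n_starts=10, seed=3, tol=1e-10, ll_tol=1e-13)
        params = fit.params
        refreshed = m_step(e_step(params, data), data)
        assert np.allclose(refreshed.gamma, params.gamma, atol=1e-6)
        assert np.allclose(refreshed.rho, params.rho, atol=1e-6)


class TestFitEM:
    def test_one_class_closed_form(self):
        data = pd.DataFrame({"a": [0, 1, 1, 2], "b": [0, 0, 1, 1]})
        fit = fit_em(data, C=1, seed=0)
        assert fit.converged and fit.n_iter == 1
        assert fit.params.gamma[0] == pytest.approx(1.0)
        assert np.allclose(fit.params.rho[0, 0, :3], [0.25, 0.5, 0.25], atol=1e-5)

    def test_determinism(self, high_sep_cohort):
        ind = build_indicator_matrix(high_sep_cohort.survey).iloc[:400]
        f1 = fit_em(ind, C=3, n_starts=4, seed=42, tol=1e-5, max_iter=500)
        f2 = fit_em(ind, C=3, n_starts=4, seed=42, tol=1e-5, max_iter=500)
        assert f1.loglik == f2.loglik
        assert np.array_equal(f1.params.gamma, f2.params.gamma)
        assert np.array_equal(f1.params.rho, f2.params.rho)
        assert np.array_equal(f1.posteriors, f2.posteriors)

    def test_loglik_is_max_of_start_logliks(self, high_sep_fit):
        model, _, _ = high_sep_fit
        fit = model.result_
        assert fit.loglik == pytest.approx(np.max(fit.start_logliks), abs=1e-8)

    def test_classes_in_canonical_order(self, high_sep_fit):
        model, _, _ = high_sep_fit
        g = model.gamma_
        assert all(g[i] >= g[i + 1] for i in range(len(g) - 1))

    def test_posterior_rows_and_simplexes(self, high_sep_fit):
        model, _, _ = high_sep_fit
        assert np.allclose(model.posteriors_.sum(axis=1), 1.0, atol=1e-10)
        assert model.gamma_.sum() == pytest.approx(1.0, abs=1e-10)
        for j, k in enumerate(model.item_levels_):
            assert np.allclose(model.rho_[:, j, :k].sum(axis=1), 1.0, atol=1e-8)

    def test_parameter_recovery_well_separated(self):
        spec = scenario_library()["high_separation"]
        spec.n = 5000
        cohort = generate_cohort(spec, seed=21, render_records=False)
        ind = build_indicator_matrix(cohort.survey)
        fit = fit_em(ind, C=4, n_starts=8, seed=21, tol=1e-6, max_iter=2000)
        rho_true = implied_rho(spec)
        perm = align_classes(fit.params.rho[:, :, :3], rho_true)
        gamma_err = np.abs(fit.params.gamma[perm] - spec.gamma).max()
        rho_err = np.abs(fit.params.rho[perm][:, :, :3] - rho_true).max()
        assert gamma_err < 0.02
        assert rho_err < 0.03


class TestParameterCounts:
    @pytest.mark.parametrize(
        "J, K, C, expected",
        [(16, 3, 4, 131), (16, 3, 1, 32), (1, 2, 1, 1), (3, [2, 3, 4], 2, 13)],
    )
    def test_count_parameters(self, J, K, C, expected):
        assert count_parameters(J, K, C) == expected

    @pytest.mark.parametrize(
        "C, expected",
        [(1, 43_046_688), (2, 43_046_655), (3, 43_046_622),
         (4, 43_046_589), (5, 43_046_556), (6, 43_046_523)],
    )
    def test_df_sixteen_trichotomous_items(self, C, expected):
        assert degrees_of_freedom(16, 3, C) == expected

    def test_df_small_case(self):
        assert degrees_of_freedom(2, 2, 1) == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            count_parameters(0, 3, 2)
        with pytest.raises(ValueError):
            count_parameters(2, 1, 2)


@given(st.integers(min_value=1, max_value=6))
@settings(max_examples=6, deadline=None)
def test_df_matches_parameter_identity(C):
    """df + P + 1 always reconstructs the full contingency table size."""
    assert degrees_of_freedom(16, 3, C) + count_parameters(16, 3, C) + 1 == 3**16


def test_canonical_order_sorts_by_gamma():
    rho = np.zeros((2, 1, 2))
    rho[:, 0, :] = [[0.9, 0.1], [0.2, 0.8]]
    params = LCAParams(gamma=np.array([0.3, 0.7]), rho=rho, K=[2])
    ordered = canonical_order(params)
    assert np.allclose(ordered.gamma, [0.7, 0.3])
    assert np.allclose(ordered.rho[0, 0], [0.2, 0.8])


def test_estimator_sklearn_interface(high_sep_fit):
    model, ind, _ = high_sep_fit
    params = model.get_params()
    assert params["n_classes"] == 4
    clone_params = LatentClassModel(**params).get_params()
    assert clone_params == params
    proba = model.predict_proba(ind.iloc[:50])
    assert proba.shape == (50, 4)
    assert np.allclose(proba.sum(axis=1), 1.0)
    labels = model.predict(ind.iloc[:50])
    assert np.array_equal(labels, np.argmax(proba, axis=1))
    assert model.score(ind) == pytest.approx(model.loglik_ / len(ind), rel=1e-9)
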