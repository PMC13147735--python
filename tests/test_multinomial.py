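import json

import numpy as np
import pytest

from asmd_sit.multinomial import (CLASS_ORDER, ModelSpec,
                                  MultinomialSymptomModel,
                                  MultinomialSymptomResults, SchemaError,
                                  fit_multinomial, load_model, save_model)

from oracles import softmax_by_hand


def _simulate(beta, n, seed, k=3, prev=(0.4, 0.5, 0.6)):
    """Draw (y, X) from a known reference-coded coefficient matrix."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, k)) < np.asarray(prev)).astype(np.int64)
    eta = np.column_stack([beta[i, 0] + X @ beta[i, 1:] for i in range(2)])
    eta = np.column_stack([eta, np.zeros(n)])
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    y = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)
    return y, X


def _results_from_params(params, variables, reference_class="non_case"):
    spec = ModelSpec(variables=tuple(variables), reference_class=reference_class)
    model = MultinomialSymptomModel(
        np.array([0, 1, 2]), np.zeros((3, len(variables)), dtype=np.int64), spec)
    nonref = tuple(c for c in CLASS_ORDER if c != reference_class)
    return MultinomialSymptomResults(
        model=model, params=np.asarray(params, float),
        bse=np.full_like(np.asarray(params, float), np.nan), llf=0.0,
        converged=True, llf_history=[], nonref_classes=nonref, n_obs=3)


class TestFit:
    def test_intercept_only_recovers_class_frequencies(self):
        y = np.array([0] * 10 + [1] * 10 + [2] * 10)
        res = MultinomialSymptomModel(
            y, np.zeros((30, 0), dtype=np.int64),
            ModelSpec(variables=(), ridge_penalty=0.0)).fit()
        probs = res.predict_proba(np.zeros((1, 0)))
        assert probs == pytest.approx([1 / 3, 1 / 3, 1 / 3], abs=1e-9)

    def test_unbalanced_intercept_only(self):
        y = np.array([0] * 6 + [1] * 14 + [2] * 20)
        res = MultinomialSymptomModel(
            y, np.zeros((40, 0), dtype=np.int64),
            ModelSpec(variables=(), ridge_penalty=0.0)).fit()
        probs = res.predict_proba(np.zeros((1, 0)))
        assert probs == pytest.approx([0.15, 0.35, 0.5], abs=1e-9)

    def test_perfect_separation_stays_finite_with_ridge(self):
        y = np.array([0] * 20 + [1] * 20 + [2] * 20)
        X = (y == 0).astype(np.int64)[:, None]
        res = MultinomialSymptomModel(
            y, X, ModelSpec(variables=("s",), ridge_penalty=1e-2)).fit()
        assert res.converged
        assert np.isfinite(res.params).all()

    def test_loglik_monotone_over_iterations(self):
        beta = np.array([[0.3, 1.0, -0.5, 0.2], [-0.2, 0.4, 0.8, -1.0]])
        y, X = _simulate(beta, 2000, seed=5)
        res = MultinomialSymptomModel(
            y, X, ModelSpec(variables=("a", "b", "c"))).fit()
        h = res.llf_history
        assert all(b >= a - 1e-9 for a, b in zip(h, h[1:]))

    def test_parameter_recovery_within_three_se(self):
        beta = np.array([[0.5, 1.2, -0.7, 0.4], [-0.3, 0.5, 0.9, -1.1]])
        y, X = _simulate(beta, 8000, seed=7)
        res = MultinomialSymptomModel(
            y, X, ModelSpec(variables=("a", "b", "c"), ridge_penalty=1e-4)).fit()
        z = np.abs(res.params - beta) / res.bse
        assert z.max() < 3.0

    def test_matches_sklearn_unpenalized(self):
        from sklearn.linear_model import LogisticRegression
        beta = np.array([[0.3, 0.8, -0.5, 0.0], [-0.1, 0.0, 0.6, -0.8]])
        y, X = _simulate(beta, 3000, seed=11)
        res = MultinomialSymptomModel(
            y, X, ModelSpec(variables=("a", "b", "c"), ridge_penalty=0.0)).fit()
        sk = LogisticRegression(C=np.inf, tol=1e-10, max_iter=5000).fit(X, y)
        grid = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)])
        assert np.abs(np.atleast_2d(res.predict_proba(grid))
                      - sk.predict_proba(grid)).max() < 1e-5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            MultinomialSymptomModel(
                np.zeros(10, dtype=int), np.zeros((10, 1), dtype=np.int64),
                ModelSpec(variables=("s",)))

    def test_reference_class_relabeling_keeps_probabilities(self):
        beta = np.array([[0.3, 1.0, -0.5, 0.2], [-0.2, 0.4, 0.8, -1.0]])
        y, X = _simulate(beta, 2000, seed=3)
        grid = np.array([[0, 0, 0], [1, 1, 0], [1, 0, 1]])
        probs = {}
        for ref in CLASS_ORDER:
            res = MultinomialSymptomModel(
                y, X, ModelSpec(variables=("a", "b", "c"), ridge_penalty=0.0,
                                reference_class=ref)).fit()
            probs[ref] = np.atleast_2d(res.predict_proba(grid))
        for ref in CLASS_ORDER[1:]:
            assert np.abs(probs[ref] - probs["non_case"]).max() < 1e-6


class TestPredict:
    def test_zero_coefficients_give_uniform(self):
        res = _results_from_params(np.zeros((2, 3)), ("v1", "v2"))
        assert res.predict_proba({"v1": 1, "v2": 0}) == pytest.approx(
            [1 / 3, 1 / 3, 1 / 3])

    def test_huge_case_intercept_saturates(self):
        params = np.zeros((2, 1))
        params[0, 0] = 50.0  # first non-reference class is 'case'
        res = _results_from_params(params, ())
        probs = res.predict_proba(np.zeros((1, 0)))
        assert probs[CLASS_ORDER.index("case")] >= 1 - 1e-20

    def test_matches_hand_softmax(self):
        params = np.array([[0.4, 1.1, -0.6], [-0.2, 0.3, 0.9]])
        res = _results_from_params(params, ("v1", "v2"))
        x = (1, 0)
        expected = softmax_by_hand(params[:, 0], params[:, 1:], x)
        got = res.predict_proba({"v1": 1, "v2": 0})
        # hand oracle lists (case, control) then the reference class
        assert got == pytest.approx([expected[0], expected[1], expected[2]])

    def test_probabilities_sum_to_one_and_positive(self):
        params = np.array([[3.4, -2.1, 0.6], [-1.2, 4.3, 0.9]])
        res = _results_from_params(params, ("v1", "v2"))
        grid = np.array([[i, j] for i in (0, 1) for j in (0, 1)])
        probs = np.atleast_2d(res.predict_proba(grid))
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-12
        assert (probs > 0).all()

    def test_missing_variable_named_in_error(self):
        res = _results_from_params(np.zeros((2, 3)), ("v1", "v2"))
        with pytest.raises(KeyError, match="v2"):
            res.predict_proba({"v1": 1})

    def test_non_binary_pattern_rejected(self):
        res = _results_from_params(np.zeros((2, 3)), ("v1", "v2"))
        with pytest.raises(ValueError, match="0/1"):
            res.predict_proba({"v1": 0.5, "v2": 0})


class TestSerialization:
    def _fitted(self):
        beta = np.array([[0.3, 1.0, -0.5], [-0.2, 0.4, 0.8]])
        y, X = _simulate(np.hstack([beta, np.zeros((2, 1))]), 500, seed=2)
        return MultinomialSymptomModel(
            y, X[:, :2], ModelSpec(variables=("a", "b"))).fit()

    def test_round_trip_full_precision(self, tmp_path):
        res = self._fitted()
        path = tmp_path / "model.json"
        save_model(res, path)
        back = load_model(path)
        assert back.spec.variables == res.spec.variables
        np.testing.assert_array_equal(back.params, res.params)

    def test_reloaded_model_scores_identically(self, tmp_path):
        res = self._fitted()
        path = tmp_path / "model.json"
        save_model(res, path)
        back = load_model(path)
        grid = np.array([[i, j] for i in (0, 1) for j in (0, 1)])
        np.testing.assert_array_equal(
            np.atleast_2d(res.predict_proba(grid)),
            np.atleast_2d(back.predict_proba(grid)))

    def test_truncated_file_raises_schema_error(self, tmp_path):
        res = self._fitted()
        path = tmp_path / "model.json"
        save_model(res, path)
        path.write_text(path.read_text()[:40])
        with pytest.raises(SchemaError):
            load_model(path)

    def test_wrong_schema_version_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text(json.dumps({"schema_version": 99}))
        with pytest.raises(SchemaError, match="schema_version"):
            load_model(path)


def test_from_cohort_excludes_incomplete_records(study_cohort):
    import pandas as pd
    df = study_cohort.frame.copy()
    df.loc[df.index[:25], "ataxia"] = pd.NA
    from asmd_sit import Cohort
    cohort = Cohort(df, study_cohort.catalog)
    res = fit_multinomial(cohort, ModelSpec(variables=("ataxia", "dysphagia")))
    assert res.model.n_excluded == 25
    assert res.n_obs == len(cohort) - 25
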