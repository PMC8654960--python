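"""Interventional Shapley values vs exhaustive subset enumeration."""

from itertools import combinations
from math import factorial

import numpy as np
import pytest

import vitalembed as ve
from vitalembed.evaluate import fit_downstream
from vitalembed.explain import aggregate_by_variable, summary_table, tree_attributions


def shapley_bruteforce(predict_raw, x, refs, n_features):
    """Exact interventional Shapley values by enumerating all 2^F subsets,
    per background reference, averaged."""
    feats = list(range(n_features))
    phi = np.zeros(n_features)
    for r in refs:
        def v(S):
            z = r.copy()
            z[list(S)] = x[list(S)]
            return predict_raw(z[None, :])[0]

        for i in feats:
            rest = [f for f in feats if f != i]
            for k in range(len(rest) + 1):
                w = factorial(k) * factorial(n_features - k - 1) / factorial(n_features)
                for S in combinations(rest, k):
                    phi[i] += w * (v(S + (i,)) - v(S))
    return phi / len(refs)


def _fit_toy_gbt(n_features=6, n=500, seed=0, **hp):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    logit = 1.5 * X[:, 0] - 1.0 * X[:, 1] + 0.5 * X[:, 2] * X[:, 3]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    hyper = {"num_leaves": 8, "min_data_in_leaf": 5}
    hyper.update(hp)
    return fit_downstream(X[:400], y[:400], X[400:], y[400:], seed=seed,
                          hyperparams=hyper), X


class TestTreeAttributions:
    def test_single_split_stump_closed_form(self):
        # f(x) = a if x0 <= c else b; background half in each branch:
        # phi_x0 = a - (a+b)/2 for a sample in the a-branch, others 0.
        rng = np.random.default_rng(1)
        X = np.zeros((400, 3))
        X[:, 0] = np.r_[np.full(200, -1.0), np.full(200, 1.0)]
        X[:, 1:] = rng.normal(size=(400, 2))
        y = np.r_[np.ones(200), np.zeros(200)]
        model = fit_downstream(X, y, X, y, seed=0,
                               hyperparams={"num_leaves": 2})
        background = X[[0, 1, 200, 201]]  # half per branch
        sample = X[[0]]
        res = tree_attributions(model, sample, background)
        raw = model.predict_raw(np.array([[-1.0, 0, 0], [1.0, 0, 0]]))
        a, b = raw[0], raw[1]
        assert res.phi[0, 0] == pytest.approx(a - (a + b) / 2, abs=1e-9)
        np.testing.assert_allclose(res.phi[0, 1:], 0.0, atol=1e-9)

    def test_constant_model_gives_zero_attributions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 4))
        y = (rng.random(300) < 0.3).astype(float)
        model = fit_downstream(np.ones_like(X), y, np.ones_like(X), y, seed=0)
        res = tree_attributions(model, np.ones((5, 4)), np.ones((10, 4)))
        np.testing.assert_allclose(res.phi, 0.0, atol=1e-9)
        assert res.base_value == pytest.approx(res.predictions[0])

    def test_efficiency_axiom_holds_everywhere(self):
        model, X = _fit_toy_gbt()
        res = tree_attributions(model, X[:40], X[100:160])
        np.testing.assert_allclose(
            res.phi.sum(axis=1) + res.base_value, res.predictions, atol=1e-6
        )

    def test_matches_bruteforce_enumeration_on_small_trees(self):
        """Exhaustive 2^F interventional Shapley enumeration on shallow
        ensembles (<= 8 features, depth <= 3) agrees to floating tolerance."""
        for seed, nf in ((0, 5), (1, 8)):
            model, X = _fit_toy_gbt(
                n_features=nf, seed=seed,
                num_leaves=8, max_depth=3,
            )
            samples = X[:3]
            refs = X[50:55]
            res = tree_attributions(model, samples, refs)
            for i, x in enumerate(samples):
                want = shapley_bruteforce(model.predict_raw, x, refs, nf)
                np.testing.assert_allclose(res.phi[i], want, atol=1e-8)

    def test_non_tree_model_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] > 0).astype(float)
        mlp = fit_downstream(X, y, X, y, kind="mlp", seed=0)
        with pytest.raises(ValueError):
            tree_attributions(mlp, X[:2], X[:10])


class TestAggregation:
    def _attributed(self):
        model, X = _fit_toy_gbt(n_features=6)
        res = tree_attributions(model, X[:20], X[100:140])
        provenance = ["SAO2:dim_000", "SAO2:dim_001", "ETCO2:dim_000",
                      "ETCO2:dim_001", "static:age", "static:height"]
        return aggregate_by_variable(res, provenance), res

    def test_aggregated_count_and_partition(self):
        agg, res = self._attributed()
        assert agg.aggregated.shape == (20, 4)
        assert agg.aggregated_names == ("SAO2", "ETCO2", "static:age",
                                        "static:height")
        np.testing.assert_allclose(
            agg.aggregated.sum(axis=1), res.phi.sum(axis=1), atol=1e-12
        )

    def test_efficiency_survives_summation(self):
        agg, res = self._attributed()
        np.testing.assert_allclose(
            agg.aggregated.sum(axis=1) + agg.base_value, agg.predictions,
            atol=1e-6,
        )

    def test_incomplete_provenance_rejected(self):
        _, res = self._attributed()
        with pytest.raises(ValueError):
            aggregate_by_variable(res, ["SAO2:dim_000"])

    def test_zero_attribution_variable_aggregates_to_zero(self):
        model, X = _fit_toy_gbt(n_features=6)
        res = tree_attributions(model, X[:10], X[100:120])
        res.phi[:, 4:] = 0.0
        agg = aggregate_by_variable(
            res, ["A:dim_0"] * 4 + ["static:age", "static:height"]
        )
        np.testing.assert_allclose(agg.aggregated[:, 1:], 0.0, atol=1e-12)


class TestSummaryTable:
    def test_top_k_and_dominant_variable_rank_first(self):
        _, res = (None, None)
        model, X = _fit_toy_gbt(n_features=6)
        res = tree_attributions(model, X[:15], X[100:130])
        res.phi[:, :] = 0.0
        res.phi[:, 2] = 1.0  # all attribution mass on one feature
        agg = aggregate_by_variable(
            res,
            ["V0:dim_0", "V1:dim_0", "V2:dim_0", "V3:dim_0",
             "static:age", "static:height"],
        )
        table = summary_table(agg, top_k=3)
        assert set(table["rank"]) == {1, 2, 3}
        assert table.loc[table["rank"] == 1, "variable"].iloc[0] == "V2"

    def test_ranking_invariant_to_sample_order(self):
        model, X = _fit_toy_gbt(n_features=6)
        res = tree_attributions(model, X[:12], X[100:130])
        prov = [f"V{j}:dim_0" for j in range(6)]
        t1 = summary_table(aggregate_by_variable(res, prov), top_k=2)
        perm = np.random.default_rng(0).permutation(12)
        res2 = tree_attributions(model, X[:12][perm], X[100:130])
        t2 = summary_table(aggregate_by_variable(res2, prov), top_k=2)
        assert list(t1.drop_duplicates("rank")["variable"]) == list(
            t2.drop_duplicates("rank")["variable"]
        )

    def test_top_k_must_be_positive(self):
        model, X = _fit_toy_gbt(n_features=6)
        res = tree_attributions(model, X[:5], X[100:110])
        agg = aggregate_by_variable(res, [f"V{j}:dim_0" for j in range(6)])
        with pytest.raises(ValueError):
            summary_table(agg, top_k=0)
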