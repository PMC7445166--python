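import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from toxmod.association import PhenotypeTable
from toxmod.prediction import (
    PredictionModel,
    SelectionFrequencyTable,
    build_design,
    evaluate_quantile_sets,
    impute_mode,
    predict_probability,
    quantile_sets,
    random_lasso_frequencies,
    refit_no_shrinkage,
    roc_auc,
    stratified_split,
)

warnings.filterwarnings("ignore", category=FutureWarning)


def _pheno_96():
    grades = [4] * 54 + [2] * 8 + [0] * 34
    return PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": [f"S{i:03d}" for i in range(96)],
                "grade_maximal": grades,
            }
        )
    )


class TestStratifiedSplit:
    def test_quoted_split(self):
        split = stratified_split(_pheno_96(), 0.2, seed=0)
        assert len(split.training["high"]) == 44 and len(split.validation["high"]) == 10
        assert len(split.training["low"]) == 28 and len(split.validation["low"]) == 6
        assert len(split.prediction_only) == 8

    def test_fraction_zero_all_training(self):
        split = stratified_split(_pheno_96(), 0.0, seed=0)
        assert split.validation_samples == []
        assert len(split.training_samples) == 88

    def test_determinism(self):
        a = stratified_split(_pheno_96(), 0.2, seed=5)
        b = stratified_split(_pheno_96(), 0.2, seed=5)
        assert a.training == b.training and a.validation == b.validation

    def test_disjoint_and_no_intermediate_training(self):
        split = stratified_split(_pheno_96(), 0.2, seed=1)
        assert not set(split.training_samples) & set(split.validation_samples)
        assert not set(split.prediction_only) & set(split.training_samples)

    def test_small_stratum_error(self):
        pheno = PhenotypeTable(pd.DataFrame({"sample_id": ["a", "b"], "grade_maximal": [4, 0]}))
        with pytest.raises(ValueError, match="stratum"):
            stratified_split(pheno, 0.2, seed=0)


class TestImputeAndDesign:
    def test_mode_imputation_prefers_smaller(self):
        X = pd.DataFrame({"v": [0.0, 0.0, 1.0, 1.0, np.nan]})
        assert impute_mode(X)["v"].iloc[-1] == 0.0

    def test_build_design_drops_intermediates(self):
        X = pd.DataFrame({"v": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        classes = np.array(["high", "intermediate", "low"])
        Xd, y = build_design(X, classes)
        assert list(Xd.index) == ["a", "c"]
        assert y.tolist() == [1.0, 0.0]


def _design(n=96, p=51, n_causal=1, beta=np.log(5), seed=0, maf=0.3):
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, maf, size=(n, p)).astype(float)
    eta = X[:, :n_causal].sum(axis=1) * beta
    liab = eta + rng.logistic(0, 1, n)
    y = (liab > np.median(liab)).astype(float)
    cols = [f"v{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestRandomLasso:
    def test_constant_response_error(self):
        X, _ = _design()
        with pytest.raises(ValueError, match="two classes"):
            random_lasso_frequencies(X, np.zeros(len(X)), n_perm=1)

    def test_counts_bounded(self):
        X, y = _design(p=20)
        freq = random_lasso_frequencies(X, y, n_perm=20, seed=0)
        assert (freq.counts >= 0).all() and (freq.counts <= 20).all()
        assert freq.n_perm == 20

    def test_planted_variant_outranks_null(self):
        X, y = _design(p=51, n_causal=1, beta=np.log(5), seed=3)
        freq = random_lasso_frequencies(X, y, n_perm=200, seed=1)
        null = freq.frequencies[1:]
        assert freq.frequencies[0] > np.quantile(null, 0.95)

    def test_reproducible(self):
        X, y = _design(p=15)
        a = random_lasso_frequencies(X, y, n_perm=10, seed=4)
        b = random_lasso_frequencies(X, y, n_perm=10, seed=4)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_missing_values_rejected(self):
        X, y = _design(p=5)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            random_lasso_frequencies(X, y, n_perm=1)

    def test_invalid_n_perm(self):
        X, y = _design(p=5)
        with pytest.raises(ValueError):
            random_lasso_frequencies(X, y, n_perm=0)


class TestQuantileSets:
    def _table(self, counts, n_perm=1000):
        return SelectionFrequencyTable([f"v{i}" for i in range(len(counts))], np.array(counts), n_perm)

    def test_123_distinct_gives_62(self):
        sets = quantile_sets(self._table(list(range(1, 124))), quantiles=(0.5,))
        assert len(sets[0.5]) == 62

    def test_104_distinct_gives_52(self):
        sets = quantile_sets(self._table(list(range(1, 105))), quantiles=(0.5,))
        assert len(sets[0.5]) == 52

    def test_all_ties_gives_everything(self):
        sets = quantile_sets(self._table([7] * 30))
        assert all(len(s) == 30 for s in sets.values())

    def test_nested(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(0, 1000, size=rng.integers(5, 60))
            sets = quantile_sets(self._table(list(counts)), quantiles=(0.5, 0.6, 0.7, 0.8, 0.9))
            qs = sorted(sets)
            for lo, hi in zip(qs, qs[1:]):
                assert set(sets[hi]) <= set(sets[lo])

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            quantile_sets(self._table([]))


class TestRefit:
    def test_perfect_separation_finite(self):
        X = pd.DataFrame({"v": [0.0, 0.0, 0.0, 1.0, 2.0, 2.0, 2.0, 2.0]})
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        model = refit_no_shrinkage(X, y, cv_folds=4, seed=0)
        assert np.isfinite(model.coefficients).all()
        probs = predict_probability(model, pd.DataFrame({"v": [0.0, 1.0, 2.0]}))
        assert probs[0] < probs[1] < probs[2]

    def test_null_training_auc(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.binomial(2, 0.3, size=(78, 5)).astype(float), columns=list("abcde"))
        y = (rng.random(78) < 0.5).astype(float)
        model = refit_no_shrinkage(X, y, seed=1, n_lambda=20)
        auc, _ = roc_auc(model.training_probabilities, y)
        assert abs(auc - 0.5) <= 0.15

    def test_duplicate_column_ridge_symmetry(self):
        X, y = _design(n=60, p=1, n_causal=1, seed=5)
        lam = 0.05
        single = refit_no_shrinkage(X, y, penalty_override=lam / 2)
        dup = X.copy()
        dup["v0b"] = X["v0"]
        double = refit_no_shrinkage(dup, y, penalty_override=lam)
        p1 = predict_probability(single, X)
        p2 = predict_probability(double, dup)
        np.testing.assert_allclose(p1, p2, atol=1e-6)
        np.testing.assert_allclose(double.coefficients[0], double.coefficients[1], atol=1e-6)

    def test_empty_subset_error(self):
        with pytest.raises(ValueError):
            refit_no_shrinkage(pd.DataFrame(index=[0, 1]), np.array([0.0, 1.0]))


class TestPredictProbability:
    def test_zero_model_gives_half(self):
        model = PredictionModel(["a"], 0.0, np.zeros(1), penalty=1.0)
        probs = predict_probability(model, pd.DataFrame({"a": [0.0, 1.0, 2.0]}))
        np.testing.assert_allclose(probs, 0.5)

    def test_monotone_in_positive_coefficient(self):
        model = PredictionModel(["a"], -1.0, np.array([0.8]), penalty=1.0)
        probs = predict_probability(model, pd.DataFrame({"a": [0.0, 1.0, 2.0]}))
        assert probs[0] < probs[1] < probs[2]

    def test_hand_computed(self):
        model = PredictionModel(["a", "b"], 0.5, np.array([1.0, -2.0]), penalty=1.0)
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        expected = 1 / (1 + np.exp(-(0.5 + X["a"] * 1.0 + X["b"] * -2.0)))
        np.testing.assert_allclose(predict_probability(model, X), expected)

    def test_missing_variant_error(self):
        model = PredictionModel(["a", "zz"], 0.0, np.zeros(2), penalty=1.0)
        with pytest.raises(ValueError, match="zz"):
            predict_probability(model, pd.DataFrame({"a": [1.0]}))


def _auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect(self):
        auc, roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert roc.iloc[0].tolist()[:2] == [0.0, 0.0]
        assert roc.iloc[-1].tolist()[:2] == [1.0, 1.0]

    def test_all_ties(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.random(30)
        l = rng.integers(0, 2, 30)
        l[0], l[1] = 1, 0
        a1, _ = roc_auc(s, l)
        a2, _ = roc_auc(-s, l)
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # force ties
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)


class TestEvaluateQuantileSets:
    def test_single_set_chosen(self):
        X, y = _design(n=60, p=6, n_causal=2, seed=7)
        out = evaluate_quantile_sets({0.5: list(X.columns)}, X, y, None, None, seed=0, n_lambda=20)
        assert out["chosen_quantile"] == 0.5

    def test_empty_error(self):
        with pytest.raises(ValueError):
            evaluate_quantile_sets({}, pd.DataFrame(), np.array([]), None, None)

    def test_causal_set_beats_random(self):
        wins = 0
        reps = 10
        for rep in range(reps):
            X, y = _design(n=96, p=20, n_causal=5, beta=np.log(8), seed=100 + rep, maf=0.4)
            rng = np.random.default_rng(rep)
            test_idx = rng.choice(96, 20, replace=False)
            train_idx = np.setdiff1d(np.arange(96), test_idx)
            if len(np.unique(y[test_idx])) < 2:
                continue
            causal = list(X.columns[:5])
            random_set = list(rng.choice(X.columns[5:], 5, replace=False))
            out = evaluate_quantile_sets(
                {0.1: causal, 0.2: random_set},
                X.iloc[train_idx], y[train_idx], X.iloc[test_idx], y[test_idx], seed=rep, n_lambda=20,
            )
            tab = out["table"].set_index("quantile")
            if tab.loc[0.1, "test_auc"] > tab.loc[0.2, "test_auc"]:
                wins += 1
        assert wins >= 0.9 * reps - 1
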