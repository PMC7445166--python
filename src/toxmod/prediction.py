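"""Random-LASSO selection frequencies, quantile candidate sets, ridge refit,
probability prediction, ROC/AUC, and the stratified train/validation split.

The selection-frequency procedure repeatedly fits an L1-penalized logistic
path with per-variant penalty multipliers drawn from a truncated normal,
picks the 10-fold-CV deviance-minimizing penalty, and counts which variants
received a nonzero coefficient.  Candidate sets are the variants whose
selection frequency reaches an empirical quantile; each set is refit with a
ridge (no-L1-selection) logistic model whose penalty is again chosen by CV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from ._path import lambda_sequence, lasso_logistic_path, one_permutation
from .association import HIGH, INTERMEDIATE, LOW, PhenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    training: dict[str, list[str]]      # stratum -> sample ids
    validation: dict[str, list[str]]
    prediction_only: list[str]          # intermediates: never trained on
    validation_fraction: float

    @property
    def training_samples(self) -> list[str]:
        return self.training[HIGH] + self.training[LOW]

    @property
    def validation_samples(self) -> list[str]:
        return self.validation[HIGH] + self.validation[LOW]


def stratified_split(phenotypes: PhenotypeTable, validation_fraction: float = 0.2, seed: int | None = None) -> SplitSpec:
    """Per-stratum split on the maximal-toxicity class.

    Validation takes floor(fraction * n) samples per high/low stratum,
    drawn uniformly; intermediates all go to the prediction-only pool.
    """
    if not 0 <= validation_fraction < 1:
        raise ValueError("validation_fraction must be in [0, 1)")
    classes = phenotypes.classes("maximal")
    samples = np.array(phenotypes.samples)
    rng = np.random.default_rng(seed)
    training, validation = {}, {}
    for stratum in (HIGH, LOW):
        ids = samples[classes == stratum]
        if len(ids) < 2:
            raise ValueError(f"stratum {stratum!r} has {len(ids)} sample(s); need >= 2")
        n_val = int(np.floor(validation_fraction * len(ids)))
        val_ids = rng.choice(ids, size=n_val, replace=False) if n_val else np.array([], dtype=ids.dtype)
        val_set = set(val_ids.tolist())
        training[stratum] = [s for s in ids if s not in val_set]
        validation[stratum] = [s for s in ids if s in val_set]
    prediction_only = samples[classes == INTERMEDIATE].tolist()
    return SplitSpec(training, validation, prediction_only, validation_fraction)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def impute_mode(X: pd.DataFrame) -> pd.DataFrame:
    """Fill missing dosages with the per-variant mode (ties -> smaller dosage)."""
    out = X.copy()
    for col in out.columns:
        v = out[col]
        if v.isna().any():
            observed = v.dropna()
            mode = observed.mode().min() if len(observed) else 0.0
            out[col] = v.fillna(mode)
    return out


def build_design(dosages: pd.DataFrame, classes: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Mode-imputed design matrix and binary response (high=1, low=0).

    Rows with intermediate class are dropped (they are prediction-only).
    """
    keep = np.isin(classes, (HIGH, LOW))
    X = impute_mode(dosages.loc[keep])
    y = (classes[keep] == HIGH).astype(float)
    return X, y


# ---------------------------------------------------------------------------
# Selection frequencies
# ---------------------------------------------------------------------------

@dataclass
class SelectionFrequencyTable:
    variant_ids: list[str]
    counts: np.ndarray
    n_perm: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_perm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant_id": self.variant_ids, "selection_count": self.counts, "frequency": self.frequencies}
        )


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    foldid = np.empty(y.size, dtype=np.int64)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        foldid[idx] = np.arange(idx.size) % n_folds
    return foldid


def random_lasso_frequencies(
    X: pd.DataFrame,
    y: np.ndarray,
    n_perm: int = 100_000,
    cv_folds: int = 10,
    n_lambda: int = 100,
    penalty_sd: float = 0.25,
    seed: int | None = None,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-3,
) -> SelectionFrequencyTable:
    """Accumulate selection counts over randomized-penalty LASSO rounds.

    Per round, per-variant penalty multipliers ~ Normal(1, penalty_sd)
    truncated below at 0.01; the L1 logistic path (n_lambda values) is fit
    with stratified ``cv_folds``-fold CV and every variant nonzero at the
    deviance-minimizing penalty is counted.  A master seed spawns one RNG
    per round, so results are reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("response must contain exactly two classes")
    Xv = np.ascontiguousarray(X.to_numpy(dtype=float))
    if np.isnan(Xv).any():
        raise ValueError("design matrix has missing values; impute first")
    min_class = int(min((y == c).sum() for c in classes))
    if min_class < cv_folds:
        logger.warning("smallest class (%d) < cv_folds (%d); reducing folds", min_class, cv_folds)
        cv_folds = min_class
    # glmnet-like standardization, once
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd
    XsT = np.ascontiguousarray(Xs.T)
    y01 = (y == classes.max()).astype(float)

    p = Xs.shape[1]
    counts = np.zeros(p, dtype=np.int64)
    seeds = np.random.SeedSequence(seed).spawn(n_perm)
    for t in range(n_perm):
        rng = np.random.default_rng(seeds[t])
        pf = np.clip(rng.normal(1.0, penalty_sd, size=p), 0.01, None)
        foldid = _stratified_folds(y01, cv_folds, rng)
        lambdas = lambda_sequence(Xs, y01, pf, n_lambda, lambda_min_ratio)
        mask, _ = one_permutation(XsT, y01, foldid, cv_folds, pf, lambdas, tol)
        counts += mask
    return SelectionFrequencyTable(list(X.columns), counts, n_perm)


def quantile_sets(freq_table: SelectionFrequencyTable, quantiles=(0.5, 0.6, 0.7, 0.8, 0.9)) -> dict[float, list[str]]:
    """Variants at or above each empirical frequency quantile (ties included).

    Sets are nested: a higher quantile always yields a subset.
    """
    if not freq_table.variant_ids:
        raise ValueError("empty frequency table")
    freqs = freq_table.frequencies
    out: dict[float, list[str]] = {}
    for q in quantiles:
        thr = np.quantile(freqs, q)
        out[q] = [v for v, f in zip(freq_table.variant_ids, freqs) if f >= thr]
    return out


# ---------------------------------------------------------------------------
# Ridge refit and prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionModel:
    variant_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    penalty: float                      # lambda = 1 / (C * n_train)
    training_probabilities: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variant_id": "(intercept)", "coefficient": self.intercept}]
        rows += [{"variant_id": v, "coefficient": c} for v, c in zip(self.variant_ids, self.coefficients)]
        return pd.DataFrame(rows)


def refit_no_shrinkage(
    X_subset: pd.DataFrame,
    y: np.ndarray,
    cv_folds: int = 10,
    seed: int | None = None,
    n_lambda: int = 100,
    penalty_override: float | None = None,
) -> PredictionModel:
    """Ridge (L2, no L1 selection) logistic refit of a candidate variant set.

    The penalty is chosen on a log grid by ``cv_folds``-fold CV deviance
    unless ``penalty_override`` (a lambda value) is given.  All requested
    variants keep a coefficient; ridge keeps them finite even under perfect
    separation.
    """
    if X_subset.shape[1] == 0:
        raise ValueError("empty variant subset")
    y = np.asarray(y, dtype=float)
    if np.unique(y).size != 2:
        raise ValueError("response must contain exactly two classes")
    n = X_subset.shape[0]
    Xv = X_subset.to_numpy(dtype=float)
    if penalty_override is not None:
        C = 1.0 / (penalty_override * n)
        est = LogisticRegression(C=C, solver="lbfgs", max_iter=10_000, tol=1e-10)  # L2 is the default penalty
        est.fit(Xv, y)
        lam = penalty_override
    else:
        min_class = int(min((y == c).sum() for c in np.unique(y)))
        folds = min(cv_folds, min_class)
        if folds < cv_folds:
            logger.warning("reducing CV folds to %d (smallest class)", folds)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        est = LogisticRegressionCV(
            Cs=np.logspace(-4, 4, n_lambda),
            l1_ratios=(0.0,),  # pure ridge: no L1 selection
            scoring="neg_log_loss",
            cv=cv,
            solver="lbfgs",
            max_iter=10_000,
            refit=True,
            use_legacy_attributes=False,
        )
        est.fit(Xv, y)
        lam = 1.0 / (float(np.atleast_1d(est.C_)[0]) * n)
    model = PredictionModel(
        variant_ids=list(X_subset.columns),
        intercept=float(est.intercept_[0]),
        coefficients=est.coef_[0].copy(),
        penalty=lam,
    )
    model.training_probabilities = predict_probability(model, X_subset)
    return model


def predict_probability(model: PredictionModel, X_new: pd.DataFrame) -> np.ndarray:
    """Inverse-logit of the linear predictor for new samples."""
    missing = [v for v in model.variant_ids if v not in X_new.columns]
    if missing:
        raise ValueError(f"variant(s) missing from design matrix: {', '.join(missing)}")
    Xv = X_new[model.variant_ids].to_numpy(dtype=float)
    eta = model.intercept + Xv @ model.coefficients
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC (Mann-Whitney with ties counted 1/2) and ROC points.

    ``labels`` are 1 for positives, 0 for negatives; both classes required.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted, l_sorted = scores[order], labels[order]
    tps, fps, pts = 0, 0, [(0.0, 0.0, np.inf)]
    i = 0
    while i < len(s_sorted):
        thr = s_sorted[i]
        while i < len(s_sorted) and s_sorted[i] == thr:
            if l_sorted[i] == 1:
                tps += 1
            else:
                fps += 1
            i += 1
        pts.append((fps / n_neg, tps / n_pos, thr))
    roc = pd.DataFrame(pts, columns=["fpr", "tpr", "threshold"])
    return float(auc), roc


# ---------------------------------------------------------------------------
# Candidate-set evaluation
# ---------------------------------------------------------------------------

def evaluate_quantile_sets(
    sets: dict[float, list[str]],
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame | None,
    y_test: np.ndarray | None,
    seed: int | None = None,
    cv_folds: int = 10,
    n_lambda: int = 100,
) -> dict:
    """Refit every candidate set and pick the best by test AUC.

    Ties prefer fewer variants, then higher training AUC.  Without test data
    the training AUC is used for selection (degenerate but explicit).
    """
    if not sets:
        raise ValueError("no candidate sets to evaluate")
    rows, fitted = [], {}
    for q, variants in sets.items():
        model = refit_no_shrinkage(X_train[variants], y_train, cv_folds=cv_folds, seed=seed, n_lambda=n_lambda)
        train_auc, _ = roc_auc(model.training_probabilities, y_train)
        test_auc = np.nan
        if X_test is not None and len(X_test) and y_test is not None:
            test_auc, _ = roc_auc(predict_probability(model, X_test), y_test)
        fitted[q] = model
        rows.append({"quantile": q, "n_variants": len(variants), "train_auc": train_auc, "test_auc": test_auc})
    table = pd.DataFrame(rows)
    key = table["test_auc"] if table["test_auc"].notna().all() else table["train_auc"]
    ranked = sorted(
        range(len(table)),
        key=lambda i: (-key.iloc[i], table["n_variants"].iloc[i], -table["train_auc"].iloc[i]),
    )
    best_q = float(table["quantile"].iloc[ranked[0]])
    return {"table": table, "models": fitted, "chosen_quantile": best_q, "chosen_model": fitted[best_q]}


__all__ = [
    "SplitSpec",
    "stratified_split",
    "impute_mode",
    "build_design",
    "SelectionFrequencyTable",
    "random_lasso_frequencies",
    "quantile_sets",
    "PredictionModel",
    "refit_no_shrinkage",
    "predict_probability",
    "roc_auc",
    "evaluate_quantile_sets",
    "lasso_logistic_path",
    "lambda_sequence",
]
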