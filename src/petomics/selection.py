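"""Feature-set evaluation and composite-signature selection.

Two procedures:

* :func:`repeated_cv_evaluate` — stratified k-fold cross-validation, repeated
  over several repeats and several seeds, with a random-forest classifier.
  Out-of-fold class probabilities are pooled per repeat and scored as
  ROC-AUC, sensitivity (recall on the cancer class) and specificity (recall
  on the control class) at a 0.5 probability cutoff.

* :func:`aggregated_lasso` — for each of many seeds, a 10-fold
  cross-validated L1-regularized logistic path; the penalty is chosen by the
  one-standard-error rule on the binomial-deviance curve (largest lambda with
  CV deviance within one SE of the minimum), and the nonzero-coefficient
  features at that penalty are recorded. Features selected in at least
  ``freq_cutoff`` of the seeds form the final compact signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError

__all__ = [
    "CVScheme",
    "repeated_cv_evaluate",
    "evaluate_feature_sets",
    "aggregated_lasso",
    "LassoSelection",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "cancer"


@dataclass
class CVScheme:
    """Repeated stratified k-fold scheme: n_folds x n_repeats x len(seeds)."""

    n_folds: int = 10
    n_repeats: int = 10
    seeds: tuple[int, ...] = tuple(range(10))
    stratified: bool = True
    n_trees: int = 500

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValidationError("seeds must be distinct")


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("features and labels must align (n_samples rows)")
    if np.isnan(X).any():
        raise ValidationError("missing feature values are not allowed")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {list(classes)}")
    ybin = (y == POSITIVE_LABEL).astype(int) if POSITIVE_LABEL in classes else (
        y == classes[1]
    ).astype(int)
    if ybin.sum() < 2 or (1 - ybin).sum() < 2:
        raise ValidationError("need >= 2 samples per class")
    return X, ybin


def _derive_seed(*parts) -> int:
    import hashlib

    h = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def repeated_cv_evaluate(features, labels, scheme: CVScheme = None) -> dict:
    """Evaluate one feature matrix under the repeated-CV random-forest scheme.

    Returns a dict with 'resamples' (DataFrame: seed, repeat, auc,
    sensitivity, specificity) and 'aggregate' (mean/sd per metric).
    """
    scheme = scheme or CVScheme()
    X, y = _validate_xy(features, labels)
    records = []
    for seed in scheme.seeds:
        for rep in range(scheme.n_repeats):
            skf = StratifiedKFold(
                n_splits=scheme.n_folds,
                shuffle=True,
                random_state=_derive_seed(seed, rep) if scheme.stratified else None,
            )
            prob = np.empty(len(y))
            for f, (tr, te) in enumerate(skf.split(X, y)):
                clf = RandomForestClassifier(
                    n_estimators=scheme.n_trees,
                    max_features="sqrt",
                    random_state=_derive_seed(seed, rep, f),
                    n_jobs=1,
                )
                clf.fit(X[tr], y[tr])
                prob[te] = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
            pred = (prob > 0.5).astype(int)
            records.append(
                {
                    "seed": seed,
                    "repeat": rep,
                    "auc": roc_auc_score(y, prob),
                    "sensitivity": float(pred[y == 1].mean()),
                    "specificity": float(1 - pred[y == 0].mean()),
                }
            )
    res = pd.DataFrame(records)
    agg = {
        m: {"mean": float(res[m].mean()), "sd": float(res[m].std(ddof=1)) if len(res) > 1 else 0.0}
        for m in ("auc", "sensitivity", "specificity")
    }
    return {"resamples": res, "aggregate": agg}


def evaluate_feature_sets(
    gene_features: pd.DataFrame,
    pet_features: pd.DataFrame,
    labels,
    scheme: CVScheme = None,
) -> dict:
    """Run the CV evaluation for Genes-only, PET-only and Composite sets."""
    if not gene_features.index.equals(pet_features.index):
        raise ValidationError("gene and PET feature tables must share sample order")
    composite = pd.concat([gene_features, pet_features], axis=1)
    return {
        "genes": repeated_cv_evaluate(gene_features, labels, scheme),
        "pet": repeated_cv_evaluate(pet_features, labels, scheme),
        "composite": repeated_cv_evaluate(composite, labels, scheme),
    }


@dataclass
class LassoSelection:
    """Aggregated lasso output: per-seed sets, frequencies, final signature."""

    per_seed_sets: list[set] = field(default_factory=list)
    frequencies: pd.Series = None
    final_set: list = field(default_factory=list)
    lambda_choices: list = field(default_factory=list)


def _binomial_deviance(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -2.0 * float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _l1_logistic(X, y, lam):
    """L1 logistic at glmnet-style penalty lambda (objective mean-deviance + lam*||b||_1)."""
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (len(y) * lam),
        solver="liblinear",
        intercept_scaling=1000.0,  # effectively unpenalized intercept
        max_iter=500,
        tol=1e-6,
    )
    clf.fit(X, y)
    return clf


def aggregated_lasso(
    features,
    labels,
    n_seeds: int = 100,
    n_folds: int = 10,
    freq_cutoff: float = 0.5,
    n_lambdas: int = 40,
    lambda_min_ratio: float = 0.01,
    base_seed: int = 0,
) -> LassoSelection:
    """Aggregate lambda.1se lasso selections over many CV seeds.

    ``features`` may be a DataFrame (column names become feature IDs) or an
    array. Features are standardized internally (mean 0, SD 1) so the L1
    penalty treats them symmetrically.
    """
    names = (
        list(features.columns)
        if isinstance(features, pd.DataFrame)
        else [f"x{i}" for i in range(np.asarray(features).shape[1])]
    )
    X, y = _validate_xy(features, labels)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    kept_names = [n for n, k in zip(names, keep) if k]
    n = len(y)
    lam_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
    per_seed_sets, lambda_choices = [], []
    for i in range(n_seeds):
        seed_i = _derive_seed(base_seed, "lasso", i)
        fold_seed = seed_i
        for attempt in range(5):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
            folds = list(skf.split(Xs, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
                break
            logger.info("degenerate fold at seed %s, refolding", seed_i)
            fold_seed = _derive_seed(fold_seed, "refold", attempt)
        dev = np.empty((n_folds, n_lambdas))
        for f, (tr, te) in enumerate(folds):
            for j, lam in enumerate(lambdas):
                clf = _l1_logistic(Xs[tr], y[tr], lam)
                p = clf.predict_proba(Xs[te])[:, list(clf.classes_).index(1)]
                dev[f, j] = _binomial_deviance(y[te], p)
        cvm = dev.mean(axis=0)
        cvse = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        jmin = int(np.argmin(cvm))
        threshold = cvm[jmin] + cvse[jmin]
        j1se = int(np.min(np.where(cvm <= threshold)[0]))  # largest lambda within 1 SE
        lam_1se = float(lambdas[j1se])
        clf = _l1_logistic(Xs, y, lam_1se)
        nonzero = np.abs(clf.coef_[0]) > 1e-8
        per_seed_sets.append({kept_names[k] for k in np.where(nonzero)[0]})
        lambda_choices.append(lam_1se)
    counts = pd.Series(0.0, index=kept_names)
    for s in per_seed_sets:
        counts[list(s)] += 1.0
    freqs = counts / n_seeds
    final = [n_ for n_ in kept_names if freqs[n_] >= freq_cutoff]
    return LassoSelection(
        per_seed_sets=per_seed_sets,
        frequencies=freqs,
        final_set=final,
        lambda_choices=lambda_choices,
    )
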