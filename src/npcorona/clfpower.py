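"""Disease-classification pipeline on particle features and two-group power.

The classification stage mirrors a biomarker feasibility workflow: drop
particle features whose protein is also seen in depleted plasma (removing
signal accessible without particles), median-impute missing values per
feature, natural-log transform, then repeated stratified k-fold
cross-validation of a random-forest classifier with out-of-fold AUC per
repeat and a label-permutation control for overfitting.

The power calculation answers the planning question "how large a study can
detect a given fold change with assay noise cv?": a two-sided two-sample
t-test on log concentrations with per-test Bonferroni alpha, effect
δ = ln(fold_change) and log-scale sd σ = sqrt(ln(1+cv²)), evaluated with
the noncentral-t distribution (df = 2n−2, noncentrality δ/σ·√(n/2)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .matrixio import IntensityTensor

logger = logging.getLogger(__name__)


def filter_np_features(np_matrix: IntensityTensor, depleted_plasma_proteins) -> tuple:
    """Drop particle features derived from proteins also observed in
    depleted plasma. Returns (filtered tensor, number of protein rows
    dropped); an empty result is allowed with a warning."""
    depleted = frozenset(depleted_plasma_proteins)
    keep = [p for p in np_matrix.protein_ids if p not in depleted]
    dropped = len(np_matrix.protein_ids) - len(keep)
    if not keep:
        warnings.warn("all particle features were also in depleted plasma; empty matrix")
    return IntensityTensor(np_matrix.data.loc[keep].copy(), scale=np_matrix.scale), dropped


def feature_matrix(tensor: IntensityTensor) -> pd.DataFrame:
    """Flatten a tensor into a (particle__protein) feature × subject matrix
    (median over replicates per subject; subjects are the sample level)."""
    rows = {}
    for (np_id, _condition, sample), frame in tensor.replicate_groups():
        med = frame.median(axis=1, skipna=True)
        for protein, value in med.items():
            rows.setdefault(f"{np_id}__{protein}", {})[sample] = value
    return pd.DataFrame(rows).T.sort_index()


def impute_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each feature's missing values by the median of its observed
    values across subjects; all-missing features are dropped with a
    warning. No other normalization is applied."""
    medians = matrix.median(axis=1, skipna=True)
    empty = medians.index[medians.isna()]
    if len(empty):
        warnings.warn(f"{len(empty)} all-missing feature(s) dropped")
        matrix = matrix.drop(index=empty)
        medians = medians.drop(index=empty)
    return matrix.apply(lambda row: row.fillna(medians.loc[row.name]), axis=1)


@dataclass
class ClassifierReport:
    aucs: list
    mean_auc: float
    importances: pd.Series  # mean impurity importance per feature, descending
    permutation_mean_auc: float | None = None


def _check_classes(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {folds} folds"
        )


def _one_round(X: np.ndarray, y: np.ndarray, folds: int, rng_seed: int,
               n_estimators: int):
    """One round of stratified k-fold CV: out-of-fold probabilities, AUC,
    and fold-averaged impurity importances."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    proba = np.empty(len(y))
    importances = np.zeros(X.shape[1])
    for train, test in skf.split(X, y):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=rng_seed, n_jobs=1
        )
        clf.fit(X[train], y[train])
        proba[test] = clf.predict_proba(X[test])[:, 1]
        importances += clf.feature_importances_
    return roc_auc_score(y, proba), importances / folds


def repeated_cv_classify(
    features: pd.DataFrame,
    labels: pd.Series,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
) -> ClassifierReport:
    """Repeated stratified k-fold random-forest classification.

    ``features``: feature × subject (pre-imputed, log scale); ``labels``:
    binary per subject. AUC is computed per repeat from the pooled
    out-of-fold class probabilities; impurity importances are averaged
    across folds and repeats.
    """
    X = features.T.loc[labels.index].to_numpy(dtype=float)
    y = pd.Categorical(labels).codes
    _check_classes(y, folds)
    aucs = []
    imp = np.zeros(X.shape[1])
    for r in range(repeats):
        auc, importances = _one_round(X, y, folds, rng_seed=seed * 100 + r,
                                      n_estimators=n_estimators)
        aucs.append(float(auc))
        imp += importances
    ranking = pd.Series(imp / repeats, index=features.index).sort_values(ascending=False)
    return ClassifierReport(aucs, float(np.mean(aucs)), ranking)


def permutation_control(
    features: pd.DataFrame,
    labels: pd.Series,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
) -> float:
    """Mean AUC after randomizing class assignments once per repeat: an
    unbiased pipeline lands near 0.5, exposing overfitting if not."""
    X = features.T.loc[labels.index].to_numpy(dtype=float)
    y = pd.Categorical(labels).codes
    _check_classes(y, folds)
    aucs = []
    for r in range(repeats):
        rng = np.random.default_rng([seed, 5, r])
        y_perm = rng.permutation(y)
        if len(np.unique(y_perm)) < 2:  # pragma: no cover - permutation keeps counts
            continue
        auc, _ = _one_round(X, y_perm, folds, rng_seed=seed * 100 + r,
                            n_estimators=n_estimators)
        aucs.append(float(auc))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------
# power
# ---------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Two-group comparison design: n per group, assay CV, detectable fold
    change, family-wise alpha and Bonferroni divisor (number of tests)."""

    n_per_group: int
    cv: float
    fold_change: float
    alpha: float = 0.05
    n_tests: int = 1

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not self.cv > 0:
            raise ValueError("cv must be positive")
        if not self.fold_change > 0:
            raise ValueError("fold_change must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


def power_two_group(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test at per-test alpha/n_tests.

    On the log scale a fold change Δ is a mean shift δ = ln(Δ) against
    sd σ = sqrt(ln(1+cv²)); power comes from the noncentral-t distribution
    with df = 2n−2 and noncentrality δ/σ·√(n/2). At fold_change = 1 the
    returned value is the per-test type-I rate.
    """
    sigma = np.sqrt(np.log1p(spec.cv ** 2))
    delta = np.log(spec.fold_change)
    nc = delta / sigma * np.sqrt(spec.n_per_group / 2.0)
    df = 2 * spec.n_per_group - 2
    alpha_t = spec.alpha / spec.n_tests
    t_crit = stats.t.isf(alpha_t / 2.0, df)
    power = stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
    return float(power)


def power_monte_carlo(spec: PowerSpec, n_sims: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo rejection rate of the same design (simulation oracle):
    draws log-normal groups with the specified CV and fold change and
    counts two-sided t-test rejections at alpha/n_tests."""
    rng = np.random.default_rng([seed, 6])
    sigma = np.sqrt(np.log1p(spec.cv ** 2))
    n = spec.n_per_group
    a = rng.normal(0.0, sigma, size=(n_sims, n))
    b = rng.normal(np.log(spec.fold_change), sigma, size=(n_sims, n))
    _, p = stats.ttest_ind(a, b, axis=1)
    return float(np.mean(p < spec.alpha / spec.n_tests))
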