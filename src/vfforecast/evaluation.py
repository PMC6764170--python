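"""Repeated stratified 10-fold cross-validation, metrics, and group statistics.

Protocol: the data are shuffled and split into k (default 10) folds,
stratified on the class label so the VF/control balance is preserved; one
fold is held out for testing and the other nine train the model; the split
is repeated (default 10 times) with fresh shuffles. Sensitivity,
specificity and accuracy are computed per held-out fold and aggregated as
mean +- SD over all repeat x fold cells; ROC/AUC is computed on the pooled
held-out scores of each repeat and averaged over repeats (a per-fold ROC
on 5-6 samples is too coarse to be meaningful).

The standardizer is fit on the nine training folds only by default;
``scaler_scope="global"`` reproduces the original protocol of scaling the
whole dataset before splitting (which leaks the test fold's mean/SD into
training and is provided for fidelity only).

Group statistics: Welch's unequal-variance two-tailed t-test for feature
and accuracy comparisons (group SDs here can differ by orders of
magnitude), one-way ANOVA with Tukey HSD for the five-algorithm
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .classification import build_classifier, fit_standardizer, TrainConfig
from .errors import InsufficientDataError, InvalidParameterError
from .types import VF

#: Feature-set definitions by canonical column names.
FEATURE_SETS: Dict[str, Tuple[str, ...]] = {}


def _init_feature_sets():
    from .types import HRV_FEATURE_NAMES, QRS_FEATURE_NAMES
    FEATURE_SETS["HRV-11"] = HRV_FEATURE_NAMES
    FEATURE_SETS["QRS-4"] = QRS_FEATURE_NAMES
    FEATURE_SETS["combined-15"] = HRV_FEATURE_NAMES + QRS_FEATURE_NAMES


_init_feature_sets()


def make_folds(labels: Sequence, k: int = 10, repeats: int = 10,
               seed: int = 0, stratified: bool = True) -> List[List[np.ndarray]]:
    """Return ``repeats`` lists of ``k`` test-index arrays.

    Within each repeat the test folds partition all samples exactly once
    and fold sizes differ by at most one. Falls back (with a warning) to
    non-stratified folds when a class has fewer members than ``k``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < k:
        raise InvalidParameterError(f"cannot split {n} samples into {k} folds")
    use_strat = stratified
    if stratified and np.min(np.bincount(pd.factorize(labels)[0])) < k:
        warnings.warn("a class has fewer members than k; "
                      "falling back to non-stratified folds", stacklevel=2)
        use_strat = False
    out = []
    for r in range(repeats):
        splitter = (StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
                    if use_strat else
                    KFold(n_splits=k, shuffle=True, random_state=seed + r))
        out.append([test for _, test in splitter.split(np.zeros(n), labels)])
    return out


def confusion_metrics(predictions: Sequence, truth: Sequence
                      ) -> Tuple[float, float, float]:
    """``(sensitivity %, specificity %, accuracy %)`` with VF positive.

    Sensitivity (specificity) is NaN when the truth holds no positives
    (negatives).
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise InvalidParameterError("predictions and truth differ in length")
    pos, neg = true == VF, true != VF
    tp = np.count_nonzero(pos & (pred == VF))
    tn = np.count_nonzero(neg & (pred != VF))
    n_pos, n_neg = np.count_nonzero(pos), np.count_nonzero(neg)
    sens = 100.0 * tp / n_pos if n_pos else float("nan")
    spec = 100.0 * tn / n_neg if n_neg else float("nan")
    acc = 100.0 * (tp + tn) / true.size
    return sens, spec, acc


def roc_auc(scores: Sequence[float], truth: Sequence
            ) -> Tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal AUC of the ROC curve; returns ``(auc, fpr, tpr)``."""
    scores = np.asarray(scores, dtype=float)
    true = (np.asarray(truth) == VF).astype(int)
    if np.unique(true).size < 2:
        raise InsufficientDataError("ROC needs both classes in the truth")
    fpr, tpr, _ = roc_curve(true, scores)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


@dataclass
class CVReport:
    """Per-fold metrics and aggregates for one (algorithm, feature set) run."""

    algorithm: str
    feature_set: str
    feature_names: Tuple[str, ...]
    fold_metrics: pd.DataFrame          # repeat, fold, sensitivity, specificity, accuracy
    repeat_auc: np.ndarray              # one pooled AUC per repeat
    roc_points: Optional[pd.DataFrame] = None
    seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def summary(self) -> Dict[str, float]:
        fm = self.fold_metrics
        return {
            "sensitivity_mean": float(np.nanmean(fm["sensitivity"])),
            "specificity_mean": float(np.nanmean(fm["specificity"])),
            "accuracy_mean": float(fm["accuracy"].mean()),
            "accuracy_sd": float(fm["accuracy"].std(ddof=0)),
            "auc_mean": float(np.mean(self.repeat_auc)),
            "auc_sd": float(np.std(self.repeat_auc)),
        }

    def accuracy_per_cell(self) -> np.ndarray:
        """All repeat x fold accuracies (the ANOVA replicate vector)."""
        return self.fold_metrics["accuracy"].to_numpy()


def run_experiment(features: pd.DataFrame, labels: Sequence,
                   feature_set: str = "QRS-4", algorithm: str = "ANN",
                   k: int = 10, repeats: int = 10, seed: int = 0,
                   stratified: bool = True, scaler_scope: str = "fold",
                   ann_config: Optional[TrainConfig] = None) -> CVReport:
    """Cross-validate one classifier on one feature set.

    ``features`` has one row per record with Table-style feature columns;
    ``labels`` holds ``"VF"``/``"control"`` per row.
    """
    if feature_set not in FEATURE_SETS:
        raise InvalidParameterError(
            f"unknown feature set {feature_set!r}; choose from {list(FEATURE_SETS)}")
    if scaler_scope not in ("fold", "global"):
        raise InvalidParameterError("scaler_scope must be 'fold' or 'global'")
    names = FEATURE_SETS[feature_set]
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise InvalidParameterError(f"feature table lacks columns: {missing}")
    X = features.loc[:, list(names)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise InvalidParameterError("feature table contains missing values")
    y = (np.asarray(labels) == VF).astype(int)

    if scaler_scope == "global":
        X = fit_standardizer(X, names).apply(X)

    folds = make_folds(labels, k=k, repeats=repeats, seed=seed,
                       stratified=stratified)
    rows = []
    aucs = []
    roc_frames = []
    for r, repeat_folds in enumerate(folds):
        pooled_scores = np.empty(y.size)
        for f, test_idx in enumerate(repeat_folds):
            train_mask = np.ones(y.size, dtype=bool)
            train_mask[test_idx] = False
            Xtr, Xte = X[train_mask], X[test_idx]
            if scaler_scope == "fold":
                scaler = fit_standardizer(Xtr, names)
                Xtr, Xte = scaler.apply(Xtr), scaler.apply(Xte)
            clf = build_classifier(algorithm, seed=seed * 1000 + r * 10 + f,
                                   ann_config=ann_config)
            try:
                clf.fit(Xtr, y[train_mask])
            except Exception as exc:
                raise RuntimeError(
                    f"{algorithm} training failed on repeat {r} fold {f}: {exc}"
                    ) from exc
            scores = clf.predict_proba(Xte)[:, 1]
            pooled_scores[test_idx] = scores
            pred = np.where(scores >= 0.5, VF, "control")
            true = np.where(y[test_idx] == 1, VF, "control")
            sens, spec, acc = confusion_metrics(pred, true)
            rows.append({"repeat": r, "fold": f, "sensitivity": sens,
                         "specificity": spec, "accuracy": acc})
        auc, fpr, tpr = roc_auc(pooled_scores, np.where(y == 1, VF, "control"))
        aucs.append(auc)
        roc_frames.append(pd.DataFrame({"repeat": r, "fpr": fpr, "tpr": tpr}))
    return CVReport(
        algorithm=algorithm, feature_set=feature_set, feature_names=names,
        fold_metrics=pd.DataFrame(rows), repeat_auc=np.asarray(aucs),
        roc_points=pd.concat(roc_frames, ignore_index=True), seed=seed,
        config={"k": k, "repeats": repeats, "stratified": stratified,
                "scaler_scope": scaler_scope})


def compare_groups_ttest(x: Sequence[float], y: Sequence[float],
                         equal_var: bool = False) -> Tuple[float, float]:
    """Two-tailed t-test (Welch by default); returns ``(t, p)``.

    Degenerate inputs follow the conventions: identical constant groups
    give ``(0, 1)``; distinct constant groups give ``(+-inf, 0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def compare_algorithms_anova(accuracy_table: pd.DataFrame,
                             alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA + Tukey HSD across algorithms.

    ``accuracy_table`` has one column per algorithm and one row per
    repeat x fold replicate (a balanced design is required).
    """
    if accuracy_table.shape[1] < 2:
        raise InvalidParameterError("need at least 2 algorithms to compare")
    if accuracy_table.isna().any().any():
        raise InvalidParameterError("accuracy table contains missing values "
                                    "(unbalanced design)")
    groups = [accuracy_table[c].to_numpy(dtype=float) for c in accuracy_table]
    if len({g.size for g in groups}) != 1:
        raise InvalidParameterError("unequal replicate counts across algorithms")
    if all(np.allclose(g, groups[0]) for g in groups[1:]):
        # identical columns: F = 0 by definition, nothing to reject
        k, n = len(groups), sum(g.size for g in groups)
        pairs = [(a, b) for i, a in enumerate(accuracy_table.columns)
                 for b in list(accuracy_table.columns)[i + 1:]]
        tukey = pd.DataFrame({"group1": [p[0] for p in pairs],
                              "group2": [p[1] for p in pairs],
                              "meandiff": 0.0, "p_adj": 1.0, "reject": False})
        return AnovaResult(f=0.0, p=1.0, df_between=k - 1, df_within=n - k,
                           tukey=tukey)
    f, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    group_labels = np.repeat(list(accuracy_table.columns),
                             [g.size for g in groups])
    res = pairwise_tukeyhsd(values, group_labels, alpha=alpha)
    tukey = pd.DataFrame(res.summary().data[1:],
                         columns=[str(c) for c in res.summary().data[0]])
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    k, n = len(groups), values.size
    return AnovaResult(f=float(f), p=float(p), df_between=k - 1,
                       df_within=n - k, tukey=tukey)
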