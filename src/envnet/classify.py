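"""Linear-SVM identification of group status from nodal graph features.

A linear support vector machine is trained on each of the six nodal
metrics and on the pooled 6*n feature vector, evaluated with repeated
stratified five-fold cross-validation (fresh fold assignment per
repetition, features z-scored with training-fold statistics only), and
tested against an empirical chance level obtained by label permutation.

Performance is summarized as mean +/- SD accuracy, sensitivity (true
positive rate, "positive" = case) and specificity (true negative rate)
across repetitions, all in percent, plus the per-subject mean predicted
label: the fraction of repetitions in which a subject was predicted
"case" while held out, a per-individual gradation of classifier
confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .graphs import METRICS

__all__ = [
    "ClassifierReport",
    "cross_validated_svm",
    "permutation_pvalue",
    "run_contrasts",
]


@dataclass
class ClassifierReport:
    """Cross-validated classification performance for one contrast."""

    feature_set: str
    contrast: str
    accuracy_mean: float  # percent
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    n_folds: int
    n_reps: int
    seed: int
    mean_predicted_label: pd.Series | None = None
    p_value: float | None = None
    n_perm: int | None = None
    per_rep_accuracy: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        d = {
            "feature_set": self.feature_set,
            "contrast": self.contrast,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity_mean": self.sensitivity_mean,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_mean": self.specificity_mean,
            "specificity_sd": self.specificity_sd,
            "n_folds": self.n_folds,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
            d["n_perm"] = self.n_perm
        return d


def _check_inputs(X: np.ndarray, y: np.ndarray, n_folds: int) -> None:
    if X.ndim != 2:
        raise ValueError("features must be 2-D (subjects x features)")
    if not np.isfinite(X).all():
        raise ValueError("features contain missing/non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(
            f"need exactly two classes, got {classes.tolist()}"
        )
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects; need at least "
            f"n_folds={n_folds} per class for stratified CV"
        )


def _one_cv_pass(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    rep_seed: int,
    C: float,
) -> tuple[float, float, float, np.ndarray]:
    """One repetition: fresh stratified folds; pooled test predictions."""
    pred = np.empty_like(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=rep_seed)
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(X[train]), y[train])
        pred[test] = clf.predict(scaler.transform(X[test]))
    acc = float(np.mean(pred == y))
    sens = float(np.mean(pred[y == 1] == 1))
    spec = float(np.mean(pred[y == 0] == 0))
    return acc, sens, spec, pred


def cross_validated_svm(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    n_folds: int = 5,
    n_reps: int = 100,
    seed: int = 0,
    C: float = 1.0,
    feature_set: str = "pooled",
    contrast: str = "case_vs_control",
    subject_ids: Sequence[str] | None = None,
) -> ClassifierReport:
    """Repeated stratified k-fold linear-SVM evaluation.

    Per repetition a fresh stratified fold assignment is drawn; within
    each fold, features are standardized using training-fold mean/SD
    only (no test-set leakage) and a linear SVM (fixed C) is trained.
    Accuracy, sensitivity and specificity are computed per repetition
    from the pooled held-out predictions, then averaged; labels must be
    0 (control) / 1 (case).
    """
    if isinstance(features, pd.DataFrame):
        if subject_ids is None:
            subject_ids = list(features.index)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_inputs(X, y, n_folds)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps)
    accs = np.empty(n_reps)
    sens = np.empty(n_reps)
    spec = np.empty(n_reps)
    label_sum = np.zeros(y.size)
    for r in range(n_reps):
        a, s, sp, pred = _one_cv_pass(
            X, y, n_folds, int(rep_seeds[r] % (2**31)), C
        )
        accs[r], sens[r], spec[r] = a, s, sp
        label_sum += pred
    mean_label = label_sum / n_reps
    mpl = None
    if subject_ids is not None:
        mpl = pd.Series(mean_label, index=list(subject_ids),
                        name="mean_predicted_label")
    else:
        mpl = pd.Series(mean_label, name="mean_predicted_label")
    return ClassifierReport(
        feature_set=feature_set,
        contrast=contrast,
        accuracy_mean=100 * accs.mean(),
        accuracy_sd=100 * accs.std(ddof=1),
        sensitivity_mean=100 * sens.mean(),
        sensitivity_sd=100 * sens.std(ddof=1),
        specificity_mean=100 * spec.mean(),
        specificity_sd=100 * spec.std(ddof=1),
        n_folds=n_folds,
        n_reps=n_reps,
        seed=seed,
        mean_predicted_label=mpl,
        per_rep_accuracy=accs,
    )


def permutation_pvalue(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    observed_accuracy: float,
    n_perm: int = 5_000,
    n_reps_perm: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """One-tailed permutation p-value for a mean CV accuracy (percent).

    Labels are shuffled ``n_perm`` times and the mean CV accuracy is
    recomputed with ``n_reps_perm`` repetitions per shuffle (the
    permutation distribution of a mean accuracy is insensitive to the
    repetition count at this scale); p = (1 + #{perm >= observed}) /
    (n_perm + 1), so p is always in (0, 1].
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very low for a permutation p-value",
            RuntimeWarning, stacklevel=2,
        )
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_inputs(X, y, n_folds)
    root = np.random.SeedSequence(seed)
    shuffle_rng = np.random.default_rng(root.spawn(1)[0])
    perm_seeds = root.generate_state(n_perm)
    n_ge = 0
    for b in range(n_perm):
        y_perm = shuffle_rng.permutation(y)
        rep_seeds = np.random.SeedSequence(
            int(perm_seeds[b] % (2**31))
        ).generate_state(n_reps_perm)
        accs = [
            _one_cv_pass(X, y_perm, n_folds, int(rs % (2**31)), C)[0]
            for rs in rep_seeds
        ]
        if 100 * float(np.mean(accs)) >= observed_accuracy:
            n_ge += 1
    return (1 + n_ge) / (n_perm + 1)


def run_contrasts(
    tables: dict[str, pd.DataFrame],
    manifest: Sequence[dict],
    contrasts: dict[str, tuple[Sequence[str], Sequence[str]]],
    n_folds: int = 5,
    n_reps: int = 100,
    n_perm: int | None = None,
    n_reps_perm: int = 10,
    seed: int = 0,
) -> list[ClassifierReport]:
    """Evaluate every feature set on every contrast.

    ``tables`` maps feature-set name (a metric name or "pooled") to a
    subject x feature DataFrame indexed by subject_id.  ``contrasts``
    maps a contrast name to (case_subject_ids, control_subject_ids);
    build these from the manifest's group / subgroup labels.  With
    ``n_perm`` set, a permutation p-value is attached to each report.
    """
    by_id = {m["subject_id"]: m for m in manifest}
    reports: list[ClassifierReport] = []
    ss = np.random.SeedSequence(seed)
    task_seeds = ss.generate_state(len(tables) * len(contrasts) * 2)
    k = 0
    for fname, table in tables.items():
        for cname, (case_ids, ctrl_ids) in contrasts.items():
            missing = [s for s in (*case_ids, *ctrl_ids) if s not in by_id]
            if missing:
                raise ValueError(
                    f"contrast {cname!r} references unknown subjects "
                    f"{missing}"
                )
            ids = [*case_ids, *ctrl_ids]
            absent = [s for s in ids if s not in table.index]
            if absent:
                raise ValueError(
                    f"feature table {fname!r} lacks subjects {absent}"
                )
            X = table.loc[ids]
            y = np.array([1] * len(case_ids) + [0] * len(ctrl_ids))
            rep = cross_validated_svm(
                X, y, n_folds=n_folds, n_reps=n_reps,
                seed=int(task_seeds[k] % (2**31)),
                feature_set=fname, contrast=cname, subject_ids=ids,
            )
            k += 1
            if n_perm:
                rep.p_value = permutation_pvalue(
                    X, y, rep.accuracy_mean, n_perm=n_perm,
                    n_reps_perm=n_reps_perm, n_folds=n_folds,
                    seed=int(task_seeds[k] % (2**31)),
                )
                rep.n_perm = n_perm
            k += 1
            reports.append(rep)
    return reports


def metric_tables(feature_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a pooled (metric, node) table into the seven feature sets."""
    out = {m: feature_table[m] for m in METRICS
           if m in feature_table.columns.get_level_values(0)}
    out["pooled"] = feature_table
    return out


__all__.append("metric_tables")
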