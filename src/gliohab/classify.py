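"""Label compositions, linear-SVM LOOCV, and the bootstrap K comparison.

Each labeled tumor is summarized by its label composition: the percentage
p_k of defined tumor voxels carrying each habitat label k, transformed to
log10(p + 1e-2) so absent labels map to -2 and the feature scale is
compressed.  The per-subject log-ratio vectors feed a linear support vector
machine that predicts IDH mutation status under leave-one-out
cross-validation (LOOCV), with the SVM cost C tuned per training fold by a
two-step grid search (coarse powers of 4 over 2^-10..2^10, then a fine
quarter-power sweep around the best), scored by internal stratified 5-fold
accuracy.  Pooled held-out decision values yield AUC, accuracy,
sensitivity, specificity, precision, recall and F1, with IDH wild-type as
the positive class.

The number of habitat classes K is compared by refitting the classifier on
class-stratified bootstrap resamples of the cohort (default B = 100) for
each K, followed by one-way ANOVA and Tukey HSD across K per metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .clustering import LabeledTumorVolume
from .features import IDH_MUTANT, IDH_WILDTYPE
from .stats import anova_tukey

logger = logging.getLogger(__name__)

LOG_RATIO_FLOOR = 1e-2  # p is a percentage; absent labels map to log10(1e-2) = -2
POSITIVE_CLASS = IDH_WILDTYPE

COARSE_LOG2_C = np.arange(-10.0, 10.0 + 1e-9, 2.0)
FINE_STEP_LOG2 = 0.25
FINE_SPAN_LOG2 = 2.0


@dataclass
class LabelComposition:
    """Per-subject habitat composition: percentages and their log-ratios."""

    subject_id: str
    p: np.ndarray
    logratio: np.ndarray
    idh_status: Optional[str] = None
    age: Optional[float] = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.logratio = np.asarray(self.logratio, dtype=float)
        if abs(self.p.sum() - 100.0) > 1e-9:
            raise ValueError(f"label percentages sum to {self.p.sum()}, not 100")


@dataclass
class CVResult:
    """Pooled LOOCV outcome: one held-out prediction per subject."""

    folds: pd.DataFrame  # subject_id, y_true, decision, y_pred, C
    metrics: dict[str, float]


def log_ratio(p: np.ndarray) -> np.ndarray:
    """log10(p + 1e-2) of a label-percentage vector."""
    return np.log10(np.asarray(p, dtype=float) + LOG_RATIO_FLOOR)


def composition(labeled: LabeledTumorVolume, idh_status: Optional[str] = None,
                age: Optional[float] = None) -> LabelComposition:
    """Label composition of one labeled tumor.

    p_k = 100 * (#voxels with label k) / (#defined tumor voxels).
    """
    counts = labeled.label_counts()
    total = counts.sum()
    if total == 0:
        raise ValueError(f"subject {labeled.subject_id}: no defined tumor voxels")
    p = 100.0 * counts / total
    return LabelComposition(labeled.subject_id, p, log_ratio(p), idh_status, age)


def compositions_to_table(comps: Sequence[LabelComposition],
                          use_logratio: bool = True) -> tuple[np.ndarray, np.ndarray, list]:
    """Stack compositions into (X, y, subject_ids); y=1 for wild-type."""
    X = np.vstack([c.logratio if use_logratio else c.p for c in comps])
    y = np.array([1 if c.idh_status == POSITIVE_CLASS else 0 for c in comps])
    return X, y, [c.subject_id for c in comps]


# ---------------------------------------------------------------------------
# Metrics


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) statistic with midrank tie handling."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes in y_true")
    ranks = sps.rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def compute_metrics(y_true, y_pred, scores) -> dict[str, float]:
    """Confusion-matrix metrics plus rank AUC; positive class = 1 (wild-type)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    acc = (tp + tn) / len(y_true)
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0 else 0.0)
    return {
        "auc": rank_auc(y_true, scores),
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
        "f1": f1,
    }


# ---------------------------------------------------------------------------
# SVM with two-step grid search under LOOCV


def _cv_accuracy(X: np.ndarray, y: np.ndarray, c: float, seed: int) -> float:
    n_splits = min(5, int(np.bincount(y).min()))
    if n_splits < 2:
        # too few per class for internal CV: resubstitution accuracy
        clf = SVC(kernel="linear", C=c).fit(X, y)
        return float((clf.predict(X) == y).mean())
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = SVC(kernel="linear", C=c).fit(X[tr], y[tr])
        accs.append((clf.predict(X[te]) == y[te]).mean())
    return float(np.mean(accs))


def two_step_grid_search(X: np.ndarray, y: np.ndarray, seed: int = 0,
                         grid: str = "two-step") -> float:
    """Choose the linear-SVM cost C by internal stratified 5-fold accuracy.

    ``grid`` selects the search depth: "two-step" (coarse 2^-10..2^10 in
    steps of 2^2, then 2^+-2 around the best in steps of 2^0.25), "coarse"
    (first step only), or "none" (C = 1, no search).  Ties prefer the
    smaller C.
    """
    if grid == "none":
        return 1.0

    def best_c(log2_grid: np.ndarray) -> float:
        accs = [_cv_accuracy(X, y, 2.0**e, seed) for e in log2_grid]
        return float(log2_grid[int(np.argmax(accs))])  # argmax tie -> smallest C

    e0 = best_c(COARSE_LOG2_C)
    if grid == "coarse":
        return 2.0**e0
    fine = np.arange(e0 - FINE_SPAN_LOG2, e0 + FINE_SPAN_LOG2 + 1e-9, FINE_STEP_LOG2)
    return 2.0 ** best_c(fine)


def svm_loocv(X, y, subject_ids: Optional[Sequence[str]] = None,
              ages: Optional[Sequence[float]] = None, seed: int = 0,
              grid: str = "two-step") -> CVResult:
    """Leave-one-out evaluation of the linear SVM on composition features.

    Each subject is held out once; the cost C is tuned on the remaining
    n-1 subjects by :func:`two_step_grid_search` (nested inside the fold so
    the held-out subject never informs the hyperparameter), the SVM is
    refit, and the held-out decision value is recorded.  Metrics are
    computed from the pooled held-out predictions, AUC from the decision
    values with wild-type (y=1) as the positive class.

    ``ages`` (optional) appends a z-scored age column, normalized within
    each training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 4 or len(np.unique(y)) < 2:
        raise ValueError("need n >= 4 with both classes present")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(n)]
    ages_arr = None if ages is None else np.asarray(ages, dtype=float)

    rows = []
    for i in range(n):
        tr = np.arange(n) != i
        if len(np.unique(y[tr])) < 2:
            raise ValueError("training fold has a single class")
        Xtr, Xte = X[tr], X[i:i + 1]
        if ages_arr is not None:
            mu, sd = ages_arr[tr].mean(), ages_arr[tr].std()
            sd = sd if sd > 0 else 1.0
            Xtr = np.column_stack([Xtr, (ages_arr[tr] - mu) / sd])
            Xte = np.column_stack([Xte, (ages_arr[i:i + 1] - mu) / sd])
        c = two_step_grid_search(Xtr, y[tr], seed=seed, grid=grid)
        clf = SVC(kernel="linear", C=c).fit(Xtr, y[tr])
        dec = float(clf.decision_function(Xte)[0])
        rows.append({"subject_id": subject_ids[i], "y_true": int(y[i]),
                     "decision": dec, "y_pred": int(dec > 0), "C": c})

    folds = pd.DataFrame(rows)
    metrics = compute_metrics(folds["y_true"], folds["y_pred"], folds["decision"])
    return CVResult(folds=folds, metrics=metrics)


# ---------------------------------------------------------------------------
# Bootstrap comparison across K


@dataclass
class KComparisonTable:
    """Bootstrap metrics per K with ANOVA/Tukey comparisons per metric."""

    replicates: pd.DataFrame          # K, replicate, metric columns
    summary: pd.DataFrame             # per-K mean and percentile 95% CI
    tests: dict[str, dict]            # metric -> {F, p, tukey}


def bootstrap_k_selection(features_by_k: dict[int, np.ndarray], y,
                          n_bootstrap: int = 100, seed: int = 0,
                          grid: str = "coarse",
                          metrics_of_interest: Sequence[str] = ("auc", "accuracy", "f1"),
                          ) -> KComparisonTable:
    """Compare candidate K values by bootstrapped LOOCV performance.

    Per replicate, subjects are resampled with replacement stratified by
    IDH class (each class keeps its size, so both classes are always
    present) and LOOCV is rerun on the resample for every K.  Per-K means
    and percentile 95% CIs are tabulated, and a one-way ANOVA with Tukey
    HSD across K is run per metric.
    """
    y = np.asarray(y, dtype=int)
    ks = sorted(features_by_k)
    for k in ks:
        if len(features_by_k[k]) != len(y):
            raise ValueError(f"feature table for K={k} does not match y")
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)

    rows = []
    for b in range(n_bootstrap):
        resample = np.concatenate([rng.choice(idx_neg, size=len(idx_neg)),
                                   rng.choice(idx_pos, size=len(idx_pos))])
        for k in ks:
            res = svm_loocv(features_by_k[k][resample], y[resample],
                            seed=seed + b, grid=grid)
            rows.append({"K": k, "replicate": b, **res.metrics})
    reps = pd.DataFrame(rows)

    summaries = []
    for k in ks:
        sub = reps[reps["K"] == k]
        for m in metrics_of_interest:
            summaries.append({
                "K": k, "metric": m, "mean": sub[m].mean(),
                "ci_lo": np.percentile(sub[m], 2.5),
                "ci_hi": np.percentile(sub[m], 97.5),
            })
    summary = pd.DataFrame(summaries)

    tests = {}
    for m in metrics_of_interest:
        groups = [reps.loc[reps["K"] == k, m].to_numpy() for k in ks]
        try:
            f, p, tukey = anova_tukey(groups)
            tukey = tukey.assign(K_i=[ks[i] for i in tukey["group_i"]],
                                 K_j=[ks[j] for j in tukey["group_j"]])
            tests[m] = {"F": f, "p": p, "tukey": tukey}
        except ValueError as exc:
            logger.warning("ANOVA for %s degenerate: %s", m, exc)
            tests[m] = {"F": float("nan"), "p": float("nan"), "tukey": None}
    return KComparisonTable(replicates=reps, summary=summary, tests=tests)
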