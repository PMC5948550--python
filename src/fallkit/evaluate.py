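"""Threshold training, stratified cross-validation and detection metrics.

The classifier is a single threshold t on the per-file maximum of J3:
a file is predicted "fall" iff its score >= t.  Training picks, among the
candidate thresholds (midpoints between consecutive distinct sorted scores
plus below-min / above-max sentinels), the balanced-accuracy maximizers and
returns the smallest of them -- the lower-threshold rule that favours
sensitivity, since elderly falls show lower accelerations than the young
adults most training falls come from.

Metrics follow the event-detection convention: SEN = TP/(TP+FN),
SPE = TN/(TN+FP), and the balanced accuracy ACC = (SEN+SPE)/2, chosen
because ADL files far outnumber fall files.  The kappa report computes the
observed accuracy (TP+TN)/total, the standard chance-expected accuracy from
the marginal products, Cohen's kappa, and optionally a variant kappa from a
caller-supplied expected accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class ConfusionMatrix:
    """TP/FN/TN/FP; fractional values allowed (means over folds)."""

    TP: float
    FN: float
    TN: float
    FP: float

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.TP + self.FN + self.TN + self.FP


@dataclass
class EvalResult:
    """Per-fold and aggregate cross-validation outcome."""

    fold_thresholds: np.ndarray
    fold_sen: np.ndarray
    fold_spe: np.ndarray
    fold_acc: np.ndarray
    mean_cm: ConfusionMatrix
    pooled_cm: ConfusionMatrix

    @property
    def summary(self) -> dict:
        def ms(a: np.ndarray) -> tuple[float, float]:
            return float(np.mean(a)), float(np.std(a, ddof=1))

        sen_m, sen_s = ms(self.fold_sen)
        spe_m, spe_s = ms(self.fold_spe)
        acc_m, acc_s = ms(self.fold_acc)
        thr_m, thr_s = ms(self.fold_thresholds)
        pooled = metrics(self.pooled_cm)
        return {
            "sensitivity_pct": {"mean": 100 * sen_m, "std": 100 * sen_s},
            "specificity_pct": {"mean": 100 * spe_m, "std": 100 * spe_s},
            "accuracy_pct": {"mean": 100 * acc_m, "std": 100 * acc_s},
            "threshold": {"mean": thr_m, "std": thr_s},
            "pooled": {k: 100 * v for k, v in pooled.items()},
            "mean_confusion": {
                "TP": self.mean_cm.TP,
                "FN": self.mean_cm.FN,
                "TN": self.mean_cm.TN,
                "FP": self.mean_cm.FP,
            },
        }


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each file to one of k folds, class proportions preserved.

    Deterministic given the seed; fold sizes differ by at most one and each
    fold's class counts are within one file of the global proportion.
    """
    labels = np.asarray(labels, dtype=bool)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in (False, True):
        if (labels == cls).sum() < k:
            raise ValueError("each class needs at least k members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


def confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionMatrix:
    """Counts under the rule: predict fall iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    return ConfusionMatrix(
        TP=float(np.sum(pred & labels)),
        FN=float(np.sum(~pred & labels)),
        TN=float(np.sum(~pred & ~labels)),
        FP=float(np.sum(pred & ~labels)),
    )


def metrics(cm: ConfusionMatrix) -> dict:
    """SEN, SPE and balanced ACC from a confusion matrix."""
    if cm.TP + cm.FN <= 0 or cm.TN + cm.FP <= 0:
        raise ValueError("metrics undefined: a class is empty")
    sen = cm.TP / (cm.TP + cm.FN)
    spe = cm.TN / (cm.TN + cm.FP)
    return {"SEN": sen, "SPE": spe, "ACC": 0.5 * (sen + spe)}


def balanced_accuracy_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    return metrics(confusion_at(scores, labels, threshold))["ACC"]


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus sentinels."""
    distinct = np.unique(np.asarray(scores, dtype=float))
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    lo = distinct[0] - 1.0  # below-min: everything predicted fall
    hi = distinct[-1] + 1.0  # above-max: nothing predicted fall
    return np.concatenate(([lo], mids, [hi]))


def train_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Smallest balanced-accuracy-maximizing candidate threshold."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("training needs both classes")
    cands = candidate_thresholds(scores)
    accs = np.array([balanced_accuracy_at(scores, labels, t) for t in cands])
    best = accs.max()
    return float(cands[np.nonzero(np.isclose(accs, best))[0][0]])


def kappa_report(cm: ConfusionMatrix, expected_accuracy: float | None = None) -> dict:
    """Observed/expected accuracy and Cohen's kappa.

    ``expected_accuracy``, if given, yields an additional variant kappa
    computed with that Pe instead of the standard marginal-product Pe.
    """
    if cm.total <= 0:
        raise ValueError("empty confusion matrix")
    po = (cm.TP + cm.TN) / cm.total
    # marginals: predicted fall / actual fall etc.
    pred_fall = (cm.TP + cm.FP) / cm.total
    act_fall = (cm.TP + cm.FN) / cm.total
    pe = pred_fall * act_fall + (1 - pred_fall) * (1 - act_fall)
    out = {"observed_accuracy": po, "expected_accuracy": pe}
    if pe >= 1.0:
        raise ValueError("kappa undefined: expected accuracy is 1")
    out["kappa"] = (po - pe) / (1 - pe)
    if expected_accuracy is not None:
        if expected_accuracy >= 1.0:
            raise ValueError("kappa undefined: expected accuracy is 1")
        out["kappa_variant"] = (po - expected_accuracy) / (1 - expected_accuracy)
    return out


def cross_validate(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Stratified k-fold over per-file scores.

    Each round trains a threshold on k-1 folds and evaluates on the held-out
    fold.  Headline SEN/SPE/ACC are means of per-fold rates; the pooled
    variant (counts summed over folds) is also reported, as is the mean
    confusion matrix (fractional cells, Table-style).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    assignment = stratified_folds(labels, k, seed)
    thr, sen, spe, acc = [], [], [], []
    cms: list[ConfusionMatrix] = []
    for fold in range(k):
        test = assignment == fold
        t = train_threshold(scores[~test], labels[~test])
        cm = confusion_at(scores[test], labels[test], t)
        m = metrics(cm)
        thr.append(t)
        sen.append(m["SEN"])
        spe.append(m["SPE"])
        acc.append(m["ACC"])
        cms.append(cm)
    mean_cm = ConfusionMatrix(
        TP=float(np.mean([c.TP for c in cms])),
        FN=float(np.mean([c.FN for c in cms])),
        TN=float(np.mean([c.TN for c in cms])),
        FP=float(np.mean([c.FP for c in cms])),
    )
    pooled_cm = ConfusionMatrix(
        TP=float(np.sum([c.TP for c in cms])),
        FN=float(np.sum([c.FN for c in cms])),
        TN=float(np.sum([c.TN for c in cms])),
        FP=float(np.sum([c.FP for c in cms])),
    )
    return EvalResult(
        fold_thresholds=np.array(thr),
        fold_sen=np.array(sen),
        fold_spe=np.array(spe),
        fold_acc=np.array(acc),
        mean_cm=mean_cm,
        pooled_cm=pooled_cm,
    )


def score_corpus(
    recordings: list,
    config=None,
    veto: bool = True,
) -> pd.DataFrame:
    """Run the pipeline over a corpus; one row per file: score + label."""
    from fallkit.detector import max_score

    rows = []
    for rec in recordings:
        rows.append(
            {
                "activity": rec.activity_code,
                "is_fall": rec.is_fall,
                "score": max_score(rec, config, veto=veto),
            }
        )
    return pd.DataFrame(rows)
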