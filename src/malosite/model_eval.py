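"""Classifier training, tenfold cross-validation and the metric suite.

Metrics are the confusion-matrix quartet (sensitivity, specificity,
accuracy, Matthews correlation) plus threshold-free AUROC / AUPR, with a
label-permutation test for significance against random prediction.

All fold-level fitting — corpus encoders, the z-score scaler and the
Fisher-score ranking — happens on the training fold only; the held-out
fold is only ever transformed and scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from malosite.featurize import EncoderConfig, FeatureExtractor
from malosite.preprocess_select import (
    FeatureMatrix,
    fscore,
    select_top_fraction,
    zscore_fit,
    zscore_transform,
)
from malosite.sequence_io import SiteDataset

METRIC_NAMES = ("Sn", "Sp", "ACC", "MCC", "AUROC", "AUPR")

_FAMILY_DEFAULTS: dict[str, dict[str, object]] = {
    "gradient_boosted_trees": {"n_estimators": 80, "learning_rate": 0.1},
    "random_forest": {"n_trees": 100, "split": "gini"},
    "rbf_svm": {"penalty": 2.0, "kernel": "rbf"},
    "mlp": {"hidden_layers": 4, "learning_rate": 0.08},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus hyperparameters (defaults per family).

    Families: ``gradient_boosted_trees`` (XGBoost, 80 estimators at
    learning rate 0.1), ``random_forest`` (100 trees, Gini split),
    ``rbf_svm`` (soft-margin cost 2, RBF kernel) and ``mlp`` (4 hidden
    layers, learning rate 0.08).
    """

    family: str = "gradient_boosted_trees"
    hyperparameters: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_DEFAULTS:
            raise ValueError(
                f"unknown family {self.family!r}; known: {sorted(_FAMILY_DEFAULTS)}"
            )

    def resolved(self) -> dict[str, object]:
        out = dict(_FAMILY_DEFAULTS[self.family])
        out.update(self.hyperparameters)
        return out


def build_classifier(spec: ClassifierSpec, seed: int):
    """Instantiate the scikit-learn / XGBoost estimator behind a spec."""
    h = spec.resolved()
    if spec.family == "gradient_boosted_trees":
        return XGBClassifier(
            n_estimators=int(h["n_estimators"]),
            learning_rate=float(h["learning_rate"]),
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(h["n_trees"]),
            criterion=str(h["split"]),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "rbf_svm":
        return SVC(
            C=float(h["penalty"]),
            kernel=str(h["kernel"]),
            probability=True,
            random_state=seed,
        )
    # mlp: the stated layer count, geometrically decreasing widths
    n_layers = int(h["hidden_layers"])
    widths = tuple(max(8, 128 // 2 ** i) for i in range(n_layers))
    return MLPClassifier(
        hidden_layer_sizes=widths,
        learning_rate_init=float(h["learning_rate"]),
        random_state=seed,
        max_iter=300,
    )


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Tally a binary confusion table (1 = positive, 0 = negative)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.size == 0:
        raise ValueError("empty input")
    if yt.shape != yp.shape:
        raise ValueError("length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, ACC and MCC from a confusion table.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)),
    with the 0/0 cases mapping to 0 by convention.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / c.total if c.total else 0.0
    denom = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"Sn": sn, "Sp": sp, "ACC": acc, "MCC": mcc}


def roc_auc(scores: Sequence[float], y_true: Sequence[int]) -> float:
    """Area under the ROC curve (rank statistic, half-credit ties)."""
    y = np.asarray(y_true)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, float)))


def pr_auc(scores: Sequence[float], y_true: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    y = np.asarray(y_true)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUPR needs both classes present")
    return float(average_precision_score(y, np.asarray(scores, float)))


def permutation_pvalue(
    scores: Sequence[float],
    y_true: Sequence[int],
    statistic: str = "auroc",
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """One-sided label-permutation p-value for AUROC or AUPR.

    p = (r + 1) / (n_perm + 1), r the number of label permutations whose
    statistic is at least the observed one.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    stat = {"auroc": roc_auc, "aupr": pr_auc}[statistic]
    y = np.asarray(y_true)
    s = np.asarray(scores, float)
    observed = stat(s, y)
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if stat(s, perm) >= observed - 1e-12:
            r += 1
    return (r + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Training and cross-validation


def export_curves(
    scores: Sequence[float],
    y_true: Sequence[int],
    roc_path: str | Path,
    pr_path: str | Path,
) -> None:
    """Write ROC and precision-recall curves as (threshold, x, y) TSVs."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    y = np.asarray(y_true)
    s = np.asarray(scores, float)
    fpr, tpr, thr = roc_curve(y, s)
    pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr}).to_csv(
        roc_path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
    )
    prec, rec, thr_pr = precision_recall_curve(y, s)
    pd.DataFrame(
        {
            "threshold": np.append(thr_pr, np.nan),  # last PR point has no threshold
            "recall": rec,
            "precision": prec,
        }
    ).to_csv(pr_path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def _labels_to_int(labels: Sequence[str]) -> np.ndarray:
    out = np.asarray([1 if l == "positive" else 0 for l in labels])
    return out


def train_and_predict(
    train: FeatureMatrix,
    test: FeatureMatrix,
    spec: ClassifierSpec,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a classifier on labeled training features and score test rows.

    Returns per-row continuous scores in [0, 1] (positive-class
    probability) and hard labels thresholded at 0.5.
    """
    if train.labels is None:
        raise ValueError("training matrix must carry labels")
    model = build_classifier(spec, seed)
    model.fit(train.values, _labels_to_int(train.labels))
    scores = model.predict_proba(test.values)[:, 1]
    return scores, (scores >= 0.5).astype(int)


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics.

    ``sd`` holds the sample standard deviation of each metric across
    folds — the error-bar half-length used when comparing classifiers.
    P-values come from a label-permutation test on the pooled
    out-of-fold scores (significance against random prediction).
    """

    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    n_folds: int
    seed: int
    classifier: str
    encoders: list[str]
    selection_fraction: float | None
    n_features_used: int
    p_auroc: float | None = None
    p_aupr: float | None = None
    significance_method: str = "label permutation on pooled out-of-fold scores"

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "classifier": self.classifier,
            "encoders": self.encoders,
            "selection_fraction": self.selection_fraction,
            "n_features_used": self.n_features_used,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "p_auroc": self.p_auroc,
            "p_aupr": self.p_aupr,
            "significance_method": self.significance_method,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"fold": i, "metric": m, "value": fold[m]}
            for i, fold in enumerate(self.per_fold)
            for m in METRIC_NAMES
        ]
        pd.DataFrame(rows).to_csv(
            path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
        )


def tenfold_cv(
    data: SiteDataset,
    encoders: Sequence["str | EncoderConfig"] = ("EAAC",),
    selection_fraction: float | None = 0.8,
    spec: ClassifierSpec | None = None,
    n_folds: int = 10,
    seed: int = 0,
    n_perm: int | None = None,
) -> CVReport:
    """Stratified k-fold evaluation of the full pipeline.

    Per fold: fit corpus encoders, the z-score scaler and the
    Fisher-score selection on the training fold only; transform and score
    the held-out fold; tally Sn/Sp/ACC/MCC/AUROC/AUPR. Aggregates are the
    across-fold mean and sample standard deviation. With ``n_perm`` set,
    permutation p-values for AUROC/AUPR are computed on the pooled
    out-of-fold scores.
    """
    spec = spec or ClassifierSpec()
    y = _labels_to_int(data.labels())
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs >= {n_folds} rows for {n_folds}-fold stratification"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold: list[dict[str, float]] = []
    pooled_scores: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    n_features_used = 0
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_ds, test_ds = data.subset(tr), data.subset(te)
        fx = FeatureExtractor(encoders).fit(train_ds)
        x_train = fx.transform(train_ds)
        x_test = fx.transform(test_ds)
        scaler = zscore_fit(x_train)
        x_train = zscore_transform(x_train, scaler)
        x_test = zscore_transform(x_test, scaler)
        if selection_fraction is not None:
            ranking = select_top_fraction(fscore(x_train), selection_fraction)
            keep = ranking.selected_names()
            x_train = x_train.select_columns(keep)
            x_test = x_test.select_columns(keep)
        n_features_used = x_train.n_features
        scores, preds = train_and_predict(x_train, x_test, spec, seed=seed + fold)
        y_te = y[te]
        fold_metrics = metrics(confusion(y_te, preds))
        fold_metrics["AUROC"] = roc_auc(scores, y_te)
        fold_metrics["AUPR"] = pr_auc(scores, y_te)
        per_fold.append(fold_metrics)
        pooled_scores.append(scores)
        pooled_y.append(y_te)
    mean = {m: float(np.mean([f[m] for f in per_fold])) for m in METRIC_NAMES}
    sd = {m: float(np.std([f[m] for f in per_fold], ddof=1)) for m in METRIC_NAMES}
    report = CVReport(
        per_fold=per_fold,
        mean=mean,
        sd=sd,
        n_folds=n_folds,
        seed=seed,
        classifier=spec.family,
        encoders=[_name_of(e) for e in encoders],
        selection_fraction=selection_fraction,
        n_features_used=n_features_used,
    )
    if n_perm:
        s = np.concatenate(pooled_scores)
        yy = np.concatenate(pooled_y)
        report.p_auroc = permutation_pvalue(s, yy, "auroc", n_perm=n_perm, seed=seed)
        report.p_aupr = permutation_pvalue(s, yy, "aupr", n_perm=n_perm, seed=seed)
    return report


def _name_of(e: "str | EncoderConfig") -> str:
    return e if isinstance(e, str) else e.name
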