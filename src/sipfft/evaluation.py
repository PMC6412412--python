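"""Evaluation protocol: confusion metrics, ROC/AUC, undersampling, k-fold CV.

Metrics on a binary confusion matrix (TP, FP, TN, FN):

    Acc   = (TP + TN) / (TP + TN + FP + FN)
    Sen   = TP / (TP + FN)
    Spe   = TN / (TN + FP)
    MCC   = (TP·TN − FP·FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))
    B_Acc = (Sen + Spe) / 2

All metrics are kept as fractions in [0, 1] (MCC in [−1, 1]); report
writers multiply by 100 for display. Degenerate denominators: MCC with a
zero denominator is defined as 0 (conventional); Sen/Spe with an empty
class are NaN and excluded from fold averages with a warning.

Cross-validation is stratified k-fold (default 5). Within each fold PCA
and the classifier are fitted on the training folds only, so no test
information leaks into the feature reduction; a ``pca_global`` flag
fits PCA once on the full dataset instead. Fold means use the
arithmetic mean and the sample (n−1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt

import numpy as np

from sipfft import rp_ensemble
from sipfft.baselines import SvmConfig, train_svm
from sipfft.features import FeatureMatrix, pca_fit, pca_transform
from sipfft.rp_ensemble import RpConfig
from sklearn.model_selection import StratifiedKFold


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    acc: float
    sen: float
    spe: float
    mcc: float
    bacc: float
    auc: float | None = None

    def as_dict(self, percent: bool = False) -> dict:
        s = 100.0 if percent else 1.0
        d = {
            "acc": self.acc * s,
            "sen": self.sen * s,
            "spe": self.spe * s,
            "mcc": self.mcc * s,
            "bacc": self.bacc * s,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for 0/1 label vectors of equal length."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    for v in (y_true, y_pred):
        if not np.all(np.isin(v, (0, 1))):
            raise ValueError("labels must be 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(c: ConfusionCounts, auc_value: float | None = None) -> MetricSet:
    """The five confusion-matrix scores; see the module docstring for formulas."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    acc = (tp + tn) / (tp + tn + fp + fn)
    sen = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spe = tn / (tn + fp) if tn + fp > 0 else float("nan")
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(denom) if denom > 0 else 0.0
    bacc = (sen + spe) / 2.0
    return MetricSet(acc=acc, sen=sen, spe=spe, mcc=mcc, bacc=bacc, auc=auc_value)


def roc_curve(y_true: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points swept over all distinct score thresholds.

    A sample is called positive iff its score strictly exceeds the
    threshold (matching the ensemble's strict voting rule); the curve is
    anchored at (0, 0) and (1, 1) and sorted by FPR then TPR.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for t in np.unique(scores):
        pred = (scores > t).astype(int)
        tpr = np.sum((pred == 1) & (y_true == 1)) / n_pos
        fpr = np.sum((pred == 1) & (y_true == 0)) / n_neg
        pts.add((float(fpr), float(tpr)))
    return np.array(sorted(pts))


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve returned by :func:`roc_curve`."""
    points = np.asarray(points, dtype=float)
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    return auc(roc_curve(y_true, scores))


def undersample(X: FeatureMatrix, rng: np.random.Generator) -> FeatureMatrix:
    """Balance classes: keep the minority, subsample the majority to match.

    The result is shuffled; with already balanced input this reduces to
    a permutation of the dataset.
    """
    if X.labels is None:
        raise ValueError("undersampling requires labels")
    pos = np.flatnonzero(X.labels == 1)
    neg = np.flatnonzero(X.labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("undersampling requires both classes present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    kept = rng.choice(majority, size=len(minority), replace=False)
    idx = np.concatenate([minority, kept])
    rng.shuffle(idx)
    return X.subset(idx)


@dataclass
class CvReport:
    per_fold: list[MetricSet]
    mean: MetricSet
    sd: MetricSet
    n_folds: int
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "per_fold": [m.as_dict(percent=True) for m in self.per_fold],
            "mean": self.mean.as_dict(percent=True),
            "sd": self.sd.as_dict(percent=True),
        }

    def to_markdown(self) -> str:
        """Fold-by-fold table in percent, columns Acc/Sen/Spe/MCC/B_Acc (+AUC)."""
        has_auc = all(m.auc is not None for m in self.per_fold)
        cols = ["Fold", "Acc. (%)", "Sen. (%)", "Spe. (%)", "MCC (%)", "B_Acc. (%)"]
        if has_auc:
            cols.append("AUC")
        lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]

        def row(label: str, m: MetricSet, s: MetricSet | None = None) -> str:
            def cell(v, sd_v=None):
                txt = f"{v * 100:.2f}"
                if sd_v is not None:
                    txt += f" ± {sd_v * 100:.2f}"
                return txt

            cells = [label]
            for f_name in ("acc", "sen", "spe", "mcc", "bacc"):
                cells.append(cell(getattr(m, f_name), getattr(s, f_name) if s else None))
            if has_auc:
                a = f"{m.auc:.4f}"
                if s is not None and s.auc is not None:
                    a += f" ± {s.auc:.4f}"
                cells.append(a)
            return "| " + " | ".join(cells) + " |"

        for i, m in enumerate(self.per_fold, start=1):
            lines.append(row(str(i), m))
        lines.append(row("Average", self.mean, self.sd))
        return "\n".join(lines)


def aggregate_folds(per_fold: list[MetricSet], n_folds: int, seed: int) -> CvReport:
    """Arithmetic mean and sample (n−1) SD of per-fold metrics.

    NaN fold values (degenerate Sen/Spe) are excluded with a warning.
    """

    def agg(attr: str, fn) -> float | None:
        vals = [getattr(m, attr) for m in per_fold]
        if attr == "auc" and any(v is None for v in vals):
            return None
        arr = np.asarray(vals, dtype=float)
        if np.isnan(arr).any():
            warnings.warn(f"excluding NaN fold values of {attr} from the average")
            arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            return float("nan")
        return float(fn(arr))

    mean = MetricSet(**{a: agg(a, np.mean) for a in ("acc", "sen", "spe", "mcc", "bacc", "auc")})
    def _sample_sd(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1)) if v.size > 1 else float("nan")

    sd = MetricSet(
        **{a: agg(a, _sample_sd) for a in ("acc", "sen", "spe", "mcc", "bacc", "auc")}
    )
    return CvReport(per_fold=per_fold, mean=mean, sd=sd, n_folds=n_folds, seed=seed)


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition; returns the test-index array per fold."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, cannot stratify into {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def _fit_predict(
    train: FeatureMatrix, test: FeatureMatrix, model_spec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the configured classifier; return (hard labels, ROC scores)."""
    if isinstance(model_spec, RpConfig):
        rng = np.random.default_rng(seed)
        model = rp_ensemble.fit(train, model_spec, rng)
        scores = rp_ensemble.vote_fraction(model, test)
        return (scores > model.alpha).astype(int), scores
    if isinstance(model_spec, SvmConfig):
        model = train_svm(train, model_spec)
        return model.predict(test), model.decision_score(test)
    raise TypeError(f"unsupported model spec {type(model_spec).__name__}")


def kfold_cv(
    X: FeatureMatrix,
    model_spec: RpConfig | SvmConfig,
    n_folds: int = 5,
    seed: int = 0,
    pca_q: int = 300,
    pca_global: bool = False,
    folds: list[np.ndarray] | None = None,
) -> CvReport:
    """Stratified k-fold cross-validation of the full PCA + classifier pipeline.

    ``folds`` may be supplied to share fold assignments across model
    arms for a paired comparison; otherwise they are derived from
    ``seed``. ``pca_q`` is capped at min(n_train − 1, n_features) so
    small datasets remain usable.
    """
    if X.labels is None:
        raise ValueError("cross-validation requires labels")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if folds is None:
        folds = stratified_folds(X.labels, n_folds, seed)

    all_idx = np.arange(X.n_samples)
    global_model = None
    if pca_global:
        q = min(pca_q, X.n_samples - 1, X.n_features)
        global_model = pca_fit(X, q)

    per_fold: list[MetricSet] = []
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train, test = X.subset(train_idx), X.subset(test_idx)
        if not X.reduced:
            if global_model is not None:
                pm = global_model
            else:
                q = min(pca_q, train.n_samples - 1, train.n_features)
                pm = pca_fit(train, q)
            train, test = pca_transform(pm, train), pca_transform(pm, test)
        y_pred, scores = _fit_predict(train, test, model_spec, seed=seed + fold_i)
        auc_val = None
        if len(np.unique(test.labels)) == 2:
            auc_val = roc_auc(test.labels, scores)
        per_fold.append(metrics(confusion(test.labels, y_pred), auc_value=auc_val))
    return aggregate_folds(per_fold, n_folds, seed)
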