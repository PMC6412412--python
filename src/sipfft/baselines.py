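"""SVM comparison arm.

A thin contract around scikit-learn's ``SVC`` (libsvm underneath) with
the soft-margin RBF configuration used as the comparison classifier:
penalty c = 0.03 and kernel width g = 1200, K(x, y) = exp(-g ||x - y||^2).
The decision-function value serves as the continuous ROC score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from sipfft.features import FeatureMatrix

KERNELS = ("linear", "polynomial", "rbf", "sigmoid")


@dataclass
class SvmConfig:
    kernel: str = "rbf"
    c: float = 0.03
    g: float = 1200.0
    scale: bool = False  # standardise features before training
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if self.c <= 0 or self.g <= 0:
            raise ValueError("c and g must be positive")


class SvmModel:
    """Trained SVM exposing hard labels and a continuous decision score."""

    def __init__(self, clf: SVC, mean: np.ndarray | None = None, sd: np.ndarray | None = None):
        self._clf = clf
        self._mean = mean
        self._sd = sd

    def _prep(self, X: FeatureMatrix) -> np.ndarray:
        if self._mean is None:
            return X.X
        return (X.X - self._mean) / self._sd

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        return self._clf.predict(self._prep(X)).astype(int)

    def decision_score(self, X: FeatureMatrix) -> np.ndarray:
        return self._clf.decision_function(self._prep(X))


def train_svm(X_train: FeatureMatrix, cfg: SvmConfig | None = None) -> SvmModel:
    if cfg is None:
        cfg = SvmConfig()
    if X_train.labels is None:
        raise ValueError("training features must carry labels")
    if len(np.unique(X_train.labels)) < 2:
        raise ValueError("training data must contain both classes")
    kernel = "poly" if cfg.kernel == "polynomial" else cfg.kernel
    clf = SVC(kernel=kernel, C=cfg.c, gamma=cfg.g, random_state=cfg.seed)
    mean = sd = None
    Xt = X_train.X
    if cfg.scale:
        mean = Xt.mean(axis=0)
        sd = Xt.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xt = (Xt - mean) / sd
    clf.fit(Xt, X_train.labels)
    return SvmModel(clf, mean, sd)
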