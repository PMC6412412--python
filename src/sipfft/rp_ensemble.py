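"""Random-projection ensemble classifier with KNN base learners.

Training draws B1 x B2 random projections onto a low dimension q,
partitioned into B1 non-overlapping blocks of B2 candidates. Within a
block each candidate projects the training set and a k-nearest-neighbour
classifier is scored by its leave-one-out (LOO) error over a grid of k;
the candidate (and k) with the smallest LOO error is kept. The B1
selected members each vote on new samples, and a sample is called
positive when the fraction of members voting positive exceeds a
data-driven threshold alpha, set to the training-class prevalence so
that the ensemble remains usable on imbalanced data.

All randomness flows through one seeded ``numpy.random.Generator``;
given (data, config, seed) a run is exactly reproducible.

Deterministic tie-breaking (documented contract):

* equidistant neighbours — lowest training index wins (stable sort);
* even-k vote ties — class 1 iff the training class-1 prior >= 0.5;
* candidate projections with equal minimal LOO error — earliest drawn;
* k values with equal LOO error — smallest k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from sipfft.features import FeatureMatrix

PROJECTION_LAWS = ("gaussian", "bernoulli", "identity")


@dataclass
class RpConfig:
    """Ensemble hyperparameters.

    B1 selected projections (ensemble size), B2 candidates per block,
    projected dimension q (never reported in the source method; small q
    is the norm in the random-projection ensemble literature), the KNN
    k grid (1, 4, 7, ..., 40), and the projection law. ``identity`` is a
    degeneracy hook: R is the identity map (requires q == n_features),
    which reduces the ensemble to plain KNN when B1 = B2 = 1.
    """

    B1: int = 10
    B2: int = 30
    q: int = 5
    k_grid: tuple[int, ...] = tuple(range(1, 41, 3))
    projection_law: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B1 < 1 or self.B2 < 1 or self.q < 1:
            raise ValueError("B1, B2 and q must be >= 1")
        if not self.k_grid or min(self.k_grid) < 1:
            raise ValueError("k_grid values must be >= 1")
        if self.projection_law not in PROJECTION_LAWS:
            raise ValueError(f"projection_law must be one of {PROJECTION_LAWS}")


@dataclass
class ProjectionMatrix:
    """A q x n random projection whose columns have unit l2 norm."""

    R: np.ndarray
    law: str

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        norms = np.linalg.norm(self.R, axis=0)
        if np.max(np.abs(norms - 1.0)) > 1e-10:
            raise ValueError("projection columns must have unit l2 norm")

    def project(self, X: np.ndarray) -> np.ndarray:
        """Embed samples (rows of X) into R^q; returns q x n_samples."""
        return self.R @ X.T


def sample_projection(n: int, q: int, law: str, rng: np.random.Generator) -> ProjectionMatrix:
    """Draw a q x n projection from the given law and normalise its columns."""
    if q < 1 or n < 1:
        raise ValueError("q and n must be >= 1")
    if law == "gaussian":
        R = rng.standard_normal((q, n))
    elif law == "bernoulli":
        R = rng.choice([-1.0, 1.0], size=(q, n))
    elif law == "identity":
        if q != n:
            raise ValueError("identity projection requires q == n")
        R = np.eye(n)
    else:
        raise ValueError(f"unknown projection law {law!r}")
    R = R / np.linalg.norm(R, axis=0, keepdims=True)
    return ProjectionMatrix(R=R, law=law)


def _tie_class(y: np.ndarray) -> int:
    return 1 if y.mean() >= 0.5 else 0


def _vote(pos_counts: np.ndarray, k: int, tie: int) -> np.ndarray:
    """Majority vote from class-1 counts among k neighbours."""
    pred = np.where(pos_counts * 2 > k, 1, 0)
    if k % 2 == 0:
        pred = np.where(pos_counts * 2 == k, tie, pred)
    return pred


def _loo_errors_over_k(Z: np.ndarray, y: np.ndarray, k_grid: tuple[int, ...]) -> np.ndarray:
    """LOO misclassification rate for every k in the grid at once.

    Z is q x n (samples as columns). One stable argsort of the pairwise
    distances serves all k values via cumulative neighbour-label counts.
    """
    n = Z.shape[1]
    if max(k_grid) >= n:
        raise ValueError(f"k={max(k_grid)} must be < n={n}")
    D = cdist(Z.T, Z.T)
    np.fill_diagonal(D, np.inf)  # leave-one-out: self excluded
    order = np.argsort(D, axis=1, kind="stable")
    neigh_labels = y[order]  # n x (n-1 usable)
    cum = np.cumsum(neigh_labels, axis=1)
    tie = _tie_class(y)
    errs = np.empty(len(k_grid))
    for j, k in enumerate(k_grid):
        pred = _vote(cum[:, k - 1], k, tie)
        errs[j] = np.mean(pred != y)
    return errs


def knn_loo_error(Z: np.ndarray, y: np.ndarray, k: int) -> float:
    """Leave-one-out KNN error on projected data Z (q x n), labels y."""
    y = np.asarray(y, dtype=int)
    return float(_loo_errors_over_k(np.asarray(Z, dtype=float), y, (k,))[0])


def knn_predict(
    Z_train: np.ndarray, y_train: np.ndarray, Z_test: np.ndarray, k: int
) -> np.ndarray:
    """KNN labels for projected test samples (both matrices q x n)."""
    D = cdist(Z_test.T, Z_train.T)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    pos_counts = y_train[order].sum(axis=1)
    return _vote(pos_counts, k, _tie_class(y_train))


@dataclass
class EnsembleMember:
    """One selected projection with its tuned k and projected training data."""

    projection: ProjectionMatrix
    k: int
    projected_train: np.ndarray
    train_labels: np.ndarray
    loo_error: float


@dataclass
class RpEnsembleModel:
    config: RpConfig
    members: list[EnsembleMember]
    alpha: float  # voting threshold = training class-1 prevalence

    def save(self, path: str | Path) -> None:
        d = {
            "config": {
                "B1": self.config.B1,
                "B2": self.config.B2,
                "q": self.config.q,
                "k_grid": list(self.config.k_grid),
                "projection_law": self.config.projection_law,
                "seed": self.config.seed,
            },
            "alpha": self.alpha,
            "members": [
                {
                    "R": m.projection.R.tolist(),
                    "law": m.projection.law,
                    "k": m.k,
                    "projected_train": m.projected_train.tolist(),
                    "train_labels": m.train_labels.tolist(),
                    "loo_error": m.loo_error,
                }
                for m in self.members
            ],
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: str | Path) -> "RpEnsembleModel":
        d = json.loads(Path(path).read_text())
        cfg = RpConfig(
            B1=d["config"]["B1"],
            B2=d["config"]["B2"],
            q=d["config"]["q"],
            k_grid=tuple(d["config"]["k_grid"]),
            projection_law=d["config"]["projection_law"],
            seed=d["config"]["seed"],
        )
        members = [
            EnsembleMember(
                projection=ProjectionMatrix(R=np.asarray(m["R"]), law=m["law"]),
                k=int(m["k"]),
                projected_train=np.asarray(m["projected_train"], dtype=float),
                train_labels=np.asarray(m["train_labels"], dtype=int),
                loo_error=float(m["loo_error"]),
            )
            for m in d["members"]
        ]
        return cls(config=cfg, members=members, alpha=float(d["alpha"]))


def select_member(X_train: FeatureMatrix, cfg: RpConfig, rng: np.random.Generator) -> EnsembleMember:
    """Pick the best of B2 candidate projections by minimal LOO error.

    Each candidate's error is its minimum over the k grid; the earliest
    drawn candidate wins error ties, and the smallest k wins k ties.
    """
    if X_train.labels is None:
        raise ValueError("training features must carry labels")
    y = X_train.labels
    n_train = X_train.n_samples
    k_grid = tuple(k for k in cfg.k_grid if k < n_train)
    if not k_grid:
        raise ValueError(f"all k_grid values >= n_train={n_train}")

    best: tuple[float, int, ProjectionMatrix, np.ndarray] | None = None
    for _ in range(cfg.B2):
        proj = sample_projection(X_train.n_features, cfg.q, cfg.projection_law, rng)
        Z = proj.project(X_train.X)
        errs = _loo_errors_over_k(Z, y, k_grid)
        j = int(np.argmin(errs))  # argmin takes the first minimum: smallest k
        if best is None or errs[j] < best[0]:
            best = (float(errs[j]), k_grid[j], proj, Z)
    err, k, proj, Z = best
    return EnsembleMember(
        projection=proj, k=k, projected_train=Z, train_labels=y.copy(), loo_error=err
    )


def fit(
    X_train: FeatureMatrix, cfg: RpConfig, rng: np.random.Generator | None = None
) -> RpEnsembleModel:
    """Train the ensemble: B1 selected members plus the prevalence threshold."""
    if X_train.labels is None:
        raise ValueError("training features must carry labels")
    y = X_train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    members = [select_member(X_train, cfg, rng) for _ in range(cfg.B1)]
    alpha = float(y.mean())
    return RpEnsembleModel(config=cfg, members=members, alpha=alpha)


def vote_fraction(model: RpEnsembleModel, X: FeatureMatrix) -> np.ndarray:
    """Per-sample fraction of ensemble members voting class 1.

    This is the model's only continuous output and doubles as the ROC
    score.
    """
    n_feat = model.members[0].projection.R.shape[1]
    if X.n_features != n_feat:
        raise ValueError(f"feature count {X.n_features} does not match training ({n_feat})")
    votes = np.zeros(X.n_samples)
    for m in model.members:
        Z_test = m.projection.project(X.X)
        votes += knn_predict(m.projected_train, m.train_labels, Z_test, m.k)
    return votes / len(model.members)


def predict(model: RpEnsembleModel, X: FeatureMatrix) -> np.ndarray:
    """Hard labels: positive iff the vote fraction strictly exceeds alpha."""
    return (vote_fraction(model, X) > model.alpha).astype(int)
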