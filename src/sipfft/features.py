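"""Fixed-length descriptors from variable-length PSSM profiles.

The length problem: proteins differ in length N, so the raw N x 20
profile cannot feed a fixed-dimension classifier. Multiplying the
transpose of the PSSM by the PSSM itself yields a 20 x 20 Gram matrix
independent of N; a 2-D discrete Fourier transform of that matrix,
taken in modulus, gives the 400-dimensional spectral descriptor used by
the main pipeline. DCT, SVD and column-covariance descriptors are
provided as comparison extractors, and PCA reduces the 400 features to
300 (capped for small datasets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import dctn
from sklearn.decomposition import PCA

from sipfft.pssm_io import PssmProfile

EXTRACTORS = ("FFT", "DCT", "SVD", "COV")


@dataclass
class FeatureMatrix:
    """Rows = proteins, columns = descriptor features, optional 0/1 labels."""

    ids: list[str]
    X: np.ndarray
    labels: np.ndarray | None = None
    extractor: str = "FFT"
    reduced: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids length must match number of rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.X.shape[0],):
                raise ValueError("labels must be one per row")
            if not np.all(np.isin(self.labels, (0, 1))):
                raise ValueError("labels must be 0/1")
        if self.extractor not in EXTRACTORS:
            raise ValueError(f"extractor must be one of {EXTRACTORS}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            labels=None if self.labels is None else self.labels[idx],
            extractor=self.extractor,
            reduced=self.reduced,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=[f"f{j + 1:04d}" for j in range(self.n_features)])
        df.insert(0, "id", self.ids)
        df.insert(1, "label", self.labels if self.labels is not None else -1)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, extractor: str = "FFT", reduced: bool = False) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = df["label"].to_numpy()
        return cls(
            ids=df["id"].astype(str).tolist(),
            X=df.drop(columns=["id", "label"]).to_numpy(dtype=float),
            labels=None if (labels < 0).any() else labels,
            extractor=extractor,
            reduced=reduced,
        )


def gram_matrix(p: PssmProfile, zscore_columns: bool = False) -> np.ndarray:
    """20 x 20 Gram matrix M'M of the profile: symmetric PSD, length-free.

    ``zscore_columns`` standardises each amino-acid channel to zero mean
    and unit variance before the product (experimental; raw log-odds
    values are the default input).
    """
    M = p.matrix
    if zscore_columns:
        sd = M.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        M = (M - M.mean(axis=0)) / sd
    return M.T @ M


def fft_features(A: np.ndarray) -> np.ndarray:
    """Modulus of the 2-D DFT of a 20 x 20 matrix, flattened row-major.

    The transform is normalised by 1/N along each axis, so the DC
    coefficient equals the matrix mean.
    """
    A = np.asarray(A, dtype=float)
    coeffs = np.fft.fft2(A) / (A.shape[0] * A.shape[1])
    return np.abs(coeffs).ravel()


def dct_features(A: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D type-II DCT coefficients, flattened row-major."""
    return dctn(np.asarray(A, dtype=float), type=2, norm="ortho").ravel()


def svd_features(A: np.ndarray) -> np.ndarray:
    """Left singular vectors scaled by singular values (U·S), flattened."""
    U, S, _ = np.linalg.svd(np.asarray(A, dtype=float))
    return (U * S).ravel()


def cov_features(p: PssmProfile) -> np.ndarray:
    """Sample covariance (denominator N-1) of the 20 PSSM columns, flattened."""
    if p.length < 2:
        raise ValueError("covariance features require at least 2 positions")
    return np.cov(p.matrix, rowvar=False).ravel()


def extract_features(
    profiles: Sequence[PssmProfile],
    labels: Sequence[int] | None = None,
    extractor: str = "FFT",
    zscore_columns: bool = False,
) -> FeatureMatrix:
    """Build the n x 400 descriptor matrix for a set of profiles."""
    extractor = extractor.upper()
    if extractor == "FFT":
        rows = [fft_features(gram_matrix(p, zscore_columns)) for p in profiles]
    elif extractor == "DCT":
        rows = [dct_features(gram_matrix(p, zscore_columns)) for p in profiles]
    elif extractor == "SVD":
        rows = [svd_features(gram_matrix(p, zscore_columns)) for p in profiles]
    elif extractor == "COV":
        rows = [cov_features(p) for p in profiles]
    else:
        raise ValueError(f"unknown extractor {extractor!r}; choose from {EXTRACTORS}")
    return FeatureMatrix(
        ids=[p.protein_id for p in profiles],
        X=np.vstack(rows),
        labels=None if labels is None else np.asarray(labels, dtype=int),
        extractor=extractor,
    )


@dataclass
class PcaModel:
    """Fitted principal-component model: mean, orthonormal components, variances."""

    mean: np.ndarray
    components: np.ndarray  # p x q, orthonormal columns
    explained_variance: np.ndarray
    q: int

    def to_json_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "q": self.q,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PcaModel":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            q=int(d["q"]),
        )


def pca_cap(n_samples: int, n_features: int, q: int = 300) -> int:
    """Largest admissible component count for the requested q."""
    return min(q, n_samples - 1, n_features)


def pca_fit(X: FeatureMatrix, q: int = 300) -> PcaModel:
    """Fit mean-centred PCA keeping the top q components by variance."""
    cap = min(X.n_samples - 1, X.n_features)
    if q > cap:
        raise ValueError(f"q={q} exceeds min(n_samples - 1, n_features) = {cap}")
    pca = PCA(n_components=q, svd_solver="full")
    pca.fit(X.X)
    return PcaModel(
        mean=pca.mean_,
        components=pca.components_.T,
        explained_variance=pca.explained_variance_,
        q=q,
    )


def pca_transform(model: PcaModel, X: FeatureMatrix) -> FeatureMatrix:
    """Project features onto the fitted components: (X - mean) · W."""
    if X.n_features != model.components.shape[0]:
        raise ValueError(
            f"feature count {X.n_features} does not match PCA model "
            f"({model.components.shape[0]} features)"
        )
    Z = (X.X - model.mean) @ model.components
    return FeatureMatrix(ids=list(X.ids), X=Z, labels=X.labels, extractor=X.extractor, reduced=True)
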