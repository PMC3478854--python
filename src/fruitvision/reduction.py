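"""Feature normalization and PCA energy-based dimensionality reduction.

Features are standardized to zero mean and unit variance (sample standard
deviation, denominator N-1) before PCA; PCA is an eigendecomposition of
the sample covariance whose components are sorted by decreasing variance.
The retained dimension k is the smallest number of leading components
whose cumulative explained-variance fraction ("energy") reaches a
threshold, 0.95 by default.  Fitting always happens on training data only
and the fitted transform is applied unchanged to held-out data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

SERIALIZATION_VERSION = 1


@dataclass
class NormalizationModel:
    means: np.ndarray
    deviations: np.ndarray          # zero-variance columns stored as 1.0
    constant: np.ndarray            # flags for zero-variance columns

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.means.shape[0]:
            raise ValueError(
                f"expected {self.means.shape[0]} columns, got {X.shape[1]}"
            )
        return (X - self.means) / self.deviations


@dataclass
class PCAModel:
    loadings: np.ndarray            # p x p, columns are components
    eigenvalues: np.ndarray         # non-increasing, >= 0
    explained: np.ndarray           # fractions of total variance, sum to 1
    k: int | None = None            # selected number of components

    def scores(self, X_normalized: np.ndarray, k: int | None = None) -> np.ndarray:
        k = k if k is not None else (self.k or self.loadings.shape[1])
        return np.asarray(X_normalized) @ self.loadings[:, :k]


def fit_normalization(X: np.ndarray) -> NormalizationModel:
    """Per-column mean/std (ddof=1); constant columns flagged, std set to 1."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an N x p matrix with N >= 2")
    means = X.mean(axis=0)
    devs = X.std(axis=0, ddof=1)
    constant = devs == 0.0
    devs = np.where(constant, 1.0, devs)
    return NormalizationModel(means=means, deviations=devs, constant=constant)


def fit_pca(X_normalized: np.ndarray) -> PCAModel:
    """PCA of standardized data via covariance eigendecomposition.

    Components are ordered by decreasing eigenvalue.  Sign convention:
    the largest-magnitude entry of each loading column is positive, which
    makes the decomposition deterministic.
    """
    X = np.asarray(X_normalized, dtype=np.float64)
    n, p = X.shape
    cov = (X - X.mean(axis=0)).T @ (X - X.mean(axis=0)) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|entry| of each column made positive
    pivot = np.argmax(np.abs(eigvecs), axis=0)
    signs = np.sign(eigvecs[pivot, np.arange(p)])
    signs[signs == 0] = 1.0
    eigvecs = eigvecs * signs
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else np.full(p, 1.0 / p)
    return PCAModel(loadings=eigvecs, eigenvalues=eigvals, explained=explained)


def select_components(model: PCAModel, energy: float = 0.95) -> int:
    """Smallest k whose cumulative explained-variance fraction >= energy.

    With energy = 1.0 this is the number of components with nonzero
    eigenvalue (the data's rank).
    """
    if not 0.0 < energy <= 1.0:
        raise ValueError("energy must lie in (0, 1]")
    if energy == 1.0:
        return int(np.count_nonzero(model.eigenvalues > 1e-12 * max(
            model.eigenvalues.max(), 1.0
        )))
    cum = np.cumsum(model.explained)
    return int(np.searchsorted(cum, energy - 1e-12) + 1)


@dataclass
class ReductionModel:
    """Fitted normalization + PCA with a selected dimension."""

    normalization: NormalizationModel
    pca: PCAModel
    k: int
    energy: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.scores(self.normalization.transform(X), self.k)


def fit_reduction(X: np.ndarray, energy: float = 0.95) -> ReductionModel:
    """Standardize, fit PCA, and select the energy-reaching dimension."""
    norm = fit_normalization(X)
    pca = fit_pca(norm.transform(X))
    k = select_components(pca, energy)
    pca.k = k
    return ReductionModel(normalization=norm, pca=pca, k=k, energy=energy)


def transform(
    normalization: NormalizationModel,
    pca: PCAModel,
    X: np.ndarray,
    k: int,
) -> np.ndarray:
    """Normalize then project onto the first k principal components."""
    return pca.scores(normalization.transform(X), k)


# ---------------------------------------------------------------------------
# serialization


def reduction_to_dict(model: ReductionModel) -> dict:
    return {
        "version": SERIALIZATION_VERSION,
        "kind": "reduction",
        "means": model.normalization.means.tolist(),
        "deviations": model.normalization.deviations.tolist(),
        "constant": model.normalization.constant.astype(int).tolist(),
        "loadings": model.pca.loadings.tolist(),
        "eigenvalues": model.pca.eigenvalues.tolist(),
        "k": model.k,
        "energy": model.energy,
    }


def save_reduction(model: ReductionModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(reduction_to_dict(model), fh)


def reduction_from_dict(payload: dict) -> ReductionModel:
    if payload.get("kind") != "reduction":
        raise ValueError("not a reduction model payload")
    norm = NormalizationModel(
        means=np.array(payload["means"]),
        deviations=np.array(payload["deviations"]),
        constant=np.array(payload["constant"], dtype=bool),
    )
    eigvals = np.array(payload["eigenvalues"])
    total = eigvals.sum()
    pca = PCAModel(
        loadings=np.array(payload["loadings"]),
        eigenvalues=eigvals,
        explained=eigvals / total if total > 0 else eigvals,
        k=int(payload["k"]),
    )
    return ReductionModel(
        normalization=norm, pca=pca, k=int(payload["k"]), energy=payload["energy"]
    )


def load_reduction(path) -> ReductionModel:
    with open(path) as fh:
        return reduction_from_dict(json.load(fh))
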