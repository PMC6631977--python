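"""Principal component analysis with a cumulative-variance selection rule.

The number of score dimensions fed to the classifier is the smallest k whose
cumulative explained-variance contribution reaches a threshold (default
85.0%).  If the threshold is still unreached at a hard cap (default 20
components) the model is flagged invalid ("NA"): downstream classification is
refused rather than run on a feature set that fails the rule.

Fitting is a mean-centered SVD on the calibration matrix only; validation
spectra are projected with the calibration mean and loadings (no leakage).
Loading signs are fixed so the largest-magnitude element of each column is
positive, making runs reproducible across SVD implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DegenerateDataError, NAModelError, ShapeError, StateError

PCA_VARIANCE_THRESHOLD_PCT = 85.0
PCA_COMPONENT_CAP = 20


@dataclass
class PCAModel:
    """Fitted PCA: mean, orthonormal loadings, explained ratios (percent)."""

    mean: np.ndarray
    loadings: np.ndarray  # (n_points, k_max), orthonormal columns
    explained_ratio: np.ndarray  # percent of total variance per retained PC
    k_selected: int | None = None
    valid: bool = True

    @property
    def k_max(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_ratio(self) -> np.ndarray:
        return np.cumsum(self.explained_ratio)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            mean=self.mean,
            loadings=self.loadings,
            explained_ratio=self.explained_ratio,
            k_selected=np.asarray(-1 if self.k_selected is None else self.k_selected),
            valid=np.asarray(self.valid),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path) as data:
            k = int(data["k_selected"])
            return cls(
                mean=data["mean"],
                loadings=data["loadings"],
                explained_ratio=data["explained_ratio"],
                k_selected=None if k < 0 else k,
                valid=bool(data["valid"]),
            )


def fit_pca(X: np.ndarray, k_max: int = PCA_COMPONENT_CAP) -> PCAModel:
    """Fit PCA on a preprocessed calibration matrix (n_spectra x n_points).

    Explained ratios are singular values squared over the total centered
    variance (in percent), so they refer to the full variance even when only
    ``k_max`` loading columns are retained.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise DegenerateDataError("PCA needs at least 2 spectra")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise DegenerateDataError("PCA input has zero variance")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ratios = 100.0 * s**2 / np.sum(s**2)
    k_max = min(k_max, vt.shape[0])
    loadings = vt[:k_max].T
    # deterministic sign: largest-|.| element of each loading column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k_max)])
    flip[flip == 0] = 1.0
    return PCAModel(mean=mean, loadings=loadings * flip, explained_ratio=ratios[:k_max])


def select_n_pcs(
    model: PCAModel,
    threshold_pct: float = PCA_VARIANCE_THRESHOLD_PCT,
    cap: int = PCA_COMPONENT_CAP,
) -> PCAModel:
    """Apply the cumulative-variance rule; flag the model NA if it fails.

    ``k_selected`` becomes the smallest k with cumulative explained variance
    >= ``threshold_pct``.  If no k up to ``cap`` (or the available rank,
    whichever is smaller) reaches the threshold, the model is returned with
    ``valid=False`` and ``k_selected`` pinned at the cap.
    """
    cap_eff = min(cap, model.k_max)
    cum = model.cumulative_ratio[:cap_eff]
    reached = np.flatnonzero(cum >= threshold_pct)
    if reached.size:
        return replace(model, k_selected=int(reached[0]) + 1, valid=True)
    return replace(model, k_selected=cap_eff, valid=False)


def project(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Score matrix ``(X - mean) @ loadings[:, :k_selected]``."""
    if not model.valid:
        raise NAModelError(
            "PCA model is flagged NA (variance threshold unreachable at cap)"
        )
    if model.k_selected is None:
        raise StateError("select_n_pcs must run before projecting")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ShapeError(f"X has {X.shape[1]} points, model expects {model.mean.size}")
    return (X - model.mean) @ model.loadings[:, : model.k_selected]
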