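"""PCA over standardized feature columns with contribution-rate selection.

Features mix units (volts, hertz, dimensionless entropy), so columns are
standardized to zero mean and unit variance before the eigendecomposition
— i.e. PCA on the correlation structure.  Components are ranked by their
contribution rate (percent of total variance) and the smallest leading set
whose cumulative rate reaches a threshold (default 95 %) is retained.

The model is fit on training rows only and applied unchanged to test rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = ["PCAModel", "fit_pca", "select_components", "transform"]


@dataclass
class PCAModel:
    """Standardization statistics plus eigenstructure of the feature columns.

    ``components`` holds orthonormal loading vectors as rows, ordered by
    descending eigenvalue; ``contribution_rates`` are percentages summing
    to 100.
    """

    column_means: np.ndarray
    column_scales: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    eigenvalues: np.ndarray
    contribution_rates: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "column_means": self.column_means.tolist(),
            "column_scales": self.column_scales.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "contribution_rates": self.contribution_rates.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(*(np.asarray(d[k]) for k in (
            "column_means", "column_scales", "components",
            "eigenvalues", "contribution_rates")))


def fit_pca(features: FeatureMatrix) -> PCAModel:
    """Eigendecomposition of the standardized feature covariance.

    Constant columns get a unit scale floor (with a warning) so they
    contribute a zero-variance direction instead of dividing by zero.
    """
    x = features.to_numpy()
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit PCA")
    if x.shape[1] < 1:
        raise ValueError("need at least 1 feature column")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    degenerate = scales < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant feature column(s); unit scale applied"
        )
        scales = np.where(degenerate, 1.0, scales)
    xs = (x - means) / scales
    cov = np.cov(xs, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    components = eigvecs[:, order].T
    total = eigvals.sum()
    rates = 100.0 * eigvals / total if total > 0 else np.full_like(eigvals, 0.0)
    return PCAModel(means, scales, components, eigvals, rates)


def select_components(contribution_rates, threshold: float = 95.0) -> int:
    """Smallest k whose leading cumulative contribution reaches ``threshold`` %."""
    rates = np.asarray(contribution_rates, dtype=float)
    if rates.size == 0:
        raise ValueError("empty contribution-rate list")
    if np.any(rates < 0):
        raise ValueError("contribution rates must be non-negative")
    if not 0 < threshold <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    cum = np.cumsum(rates)
    hit = np.flatnonzero(cum >= threshold - 1e-9)
    return int(hit[0]) + 1 if hit.size else rates.size


def transform(model: PCAModel, features: FeatureMatrix, k: int) -> FeatureMatrix:
    """Project rows onto the first ``k`` loadings after standardization."""
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k={k} out of range [1, {model.n_components}]")
    x = features.to_numpy()
    xs = (x - model.column_means) / model.column_scales
    scores = xs @ model.components[:k].T
    df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    return FeatureMatrix(df, features.labels.copy(),
                         np.asarray(features.window_starts).copy())
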