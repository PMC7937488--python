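"""Splitting, scoring and aggregation of gait-phase recognition results.

Recognition is reported the way the gait literature tabulates it: a 4x4
confusion matrix (true phase x predicted phase), the per-phase
recognition rate (diagonal count over row total, in percent), and an
*unweighted* mean of the four per-phase rates as the overall rate.  The
unweighted mean — rather than plain accuracy — keeps short phases such as
preswing from being swamped by long ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .features import FeatureMatrix
from .synthetic import PHASE_NAMES

__all__ = [
    "EvaluationReport",
    "split",
    "per_phase_rates",
    "overall_from_rates",
    "improvement",
]


@dataclass
class EvaluationReport:
    confusion: np.ndarray  # (4, 4) counts
    per_phase: np.ndarray  # percent per phase, NaN if phase absent
    overall: float  # unweighted mean over phases present
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_phase_rates": [None if np.isnan(v) else round(float(v), 4)
                                for v in self.per_phase],
            "overall_rate": round(float(self.overall), 4),
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        """One-row table mirroring the usual report layout."""
        cols = {name: [self.per_phase[k]] for k, name in enumerate(PHASE_NAMES)}
        cols["overall"] = [self.overall]
        return pd.DataFrame(cols, index=[self.metadata.get("classifier", "model")])


def split(features: FeatureMatrix, train_fraction: float = 0.7,
          seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified, seeded, disjoint train/test split by phase label."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    counts = np.bincount(features.labels, minlength=4)
    present = counts[counts > 0]
    if np.any(present < 2):
        raise ValueError("every phase present needs at least 2 windows to split")
    idx = np.arange(len(features))
    tr, te = train_test_split(idx, train_size=train_fraction, random_state=seed,
                              stratify=features.labels)
    return features.select_rows(np.sort(tr)), features.select_rows(np.sort(te))


def per_phase_rates(true_labels: np.ndarray, predicted_labels: np.ndarray,
                    metadata: dict | None = None) -> EvaluationReport:
    """Confusion matrix, per-phase rates and their unweighted mean."""
    y, yhat = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.shape != yhat.shape:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(y, range(4)).all() and np.isin(yhat, range(4)).all()):
        raise ValueError("labels must lie in {0, 1, 2, 3}")
    cm = confusion_matrix(y, yhat, labels=[0, 1, 2, 3])
    row = cm.sum(axis=1)
    rates = np.full(4, np.nan)
    nz = row > 0
    rates[nz] = 100.0 * np.diag(cm)[nz] / row[nz]
    if not nz.all():
        missing = [PHASE_NAMES[k] for k in np.flatnonzero(~nz)]
        warnings.warn(f"phase(s) absent from true labels: {missing}; "
                      "excluded from the overall rate")
    overall = float(np.nanmean(rates))
    return EvaluationReport(cm, rates, overall, metadata or {})


def overall_from_rates(per_phase: np.ndarray | list[float]) -> float:
    """Unweighted mean of per-phase recognition rates (percent)."""
    return float(np.mean(np.asarray(per_phase, dtype=float)))


def improvement(optimized_overall: float, baseline_overall: float) -> float:
    """Optimized minus baseline overall rate, in percentage points."""
    if not (np.isfinite(optimized_overall) and np.isfinite(baseline_overall)):
        raise ValueError("rates must be finite")
    return float(optimized_overall - baseline_overall)
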