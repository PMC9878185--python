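"""Fisher-score feature ranking and top-k filtering.

The Fisher score of feature j with two classes k of sizes n_k is

    F_j = sum_k n_k (mu_jk - mu_j)^2  /  ( sum_k n_k s2_jk + eps )

with mu_j the grand mean, mu_jk the class means and s2_jk the within-class
*population* variances; eps = 1e-12 guards features that are constant
within both classes. High F means large between-class separation relative
to within-class spread. The score is invariant to rescaling a feature
(both numerator and denominator scale by c^2), so ranking does not depend
on standardization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FisherRanking", "fisher_score", "select_top_k"]

EPS = 1e-12


@dataclass
class FisherRanking:
    """Features ordered by descending Fisher score (ties: original column order)."""

    feature_names: list[str]
    scores: np.ndarray  # aligned to feature_names, non-increasing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_names) != len(self.scores):
            raise ValueError("names and scores must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.scores) + 1),
                "feature": self.feature_names,
                "fisher_score": self.scores,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def fisher_score(table: pd.DataFrame, labels: pd.Series) -> FisherRanking:
    """Rank every column of ``table`` by its two-class Fisher score."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    X = table.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    grand = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        nk = Xc.shape[0]
        if nk < 2:
            raise ValueError(f"class {c!r} has fewer than 2 subjects")
        num += nk * (Xc.mean(axis=0) - grand) ** 2
        den += nk * Xc.var(axis=0)  # population variance
    scores = num / (den + EPS)
    order = np.lexsort((np.arange(len(scores)), -scores))  # stable: ties by column index
    return FisherRanking(
        feature_names=[table.columns[i] for i in order],
        scores=scores[order],
    )


def select_top_k(ranking: FisherRanking, table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Restrict the table to the k highest-scoring columns, in ranking order."""
    if not 1 <= k <= len(ranking.feature_names):
        raise ValueError(f"k={k} out of range [1, {len(ranking.feature_names)}]")
    cols = ranking.feature_names[:k]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"ranked feature(s) absent from table: {missing}")
    return table[cols]
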