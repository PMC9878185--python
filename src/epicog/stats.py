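"""Two-group comparison statistics with FDR correction.

Continuous features are gated per group by a Shapiro-Wilk normality test
at alpha = 0.05: both groups normal -> independent-samples t-test,
otherwise Mann-Whitney U. Categorical features use Pearson chi-square, or
Fisher's exact test when any expected cell count of a 2x2 table drops
below 5. All tests two-sided; p-values across one analysis batch are
adjusted together by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "compare_feature",
    "compare_table",
    "fdr_correct",
    "pooled_mean",
]

NORMALITY_ALPHA = 0.05
MIN_EXPECTED_COUNT = 5


@dataclass
class ComparisonResult:
    feature_name: str
    test_used: str  # t | mann_whitney | chi_square | fisher_exact | constant
    statistic: float
    p: float
    p_fdr: float | None = None
    group_summaries: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _continuous_compare(name: str, a: np.ndarray, b: np.ndarray) -> ComparisonResult:
    summaries = {
        "group_0": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
        "group_1": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
    }
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return ComparisonResult(name, "constant", 0.0, 1.0, group_summaries=summaries,
                                warnings=["constant in both groups"])
    normal = True
    for g in (a, b):
        if len(g) >= 3 and np.ptp(g) > 0:
            normal &= sps.shapiro(g).pvalue > NORMALITY_ALPHA
        else:
            normal = False
    if normal:
        stat, p = sps.ttest_ind(a, b)
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return ComparisonResult(name, test, float(stat), float(p), group_summaries=summaries)


def _categorical_compare(name: str, a: np.ndarray, b: np.ndarray) -> ComparisonResult:
    cats = np.unique(np.concatenate([a, b]))
    counts = np.array(
        [[np.sum(g == c) for c in cats] for g in (a, b)], dtype=float
    )  # 2 x n_categories
    summaries = {
        "group_0": dict(zip([str(c) for c in cats], counts[0].astype(int))),
        "group_1": dict(zip([str(c) for c in cats], counts[1].astype(int))),
    }
    if len(cats) < 2:
        return ComparisonResult(name, "constant", 0.0, 1.0, group_summaries=summaries,
                                warnings=["constant in both groups"])
    return _contingency_result(name, counts, summaries)


def _contingency_result(name: str, counts: np.ndarray, summaries: dict) -> ComparisonResult:
    chi2, p, _, expected = sps.chi2_contingency(counts, correction=False)
    warnings = []
    if (expected < MIN_EXPECTED_COUNT).any():
        if counts.shape == (2, 2):
            stat, p = sps.fisher_exact(counts.astype(int))
            return ComparisonResult(name, "fisher_exact", float(stat), float(p),
                                    group_summaries=summaries)
        warnings.append("expected cell count < 5 in a table larger than 2x2; chi-square kept")
    return ComparisonResult(name, "chi_square", float(chi2), float(p),
                            group_summaries=summaries, warnings=warnings)


def compare_feature(
    values_group0,
    values_group1,
    feature_kind: str,
    feature_name: str = "",
    contingency: np.ndarray | None = None,
    method: str | None = None,
) -> ComparisonResult:
    """Compare one feature between two groups.

    feature_kind 'continuous' runs the normality-gated t / Mann-Whitney
    route; 'categorical' runs chi-square / Fisher exact. A pre-tabulated
    ``contingency`` (groups x categories) may be given instead of raw
    values. ``method`` forces a specific test ('t' or 'mann_whitney'),
    bypassing the normality gate.
    """
    if feature_kind == "categorical" and contingency is not None:
        counts = np.asarray(contingency, dtype=float)
        return _contingency_result(feature_name, counts, {})
    a = np.asarray(values_group0, dtype=float)
    b = np.asarray(values_group1, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if method is not None:
        if method == "t":
            stat, p = sps.ttest_ind(a, b)
        elif method == "mann_whitney":
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise ValueError(f"method override must be 't' or 'mann_whitney', got {method!r}")
        return ComparisonResult(feature_name, method, float(stat), float(p))
    if feature_kind == "continuous":
        return _continuous_compare(feature_name, a, b)
    if feature_kind == "categorical":
        return _categorical_compare(feature_name, a, b)
    raise ValueError(f"feature_kind must be continuous or categorical, got {feature_kind!r}")


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pooled_mean(group_means: list[tuple[float, int]]) -> float:
    """Sample-size-weighted pooled mean of per-group means."""
    if not group_means:
        raise ValueError("need at least one (mean, n) pair")
    if any(n <= 0 for _, n in group_means):
        raise ValueError("group sizes must be positive")
    total = sum(n for _, n in group_means)
    return sum(m * n for m, n in group_means) / total


def compare_table(
    table: pd.DataFrame,
    labels: pd.Series,
    kinds: dict[str, str],
    fdr: bool = True,
) -> pd.DataFrame:
    """Batch comparison of every column; one FDR family across the batch.

    ``kinds`` maps column name -> 'continuous' | 'categorical'. Returns a
    frame with per-group summaries, test used, raw p and BH-adjusted p'.
    """
    y = np.asarray(labels)
    results = []
    for col in table.columns:
        kind = kinds.get(col, "continuous")
        r = compare_feature(table[col].to_numpy()[y == 0], table[col].to_numpy()[y == 1],
                            kind, feature_name=col)
        results.append(r)
    out = pd.DataFrame(
        {
            "feature": [r.feature_name for r in results],
            "group_CON": [r.group_summaries.get("group_0") for r in results],
            "group_CI": [r.group_summaries.get("group_1") for r in results],
            "test": [r.test_used for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
        }
    ).set_index("feature")
    if fdr:
        out["p_fdr"] = fdr_correct(out["p"].to_numpy())
    return out
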