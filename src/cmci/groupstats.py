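"""Two-group descriptive statistics with a normality-gated test choice.

For each balance descriptor (per condition) the two athlete groups are
compared by:

* a normality check per group — Kolmogorov-Smirnov against a normal with
  estimated mean/SD, using the Lilliefors correction (the plain KS test is
  anti-conservative when parameters are estimated);
* Welch's independent-samples t-test when both groups pass normality at
  alpha, otherwise the Mann-Whitney U test (exact null distribution for
  combined n <= 25 without ties, tie-corrected normal approximation
  otherwise);
* a per-descriptor AUC from a one-dimensional linear soft-margin SVM on
  the pooled values.  A 1-D linear scorer is monotone in the value, so
  this AUC coincides with the rank-based (Mann-Whitney) AUC up to
  orientation; the larger orientation is reported.

A table emitter renders the comparisons in the conventional
"mean(sd)" layout with a significance asterisk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.diagnostic import lilliefors

from .classify import _evaluate_scores
from .errors import EvaluationError, InsufficientDataError
from .features import FeatureTable

__all__ = [
    "GroupComparison",
    "ks_normality_p",
    "choose_test",
    "compare_groups",
    "descriptor_auc",
    "comparison_table",
]

DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Outcome of one descriptor's two-group comparison."""

    descriptor: str
    condition: str | None
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    normality_p_a: float
    normality_p_b: float
    test_used: str  # "t_test" | "mann_whitney"
    p_value: float
    significant: bool
    descriptor_auc: float | None
    alpha: float = DEFAULT_ALPHA


def ks_normality_p(x: np.ndarray) -> float:
    """Lilliefors-corrected KS p-value for normality with estimated params."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.std(x) == 0:
        # too small for the Lilliefors table / degenerate: call non-normal
        return 0.0
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(p)


def choose_test(p_a: float, p_b: float, alpha: float = DEFAULT_ALPHA) -> str:
    """Pure gate: t-test iff both groups pass normality at ``alpha``."""
    return "t_test" if (p_a > alpha and p_b > alpha) else "mann_whitney"


def _mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def compare_groups(a, b, alpha: float = DEFAULT_ALPHA, descriptor: str = "",
                   condition: str | None = None,
                   with_auc: bool = True, seed: int = 0) -> GroupComparison:
    """Normality-gated two-sample comparison of one descriptor.

    Group means/SDs (n-1 denominator) are reported alongside the gated
    test's p-value and, optionally, the 1-D SVM descriptor AUC.  Requires
    at least 3 observations per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"need >= 3 observations per group, got {a.size} and {b.size}"
        )
    p_a = ks_normality_p(a)
    p_b = ks_normality_p(b)
    test = choose_test(p_a, p_b, alpha)
    if test == "t_test":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = _mann_whitney_p(a, b)
    auc = descriptor_auc(a, b, seed=seed) if with_auc else None
    return GroupComparison(
        descriptor=descriptor, condition=condition,
        mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)),
        mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)),
        normality_p_a=p_a, normality_p_b=p_b,
        test_used=test, p_value=p, significant=bool(p < alpha),
        descriptor_auc=auc, alpha=alpha,
    )


def descriptor_auc(a, b, seed: int = 0) -> float:
    """AUC of a 1-D linear soft-margin SVM separating the two value lists.

    Group ``a`` is the positive class.  The linear decision function is
    monotone in the single feature, so the result equals the rank-based
    AUC or its complement; the larger of the two orientations is returned
    (0.5 when the fitted weight is zero or all values coincide).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need >= 2 observations per group")
    values = np.concatenate([a, b])
    if np.unique(values).size == 1:
        return 0.5
    labels = np.r_[np.ones(a.size, dtype=int), np.zeros(b.size, dtype=int)]
    model = SVC(kernel="linear", C=1.0, random_state=seed)
    model.fit(values[:, None], labels)
    scores = model.decision_function(values[:, None])
    if np.unique(scores).size == 1:  # zero-weight degenerate fit
        return 0.5
    try:
        auc, *_ = _evaluate_scores(labels, scores, positive_label=1)
    except EvaluationError:
        return 0.5
    return float(max(auc, 1.0 - auc))


def comparison_table(table: FeatureTable, alpha: float = DEFAULT_ALPHA,
                     group_a: str = "elite", group_b: str = "expert",
                     seed: int = 0) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-condition, per-descriptor group comparisons from a feature table.

    Returns a display frame in the "mean(sd)" layout (an asterisk flags a
    significant difference) plus the underlying comparison objects.
    """
    rows = []
    comparisons: list[GroupComparison] = []
    for condition in sorted(table.data["condition"].unique()):
        sub = table.data[table.data["condition"] == condition]
        for col in table.feature_columns:
            a = sub.loc[sub["group"] == group_a, col].dropna().to_numpy()
            b = sub.loc[sub["group"] == group_b, col].dropna().to_numpy()
            cmp_ = compare_groups(a, b, alpha=alpha, descriptor=col,
                                  condition=condition, seed=seed)
            comparisons.append(cmp_)
            star = "*" if cmp_.significant else ""
            rows.append({
                "condition": condition,
                "descriptor": col,
                group_a: f"{cmp_.mean_a:.2f}({cmp_.sd_a:.2f}){star}",
                group_b: f"{cmp_.mean_b:.2f}({cmp_.sd_b:.2f})",
                "test": cmp_.test_used,
                "p_value": cmp_.p_value,
                "auc": cmp_.descriptor_auc,
            })
    return pd.DataFrame(rows), comparisons
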