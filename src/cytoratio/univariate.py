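"""Per-feature group comparisons: normality-gated tests and effect summaries.

For each feature the two groups are compared with Student's t-test when both
groups pass the Shapiro–Wilk normality check, and with the two-sided
Mann–Whitney U test otherwise.  Alongside the p-value the comparison reports
group medians and IQR widths, the absolute median difference, the fold
change median(ref)/median(other) (> 1 ⇒ elevated in the reference group) and
the percent difference (fold change − 1) × 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import DEFAULT_PANEL, CytokinePanel


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison summary for one feature."""

    feature: str
    reference: str
    median_ref: float
    iqr_ref: float
    median_other: float
    iqr_other: float
    abs_diff: float
    pct_diff: float
    fold_change: float
    p_value: float
    test_used: str  # "t" or "mann_whitney"
    n_ref: int
    n_other: int


def _iqr_width(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25, 75])  # linear-interpolation quantiles
    return float(q3 - q1)


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney p: exact for combined n ≤ 20 without ties,
    otherwise the tie- and continuity-corrected normal approximation."""
    exact = (len(x) + len(y) <= 20) and (
        len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def compare_groups(x, y, feature: str = "", reference: str = "ref",
                   alpha_norm: float = 0.05) -> GroupComparison:
    """Compare reference-group values ``x`` against ``y``.

    Both groups need ≥ 3 non-missing values (Shapiro–Wilk minimum); smaller
    groups raise ``ValueError`` so callers can flag and skip the feature.
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(
            f"insufficient non-missing data for {feature or 'feature'}: "
            f"n_ref={len(x)}, n_other={len(y)}")

    def _normal(v: np.ndarray) -> bool:
        if np.ptp(v) == 0:
            return False  # degenerate: Shapiro undefined, treat as non-normal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(v).pvalue >= alpha_norm

    if _normal(x) and _normal(y):
        test_used = "t"
        p = float(stats.ttest_ind(x, y).pvalue)
    else:
        test_used = "mann_whitney"
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0  # all values identical: no evidence of any difference
        else:
            p = mann_whitney_p(x, y)

    med_x, med_y = float(np.median(x)), float(np.median(y))
    fold = med_x / med_y if med_y != 0 else np.inf
    return GroupComparison(
        feature=feature,
        reference=reference,
        median_ref=med_x,
        iqr_ref=_iqr_width(x),
        median_other=med_y,
        iqr_other=_iqr_width(y),
        abs_diff=abs(med_x - med_y),
        pct_diff=(fold - 1.0) * 100.0,
        fold_change=fold,
        p_value=p,
        test_used=test_used,
        n_ref=len(x),
        n_other=len(y),
    )


def compare_table(cohort: pd.DataFrame, label: str, reference: str,
                  features: list[str] | None = None,
                  panel: CytokinePanel = DEFAULT_PANEL,
                  alpha_norm: float = 0.05) -> pd.DataFrame:
    """Per-feature group-comparison table (one row per feature).

    ``label`` is the grouping column (e.g. ``bsi`` or ``gram``) and
    ``reference`` the clinically referenced level (BSI presence;
    Gram-negative).  Features with insufficient non-missing data in either
    group are flagged with ``skipped = True`` and NaN statistics rather than
    dropped, mirroring how missingness-laden lab markers are reported.
    """
    if features is None:
        features = list(panel.names)
    groups = cohort[label].dropna().unique()
    others = [g for g in groups if g != reference]
    if reference not in groups or len(others) != 1:
        raise ValueError(
            f"label {label!r} must have exactly two levels including "
            f"{reference!r}; found {sorted(map(str, groups))}")
    other = others[0]

    rows = []
    for feat in features:
        x = cohort.loc[cohort[label] == reference, feat]
        y = cohort.loc[cohort[label] == other, feat]
        try:
            c = compare_groups(x, y, feature=feat, reference=str(reference),
                               alpha_norm=alpha_norm)
        except ValueError:
            rows.append({"feature": feat, "skipped": True})
            continue
        row = {
            "feature": feat,
            "median_ref": c.median_ref, "iqr_ref": c.iqr_ref,
            "median_other": c.median_other, "iqr_other": c.iqr_other,
            "abs_diff": c.abs_diff, "pct_diff": c.pct_diff,
            "fold_change": c.fold_change, "p_value": c.p_value,
            "test_used": c.test_used, "skipped": False,
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def trim_outliers_for_display(values):
    """Values within [Q1 − 1.5·IQR, Q3 + 1.5·IQR] — for boxplot display only;
    statistics are always computed on untrimmed data."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values to define display fences")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return values[(values >= lo) & (values <= hi)]
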