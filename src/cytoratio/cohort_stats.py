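"""Demographic/clinical group-comparison tests with SPSS-style conventions.

Categorical variables use the two-sided Fisher exact test (probability-mass
summation) when any expected cell count falls below 5, and the
Yates-corrected chi-square otherwise; continuous variables use the
Mann–Whitney U test.  The screening significance level for cohort
comparability is α = 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import mann_whitney_p

#: Two-sided screening threshold for demographic comparability.
ALPHA_SCREEN = 0.01


@dataclass(frozen=True)
class ContingencyTable2x2:
    """A 2×2 count table with optional axis labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) < 1:
            raise ValueError("grand total must be >= 1")

    @classmethod
    def from_array(cls, table, **kwargs) -> "ContingencyTable2x2":
        (a, b), (c, d) = np.asarray(table)
        return cls(a=int(a), b=int(b), c=int(c), d=int(d), **kwargs)

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def degenerate(self) -> bool:
        t = self.to_array()
        return bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())

    def min_expected(self) -> float:
        t = self.to_array().astype(float)
        exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        return float(exp.min())


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all same-margin tables no more probable than the observed one."""
    if table.degenerate:
        warnings.warn("degenerate margins: Fisher p fixed at 1.0",
                      stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table.to_array(),
                                    alternative="two-sided").pvalue)


def chi_square_2x2(table: ContingencyTable2x2,
                   continuity: bool = True) -> float:
    """Pearson chi-square p for a 2×2 table, Yates-corrected by default
    (|O−E| − 0.5 clipped at zero, so the statistic never goes negative)."""
    if table.degenerate:
        raise ValueError("chi-square undefined for a zero row/column margin")
    res = stats.chi2_contingency(table.to_array(), correction=continuity)
    return float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U and p (exact for small tie-free samples,
    tie/continuity-corrected normal approximation otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    if np.ptp(np.concatenate([x, y])) == 0:
        return u, 1.0
    return u, mann_whitney_p(x, y)


def demographics_table(cohort: pd.DataFrame, label: str = "bsi",
                       reference: str = "yes") -> pd.DataFrame:
    """Cohort-comparability table over demographics and clinical variables.

    Continuous variables (age, BMI) are summarised as median (IQR width) and
    tested with Mann–Whitney; binary variables as counts, tested with Fisher
    exact when any expected count < 5 and Yates chi-square otherwise.
    """
    groups = cohort[label].dropna().unique()
    other = [g for g in groups if g != reference]
    if reference not in groups or len(other) != 1:
        raise ValueError(f"label {label!r} must have two levels "
                         f"including {reference!r}")
    other = other[0]
    ref_rows = cohort[label] == reference
    oth_rows = cohort[label] == other

    records = []
    for var in ("age", "bmi"):
        if var not in cohort.columns:
            continue
        x = cohort.loc[ref_rows, var].dropna().to_numpy()
        y = cohort.loc[oth_rows, var].dropna().to_numpy()
        _, p = mann_whitney(x, y)
        records.append({
            "variable": var,
            "summary_ref": f"{np.median(x):g} "
                           f"({np.percentile(x, 75) - np.percentile(x, 25):g})",
            "summary_other": f"{np.median(y):g} "
                             f"({np.percentile(y, 75) - np.percentile(y, 25):g})",
            "test": "mann_whitney", "p_value": p,
            "significant": p < ALPHA_SCREEN,
        })
    for var, positive in (("gender", "female"), ("ecmo", "yes"),
                          ("imv", "yes"), ("comorbidities", "yes")):
        if var not in cohort.columns:
            continue
        a = int((cohort.loc[ref_rows, var] == positive).sum())
        b = int((cohort.loc[ref_rows, var] != positive).sum())
        c = int((cohort.loc[oth_rows, var] == positive).sum())
        d = int((cohort.loc[oth_rows, var] != positive).sum())
        table = ContingencyTable2x2(a, b, c, d)
        if table.degenerate or table.min_expected() < 5:
            test, p = "fisher", fisher_exact(table)
        else:
            test, p = "chi_square", chi_square_2x2(table)
        records.append({
            "variable": var,
            "summary_ref": f"{positive}: {a}/{a + b}",
            "summary_other": f"{positive}: {c}/{c + d}",
            "test": test, "p_value": p,
            "significant": p < ALPHA_SCREEN,
        })
    return pd.DataFrame(records).set_index("variable")
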