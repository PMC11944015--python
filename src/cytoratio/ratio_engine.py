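"""Enumeration and evaluation of constrained cytokine sum-ratio features.

A ratio feature is (sum of 1–3 distinct pro-inflammatory cytokines) /
(sum of 1–3 distinct anti-inflammatory cytokines).  For the canonical
14-pro / 6-anti panel this yields (C(14,1)+C(14,2)+C(14,3)) ×
(C(6,1)+C(6,2)+C(6,3)) = 469 × 41 = 19,229 ratios, which together with the
21 raw concentrations form a 19,250-column feature matrix.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, CytokinePanel


@dataclass(frozen=True)
class RatioSpec:
    """One sum-ratio feature: numerator and denominator member sets.

    Members are stored as tuples in canonical (panel) order; construction
    via :func:`enumerate_ratios` guarantees this.  Sets, not multisets —
    no cytokine appears twice on one side.
    """

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        for side, members in (("numerator", self.numerator),
                              ("denominator", self.denominator)):
            if not 1 <= len(members):
                raise ValueError(f"{side} must have at least one member")
            if len(set(members)) != len(members):
                raise ValueError(f"{side} members must be distinct: {members}")


def feature_name(spec: RatioSpec) -> str:
    """Canonical display name, e.g. ``(GM-CSF + IL-1β)/(IL-4)``."""
    num = " + ".join(spec.numerator)
    den = " + ".join(spec.denominator)
    return f"({num})/({den})"


_NAME_RE = re.compile(r"^\((?P<num>[^()]+)\)/\((?P<den>[^()]+)\)$")


def parse_feature_name(name: str,
                       panel: CytokinePanel = DEFAULT_PANEL) -> RatioSpec:
    """Inverse of :func:`feature_name` (members re-sorted to panel order)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a ratio feature name: {name!r}")
    num = panel.sort_members(s.strip() for s in m.group("num").split(" + "))
    den = panel.sort_members(s.strip() for s in m.group("den").split(" + "))
    unknown = (set(num) | set(den)) - set(panel.names)
    if unknown:
        raise ValueError(f"unknown cytokines in {name!r}: {sorted(unknown)}")
    return RatioSpec(numerator=num, denominator=den)


def _subsets(members: tuple[str, ...], max_terms: int,
             panel: CytokinePanel) -> list[tuple[str, ...]]:
    """All 1..max_terms-member subsets, sorted lexicographically by their
    panel-index tuples (so enumeration order is reproducible)."""
    ordered = panel.sort_members(members)
    pos = {c: i for i, c in enumerate(ordered)}
    subs = []
    for k in range(1, max_terms + 1):
        subs.extend(itertools.combinations(ordered, k))
    subs.sort(key=lambda s: tuple(pos[c] for c in s))
    return subs


def enumerate_ratios(panel: CytokinePanel = DEFAULT_PANEL,
                     max_terms: int = 3) -> list[RatioSpec]:
    """Enumerate every constrained sum-ratio in canonical order.

    Ordering is lexicographic by sorted member indices, numerator major.
    The count obeys |ratios| = Σ_{k=1..m} C(|pro|,k) × Σ_{k=1..m} C(|anti|,k).
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    nums = _subsets(panel.pro, max_terms, panel)
    dens = _subsets(panel.anti, max_terms, panel)
    return [RatioSpec(numerator=n, denominator=d)
            for n in nums for d in dens]


def evaluate_ratios(cohort: pd.DataFrame, specs: list[RatioSpec],
                    panel: CytokinePanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Build the feature matrix: 21 raw concentrations then the ratios.

    Each ratio value is (Σ numerator concentrations)/(Σ denominator
    concentrations) per sample.  Raises if any denominator sum is not
    strictly positive, naming the offending sample and feature.
    """
    missing = {c for s in specs for c in s.numerator + s.denominator} \
        - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks cytokines: {sorted(missing)}")

    conc = cohort[list(panel.names)].to_numpy(dtype=float)
    col = {c: i for i, c in enumerate(panel.names)}

    # Sum each distinct side subset once; ratios reuse the cached sums.
    num_keys = list(dict.fromkeys(s.numerator for s in specs))
    den_keys = list(dict.fromkeys(s.denominator for s in specs))
    num_sums = {k: conc[:, [col[c] for c in k]].sum(axis=1) for k in num_keys}
    den_sums = {k: conc[:, [col[c] for c in k]].sum(axis=1) for k in den_keys}

    for k, v in den_sums.items():
        bad = np.nonzero(v <= 0)[0]
        if bad.size:
            sample = cohort.iloc[bad[0]].get("sample_id", bad[0])
            raise ValueError(
                f"non-positive denominator sum ({' + '.join(k)}) for "
                f"sample {sample}")

    values = np.empty((len(cohort), len(specs)), dtype=float)
    for j, s in enumerate(specs):
        values[:, j] = num_sums[s.numerator] / den_sums[s.denominator]

    ratios = pd.DataFrame(values, columns=[feature_name(s) for s in specs],
                          index=cohort.index)
    raw = cohort[list(panel.names)].astype(float)
    return pd.concat([raw, ratios], axis=1)
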