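"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately avoid the package's own
entropy/SU code paths: they work from ``collections.Counter`` and
``math.log2`` so that agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from cytoratio import (DEFAULT_PANEL, CytokinePanel, GroupEffectConfig,
                       generate_cohort)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def oracle_entropy(seq) -> float:
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in Counter(seq).values())


def oracle_su(x, y) -> float:
    hx, hy = oracle_entropy(list(x)), oracle_entropy(list(y))
    if hx + hy == 0:
        return 0.0
    hxy = oracle_entropy(list(zip(x, y)))
    return 2.0 * (hx + hy - hxy) / (hx + hy)


def oracle_fcbf(columns: dict[str, list], labels: list):
    """Predominant-feature selection on already-discrete columns.

    Features are ranked by SU with the class (ties by insertion order); a
    feature is kept unless some already-kept feature predicts it at least
    as well as it predicts the class.
    Returns (kept feature names in rank order, su per feature).
    """
    su = {f: oracle_su(col, labels) for f, col in columns.items()}
    names = list(columns)
    order = sorted((f for f in names if su[f] > 0),
                   key=lambda f: (-su[f], names.index(f)))
    kept: list[str] = []
    for f in order:
        if all(oracle_su(columns[g], columns[f]) < su[f] for g in kept):
            kept.append(f)
    return kept, su


def oracle_subset_count(n_pro: int, n_anti: int, max_terms: int) -> int:
    """Ratio count by explicit enumeration over index subsets."""
    from itertools import combinations

    nums = [c for k in range(1, max_terms + 1)
            for c in combinations(range(n_pro), k)]
    dens = [c for k in range(1, max_terms + 1)
            for c in combinations(range(n_anti), k)]
    return len({(n, d) for n in nums for d in dens})


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_panel() -> CytokinePanel:
    """A 5-cytokine panel (2 pro, 2 anti, 1 unassigned) for cheap tests."""
    return CytokinePanel(
        names=("P1", "P2", "A1", "A2", "U1"),
        pro=("P1", "P2"),
        anti=("A1", "A2"),
    )


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default-parameterised synthetic cohort (23/7/15, seed 7)."""
    return generate_cohort(GroupEffectConfig(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250921)
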