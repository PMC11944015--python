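"""Naive-Bayes nomogram on the natural-log odds-ratio scale.

Each feature bin contributes points = ln[P(bin | target)/P(bin | non-target)]
from the smoothed naive-Bayes conditionals.  A sample's predicted probability
of the target class is the logistic transform of the prior log odds plus the
sum of its bin points — an exact algebraic identity with the naive-Bayes
posterior, which makes the nomogram a lossless reading of the model.
Features are displayed in FCBF rank order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify_eval import NBModel
from .fcbf import SUScore, discretize


@dataclass(frozen=True)
class NomogramBin:
    """One interval of one feature and its log-odds-ratio points."""

    low: float   # -inf for the leftmost bin
    high: float  # +inf for the rightmost bin
    points: float


@dataclass(frozen=True)
class NomogramModel:
    """Additive scoring chart equivalent to a binary naive-Bayes model."""

    target: object
    prior_log_odds: float
    features: tuple[str, ...]           # in FCBF rank order
    bins: dict[str, tuple[NomogramBin, ...]]

    def sample_points(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-feature points each sample collects (columns in rank order)."""
        out = {}
        for f in self.features:
            edges = [b.high for b in self.bins[f][:-1]]
            codes = discretize(X[f].to_numpy(dtype=float), np.array(edges))
            out[f] = np.array([self.bins[f][c].points for c in codes])
        return pd.DataFrame(out, index=X.index)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the target class via the points identity."""
        total = self.prior_log_odds + self.sample_points(X).sum(axis=1)
        return 1.0 / (1.0 + np.exp(-total.to_numpy()))

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the chart: feature, bin_low, bin_high, points."""
        rows = [
            {"feature": f, "bin_low": b.low, "bin_high": b.high,
             "points": b.points}
            for f in self.features for b in self.bins[f]
        ]
        return pd.DataFrame(rows)


def build_nomogram(model: NBModel, ranks: list[SUScore],
                   target=None) -> NomogramModel:
    """Turn a fitted binary naive-Bayes model into a nomogram.

    Parameters
    ----------
    model
        Binary :class:`~cytoratio.classify_eval.NBModel` (its smoothed
        conditionals guarantee finite points).
    ranks
        FCBF scores; every model feature must carry a rank, and features are
        displayed in ascending rank (most informative first).
    target
        The class whose log odds the points accumulate; defaults to the
        second of the model's (sorted) classes.
    """
    if model.classes.size != 2:
        raise ValueError("nomograms require a binary model")
    if target is None:
        target = model.classes[1]
    if target not in list(model.classes):
        raise ValueError(f"target {target!r} not among model classes")
    t = list(model.classes).index(target)

    rank_by_feature = {s.feature: s.rank for s in ranks if s.rank is not None}
    unranked = [f for f in model.features if f not in rank_by_feature]
    if unranked:
        raise ValueError(f"model features without an FCBF rank: {unranked}")
    ordered = tuple(sorted(model.features, key=rank_by_feature.__getitem__))

    bins: dict[str, tuple[NomogramBin, ...]] = {}
    for f in ordered:
        cuts = model.cuts[f]
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        cond = model.cond[f]
        points = np.log(cond[:, t]) - np.log(cond[:, 1 - t])
        bins[f] = tuple(
            NomogramBin(low=float(edges[i]), high=float(edges[i + 1]),
                        points=float(points[i]))
            for i in range(len(cuts) + 1)
        )
    return NomogramModel(target=target,
                         prior_log_odds=model.prior_log_odds(target),
                         features=ordered, bins=bins)


def predict_from_points(prior_log_odds: float, points) -> float:
    """Logistic of (prior log odds + Σ points): the predicted probability.

    ``points`` is the collection of bin points a sample accrues (a scalar is
    treated as a single contribution).
    """
    total = prior_log_odds + float(np.sum(points))
    if not np.isfinite(total):
        return 0.0 if total < 0 else 1.0
    return float(1.0 / (1.0 + np.exp(-total)))
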