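"""Entropy-based feature scoring and selection (FCBF).

The selector works in three stages:

1. every continuous feature is discretized against the class labels by
   recursive entropy minimisation with the minimum-description-length (MDL)
   acceptance rule (Fayyad–Irani) — features for which no split is accepted
   are uninformative and receive an empty cut list;
2. each discretized feature is scored by symmetrical uncertainty with the
   class, SU(X, C) = 2·I(X;C)/(H(X)+H(C)) ∈ [0, 1]; features scoring 0 are
   dropped;
3. the fast correlation-based filter walks the remaining features in
   descending SU order and removes any feature that is more strongly
   associated with an already-kept feature than with the class
   (SU(Fi, Fj) ≥ SU(Fj, C)) — the predominant-feature rule that eliminates
   redundant ratios sharing cytokines.

All entropies are in bits.  Ties in SU are broken by canonical feature
order so selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "entropy",
    "mdl_discretize",
    "discretize",
    "symmetrical_uncertainty",
    "SUScore",
    "fcbf_select",
]


# ---------------------------------------------------------------------------
# Entropy primitives
# ---------------------------------------------------------------------------


def entropy(labels) -> float:
    """Shannon entropy (bits) of a discrete sequence; 0 for a constant."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty sequence is undefined")
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts.astype(float))


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _row_entropy(counts: np.ndarray) -> np.ndarray:
    """Entropy of each row of a (rows × classes) count matrix, in bits."""
    n = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, counts / np.maximum(n, 1), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=1)


def _encode(labels) -> tuple[np.ndarray, int]:
    codes = np.unique(np.asarray(labels), return_inverse=True)[1]
    return codes.astype(np.int64), int(codes.max()) + 1 if codes.size else 0


# ---------------------------------------------------------------------------
# MDL (Fayyad–Irani) discretization
# ---------------------------------------------------------------------------


def _best_split(values: np.ndarray, codes: np.ndarray, n_classes: int):
    """Best-gain boundary and its MDL verdict for one node.

    Returns ``(cut, accepted, left_mask)`` or ``None`` when no candidate
    boundary exists (constant values or a single sample).
    """
    n = values.size
    if n < 2:
        return None
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = codes[order]
    valid = v[1:] > v[:-1]
    if not valid.any():
        return None

    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    left = np.cumsum(onehot, axis=0)[:-1]          # counts up to boundary i
    total = onehot.sum(axis=0)
    right = total - left
    n_left = left.sum(axis=1)
    n_right = n - n_left

    h_all = _entropy_from_counts(total)
    h_left = _row_entropy(left)
    h_right = _row_entropy(right)
    gain = h_all - (n_left * h_left + n_right * h_right) / n
    gain = np.where(valid, gain, -np.inf)

    i = int(np.argmax(gain))                       # first max ⇒ lowest cut
    if not np.isfinite(gain[i]):
        return None

    k = int((total > 0).sum())
    k1 = int((left[i] > 0).sum())
    k2 = int((right[i] > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (
        k * h_all - k1 * h_left[i] - k2 * h_right[i])
    accepted = gain[i] > (np.log2(n - 1.0) + delta) / n

    cut = 0.5 * (v[i] + v[i + 1])
    return cut, bool(accepted), values <= cut


def mdl_discretize(values, labels) -> np.ndarray:
    """Class-driven cut points by recursive MDL-gated entropy splitting.

    Returns a (possibly empty) strictly increasing array of cut points.
    An empty result means no binary split of the feature carries enough
    class information to justify its description cost — the feature is
    uninformative under the MDL criterion.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    if values.size < 2:
        return np.empty(0)
    codes, n_classes = _encode(labels)

    cuts: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        split = _best_split(values[mask], codes[mask], n_classes)
        if split is None:
            return
        cut, accepted, left_local = split
        if not accepted:
            return
        cuts.append(cut)
        sub = np.nonzero(mask)[0]
        left_mask = np.zeros_like(mask)
        left_mask[sub[left_local]] = True
        recurse(left_mask)
        recurse(mask & ~left_mask)

    recurse(np.ones(values.size, dtype=bool))
    return np.sort(np.asarray(cuts, dtype=float))


def discretize(values, cuts) -> np.ndarray:
    """Map values to bin codes 0..len(cuts) given sorted cut points."""
    return np.searchsorted(np.asarray(cuts, dtype=float),
                           np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# Symmetrical uncertainty
# ---------------------------------------------------------------------------


def symmetrical_uncertainty(x, y) -> float:
    """SU(X, Y) = 2·I(X;Y)/(H(X)+H(Y)) on discrete sequences, in [0, 1].

    Returns 0 when H(X)+H(Y) = 0 (both constant).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    cx, nx = _encode(x)
    cy, ny = _encode(y)
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).astype(float)
    hx = _entropy_from_counts(np.bincount(cx).astype(float))
    hy = _entropy_from_counts(np.bincount(cy).astype(float))
    hxy = _entropy_from_counts(joint)
    if hx + hy == 0.0:
        return 0.0
    mi = hx + hy - hxy
    return float(min(1.0, max(0.0, 2.0 * mi / (hx + hy))))


def _su_codes(cx: np.ndarray, nx: int, cy: np.ndarray, ny: int) -> float:
    """SU on pre-encoded codes (hot path of the redundancy walk)."""
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).astype(float)
    hx = _entropy_from_counts(np.bincount(cx, minlength=nx).astype(float))
    hy = _entropy_from_counts(np.bincount(cy, minlength=ny).astype(float))
    if hx + hy == 0.0:
        return 0.0
    mi = hx + hy - _entropy_from_counts(joint)
    return float(min(1.0, max(0.0, 2.0 * mi / (hx + hy))))


# ---------------------------------------------------------------------------
# Vectorised first-split screen
# ---------------------------------------------------------------------------


def _mdl_screen(X: np.ndarray, codes: np.ndarray, n_classes: int,
                chunk: int = 2048) -> np.ndarray:
    """Whether the MDL criterion accepts the best first split, per column.

    Equivalent to ``len(mdl_discretize(X[:, j], labels)) > 0`` for every j,
    evaluated in vectorised column chunks; features rejected here need no
    recursive discretization at all.
    """
    n, n_feat = X.shape
    if n < 2:
        return np.zeros(n_feat, dtype=bool)
    if n_feat > chunk:
        return np.concatenate([
            _mdl_screen(X[:, lo:lo + chunk], codes, n_classes, chunk)
            for lo in range(0, n_feat, chunk)
        ])
    order = np.argsort(X, axis=0, kind="stable")
    v = np.take_along_axis(X, order, axis=0)
    y = codes[order]                                   # (n, F)
    valid = v[1:] > v[:-1]

    left = np.stack([np.cumsum(y == c, axis=0)[:-1] for c in range(n_classes)],
                    axis=2).astype(float)              # (n-1, F, C)
    total = left[-1] + np.stack(
        [(y[-1:] == c) for c in range(n_classes)], axis=2)[0]
    right = total[None, :, :] - left
    n_left = left.sum(axis=2)
    n_right = n - n_left

    h_all = _row_entropy(total)                        # (F,)
    h_left = _row_entropy(left.reshape(-1, n_classes)).reshape(n - 1, n_feat)
    h_right = _row_entropy(right.reshape(-1, n_classes)).reshape(n - 1, n_feat)
    gain = h_all[None, :] - (n_left * h_left + n_right * h_right) / n
    gain = np.where(valid, gain, -np.inf)

    best = np.argmax(gain, axis=0)                     # (F,)
    cols = np.arange(n_feat)
    best_gain = gain[best, cols]

    k = (total > 0).sum(axis=1)
    k1 = (left[best, cols, :] > 0).sum(axis=1)
    k2 = (right[best, cols, :] > 0).sum(axis=1)
    delta = np.log2(3.0**k - 2.0) - (
        k * h_all - k1 * h_left[best, cols] - k2 * h_right[best, cols])
    threshold = (np.log2(n - 1.0) + delta) / n
    return np.isfinite(best_gain) & (best_gain > threshold)


# ---------------------------------------------------------------------------
# FCBF selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SUScore:
    """Per-feature symmetrical uncertainty with the class and FCBF status."""

    feature: str
    su: float
    selected: bool
    rank: int | None  # consecutive from 1 among selected, by descending SU


def fcbf_select(features: pd.DataFrame, labels,
                redundancy: bool = True) -> list[SUScore]:
    """Score and select features by the fast correlation-based filter.

    Parameters
    ----------
    features
        Samples × features matrix of continuous values (raw cytokines and
        ratios); column order is the canonical tie-break order.
    labels
        Class labels, one per sample; at least two classes required.
    redundancy
        When False, skip the predominant-feature elimination and select
        every feature with SU > 0 (plain SU thresholding).

    Returns
    -------
    list of SUScore
        One entry per input feature, ordered by descending SU (ties by
        column order); ``selected`` features carry consecutive ranks.
    """
    labels = np.asarray(labels)
    if len(features) != labels.size:
        raise ValueError("features and labels must have equal length")
    codes, n_classes = _encode(labels)
    if n_classes < 2:
        raise ValueError("fcbf_select requires at least two classes")

    X = features.to_numpy(dtype=float)
    n, n_feat = X.shape
    accepted = _mdl_screen(X, codes, n_classes)

    su = np.zeros(n_feat)
    feat_codes: dict[int, tuple[np.ndarray, int]] = {}
    for j in np.nonzero(accepted)[0]:
        cuts = mdl_discretize(X[:, j], labels)
        if cuts.size == 0:
            continue
        xj = discretize(X[:, j], cuts)
        feat_codes[j] = (xj, int(xj.max()) + 1)
        su[j] = _su_codes(xj, feat_codes[j][1], codes, n_classes)

    order = sorted(np.nonzero(su > 0)[0], key=lambda j: (-su[j], j))
    kept: list[int] = []
    for j in order:
        cj, bj = feat_codes[j]
        if redundancy:
            dominated = any(
                _su_codes(feat_codes[i][0], feat_codes[i][1], cj, bj) >= su[j]
                for i in kept)
            if dominated:
                continue
        kept.append(j)

    kept_rank = {j: r + 1 for r, j in enumerate(kept)}
    all_order = sorted(range(n_feat), key=lambda j: (-su[j], j))
    return [
        SUScore(feature=features.columns[j], su=float(su[j]),
                selected=j in kept_rank, rank=kept_rank.get(j))
        for j in all_order
    ]


def scores_to_frame(scores: list[SUScore]) -> pd.DataFrame:
    """Tabulate SU scores (feature, su, selected, rank)."""
    return pd.DataFrame(
        [(s.feature, s.su, s.selected, s.rank) for s in scores],
        columns=["feature", "su", "selected", "rank"],
    )
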