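"""Information-gain feature ranking and top-k selection.

Continuous descriptor values are first binarized by a per-feature median
split (fit on training rows, thresholds frozen for reuse), then each
binary feature is scored by its information gain in bits,
IG(X) = H(C) - [P(x) H(C|x) + P(x_bar) H(C|x_bar)].

The number of retained top-ranked features is chosen by a coarse grid
scan followed by an integer ternary search that assumes the score curve
is unimodal in k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class IGRanking:
    """Per-feature information-gain scores with a descending order."""

    features: list[str]
    scores: np.ndarray  # aligned with `features` (original column order)
    order: np.ndarray  # permutation of column indices, best first

    def top(self, k: int) -> list[str]:
        if k > len(self.features):
            raise ValueError(f"k={k} exceeds {len(self.features)} features")
        return [self.features[i] for i in self.order[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [self.features[i] for i in self.order],
                "IG": self.scores[self.order],
                "rank": np.arange(1, len(self.features) + 1),
            }
        )


def binarize_features(
    matrix: pd.DataFrame, thresholds: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-split binarization: present (1) iff value > feature median.

    Thresholds are computed on the given rows unless supplied (reuse on
    unseen data); constant features map to all-absent.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty feature matrix")
    if thresholds is None:
        thresholds = matrix.median(axis=0)
    binary = (matrix > thresholds).astype(np.int8)
    return binary, thresholds


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(feature: np.ndarray, labels: np.ndarray) -> float:
    """IG of one binary feature, in bits (base-2)."""
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    h_c = _entropy(np.array([(labels == c).sum() for c in classes]))
    ig = h_c
    n = len(labels)
    for value in (0, 1):
        mask = feature == value
        if mask.sum() == 0:
            continue
        h_cond = _entropy(np.array([(labels[mask] == c).sum() for c in classes]))
        ig -= mask.sum() / n * h_cond
    return max(ig, 0.0)


def rank_features(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    thresholds: pd.Series | None = None,
) -> IGRanking:
    """Rank all columns by information gain, descending.

    Ties are broken by original column index, so the ranking is
    deterministic and invariant to row order.
    """
    labels = np.asarray(labels)
    if matrix.shape[0] != len(labels):
        raise ValueError("matrix rows must match labels")
    binary, _ = binarize_features(matrix, thresholds)
    X = binary.to_numpy()
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    n = len(labels)
    h_c = _entropy(np.array([(labels == c).sum() for c in classes]))
    # vectorized two-by-two contingency per column
    scores = np.full(X.shape[1], h_c)
    for value in (0, 1):
        mask_cols = X == value  # n x p
        n_v = mask_cols.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_cond = np.zeros(X.shape[1])
            p_any = n_v > 0
            cls_counts = np.stack(
                [((labels[:, None] == c) & mask_cols).sum(axis=0) for c in classes]
            ).astype(float)
            pc = np.where(n_v > 0, cls_counts / np.maximum(n_v, 1), 0.0)
            logs = np.where(pc > 0, np.log2(np.maximum(pc, 1e-300)), 0.0)
            h_cond = -(pc * logs).sum(axis=0)
        scores -= np.where(p_any, n_v / n, 0.0) * h_cond
    scores = np.maximum(scores, 0.0)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return IGRanking(list(matrix.columns), scores, order)


@dataclass
class ScanResult:
    grid: list[int]
    scores: list[float]

    @property
    def best_k(self) -> int:
        best = int(np.argmax(self.scores))  # argmax: first (smallest k) on ties
        return self.grid[best]

    @property
    def best_score(self) -> float:
        return max(self.scores)


DEFAULT_SCAN_GRID: tuple[int, ...] = tuple(range(50, 601, 50))


def scan_topk(
    ranking: IGRanking,
    evaluator: Callable[[Sequence[str]], float],
    grid: Sequence[int] = DEFAULT_SCAN_GRID,
) -> ScanResult:
    """Evaluate top-k feature sets over a coarse grid of k values.

    ``evaluator`` maps a feature-name list to a score (conventionally a
    cross-validated AUROC); it is called once per grid point. Ties go to
    the smallest k.
    """
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise ValueError("empty grid")
    if grid[-1] > len(ranking.features):
        raise ValueError(
            f"grid point {grid[-1]} exceeds {len(ranking.features)} features"
        )
    scores = [float(evaluator(ranking.top(k))) for k in grid]
    return ScanResult(list(grid), scores)


def ternary_search_topk(
    evaluator: Callable[[int], float],
    lo: int,
    hi: int,
) -> tuple[int, float]:
    """Integer ternary search for the k maximizing a unimodal evaluator.

    Probes m1 = lo + (hi-lo)//3 and m2 = hi - (hi-lo)//3, discards the
    third of the bracket behind the worse probe, and finishes with an
    exhaustive check of the remaining <= 3 points. Evaluator calls are
    cached; ties break toward fewer features. Returns (k, score).
    """
    if lo >= hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    cache: dict[int, float] = {}

    def f(k: int) -> float:
        if k not in cache:
            cache[k] = float(evaluator(k))
        return cache[k]

    while hi - lo > 2:
        third = (hi - lo) // 3
        m1, m2 = lo + third, hi - third
        if m1 == m2:
            m2 += 1
        if f(m1) >= f(m2):
            hi = m2 - 1
        else:
            lo = m1 + 1
    best_k, best_s = lo, f(lo)
    for k in range(lo + 1, hi + 1):
        if f(k) > best_s:
            best_k, best_s = k, f(k)
    return best_k, best_s


def select_topk(
    ranking: IGRanking,
    evaluator: Callable[[Sequence[str]], float],
    grid: Sequence[int] = DEFAULT_SCAN_GRID,
    refine: bool = True,
    bracket_halfwidth: int = 50,
) -> tuple[int, ScanResult]:
    """Coarse scan, then optional ternary refinement around the scan best.

    The refinement bracket is [best - halfwidth, best + halfwidth]
    clipped to [1, n_features].
    """
    scan = scan_topk(ranking, evaluator, grid)
    k = scan.best_k
    if refine:
        lo = max(1, k - bracket_halfwidth)
        hi = min(len(ranking.features), k + bracket_halfwidth)
        if lo < hi:
            k, _ = ternary_search_topk(
                lambda kk: evaluator(ranking.top(kk)), lo, hi
            )
    return k, scan
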