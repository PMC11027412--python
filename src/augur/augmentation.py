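"""Class rebalancing: Borderline-SMOTE oversampling + random under-sampling.

An :class:`AugmentationPlan` fixes the target counts for a chosen
augmentation ratio r: the positive class grows to
round_half_up(n_pos * (1 + r)) via synthetic borderline samples and the
negative class is uniformly under-sampled to the same count, yielding an
exactly 1:1 training set. With 215 positives the canonical ratios
0/0.25/0.5/0.75/1.0 give targets 215/269/323/376/430.

The oversampler is the borderline-1 variant: only minority points whose
m-neighborhoods are majority-dominated (but not fully majority, which
marks noise) seed interpolation, each synthetic point being a convex
combination p + u (q - p) of a danger seed p and one of its k nearest
minority neighbors q.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

#: Provenance flags attached to augmented training rows.
ORIGINAL = "original"
SYNTHETIC = "synthetic"
KEPT = "undersampled-kept"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class AugmentationPlan:
    """Target counts for one augmentation ratio; pure bookkeeping."""

    ratio: float
    n_pos_original: int
    n_pos_target: int
    n_neg_target: int
    seed: int

    @property
    def n_synthetic(self) -> int:
        return self.n_pos_target - self.n_pos_original

    def scaled_to(self, n_pos: int, seed: int | None = None) -> "AugmentationPlan":
        """The same ratio applied to a different positive count (e.g. one
        cross-validation fold)."""
        return plan_augmentation(
            n_pos, self.ratio, self.seed if seed is None else seed
        )


def plan_augmentation(
    n_pos: int,
    ratio: float,
    seed: int = 0,
    n_pos_target: int | None = None,
) -> AugmentationPlan:
    """Build an :class:`AugmentationPlan`.

    ``n_pos_target`` overrides the round-half-up arithmetic for users
    replicating externally stated counts.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    if ratio < 0:
        raise ValueError(f"augmentation ratio must be >= 0, got {ratio}")
    if n_pos_target is None:
        n_pos_target = _round_half_up(n_pos * (1.0 + ratio))
    if n_pos_target < n_pos:
        raise ValueError("n_pos_target cannot shrink the positive class")
    return AugmentationPlan(
        ratio=float(ratio),
        n_pos_original=n_pos,
        n_pos_target=n_pos_target,
        n_neg_target=n_pos_target,
        seed=seed,
    )


def _borderline_roles(
    pos: np.ndarray, neg: np.ndarray, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Classify each positive as DANGER / NOISE / safe.

    Returns (danger_mask, noise_mask). A positive is NOISE when all m
    nearest neighbors in the combined set are majority; DANGER when the
    majority share is in [m/2, m).
    """
    combined = np.vstack([pos, neg])
    is_neg = np.concatenate(
        [np.zeros(len(pos), dtype=bool), np.ones(len(neg), dtype=bool)]
    )
    nn = NearestNeighbors(n_neighbors=m + 1).fit(combined)
    _, idx = nn.kneighbors(pos)  # first neighbor is the point itself
    maj = is_neg[idx[:, 1:]].sum(axis=1)
    noise = maj == m
    danger = (maj >= m / 2) & (maj < m)
    return danger, noise


def borderline_smote(
    pos: np.ndarray,
    neg: np.ndarray,
    n_new: int,
    m: int = 5,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Generate ``n_new`` synthetic minority rows (borderline-1 variant).

    Each synthetic row is p + u (q - p) with u ~ U[0, 1], p a DANGER
    seed and q one of p's k nearest minority neighbors; deterministic
    for a fixed seed. If no DANGER point exists, all non-NOISE positives
    seed instead (logged warning).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_new == 0:
        return np.empty((0, pos.shape[1]))
    if len(pos) < 2:
        raise ValueError("need at least 2 positive rows to interpolate")
    if len(pos) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} positive rows, got {len(pos)}")
    danger, noise = _borderline_roles(pos, neg, m)
    seeds = np.flatnonzero(danger)
    if len(seeds) == 0:
        seeds = np.flatnonzero(~noise)
        logger.warning(
            "no DANGER positives found; falling back to all %d non-NOISE "
            "positives as interpolation seeds",
            len(seeds),
        )
        if len(seeds) == 0:
            raise ValueError("every positive is NOISE; cannot oversample")
    nn_pos = NearestNeighbors(n_neighbors=min(k + 1, len(pos))).fit(pos)
    _, pos_idx = nn_pos.kneighbors(pos[seeds])
    rng = np.random.default_rng(seed)
    out = np.empty((n_new, pos.shape[1]))
    for i in range(n_new):
        s = rng.integers(len(seeds))
        p = pos[seeds[s]]
        neighbors = pos_idx[s, 1:]  # drop self
        q = pos[neighbors[rng.integers(len(neighbors))]]
        u = rng.random()
        out[i] = p + u * (q - p)
    return out


def random_undersample(
    neg: np.ndarray | pd.DataFrame, n_target: int, seed: int = 0
) -> np.ndarray:
    """Indices of a uniform without-replacement subsample of the majority.

    Returns row indices (sorted, preserving original order); the
    identity permutation when ``n_target`` equals the available count.
    """
    n = len(neg)
    if n_target > n:
        raise ValueError(f"cannot keep {n_target} of {n} rows")
    if n_target == n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=n_target, replace=False))


def augment_training_set(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    plan: AugmentationPlan,
    m: int = 5,
    k: int = 5,
    standardize: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build the balanced training matrix a plan describes.

    Synthesis runs in z-scored feature space (fit on the provided rows)
    so neighborhoods are scale-free, and synthetic rows are mapped back
    to the original scale. Returns (matrix, labels, provenance) where
    provenance flags each row ``original`` / ``synthetic`` /
    ``undersampled-kept``; the output is exactly 1:1.
    """
    labels = np.asarray(labels)
    if matrix.shape[0] != len(labels):
        raise ValueError("matrix rows must match labels")
    pos_rows = matrix.loc[labels == 1]
    neg_rows = matrix.loc[labels == 0]
    if len(pos_rows) != plan.n_pos_original:
        raise ValueError(
            f"plan expects {plan.n_pos_original} positives, matrix has "
            f"{len(pos_rows)}"
        )
    if plan.n_neg_target > len(neg_rows):
        raise ValueError(
            f"plan needs {plan.n_neg_target} negatives, only {len(neg_rows)} available"
        )
    X = matrix.to_numpy(dtype=float)
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mu, sd = 0.0, 1.0
    pos_z = (pos_rows.to_numpy(dtype=float) - mu) / sd
    neg_z = (neg_rows.to_numpy(dtype=float) - mu) / sd
    synth_z = borderline_smote(pos_z, neg_z, plan.n_synthetic, m=m, k=k, seed=plan.seed)
    synth = synth_z * sd + mu
    keep = random_undersample(neg_z, plan.n_neg_target, seed=plan.seed + 1)
    synth_df = pd.DataFrame(
        synth,
        columns=matrix.columns,
        index=[f"synthetic_{i + 1}" for i in range(len(synth))],
    )
    out = pd.concat([pos_rows, synth_df, neg_rows.iloc[keep]])
    out_labels = np.concatenate(
        [
            np.ones(len(pos_rows) + len(synth_df), dtype=int),
            np.zeros(plan.n_neg_target, dtype=int),
        ]
    )
    provenance = np.array(
        [ORIGINAL] * len(pos_rows)
        + [SYNTHETIC] * len(synth_df)
        + [KEPT] * plan.n_neg_target
    )
    return out, out_labels, provenance
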