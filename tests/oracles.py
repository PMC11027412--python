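"""Independent brute-force oracles used by the test suite.

Everything here is a naive, loop-by-loop transcription of the defining
formulas, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def aac(seq: str) -> list[float]:
    return [seq.count(t) / len(seq) for t in AA]


def cksaap(seq: str, kmax: int) -> list[float]:
    out = []
    for g in range(kmax + 1):
        pairs = [seq[i] + seq[i + g + 1] for i in range(len(seq) - g - 1)]
        for a, b in product(AA, repeat=2):
            out.append(pairs.count(a + b) / (len(seq) - g - 1))
    return out


def dde(seq: str, codon_counts: dict[str, int]) -> list[float]:
    L = len(seq)
    cn = sum(codon_counts.values())
    dipeps = [seq[i : i + 2] for i in range(L - 1)]
    out = []
    for r, s in product(AA, repeat=2):
        dc = dipeps.count(r + s) / (L - 1)
        tm = (codon_counts[r] / cn) * (codon_counts[s] / cn)
        tv = tm * (1 - tm) / (L - 1)
        out.append((dc - tm) / math.sqrt(tv))
    return out


def apaac(seq: str, lam: int, w: float, h1: dict, h2: dict) -> list[float]:
    L = len(seq)
    f = [seq.count(t) / L for t in AA]
    taus = []
    for k in range(1, lam + 1):
        t1 = sum(h1[seq[i]] * h1[seq[i + k]] for i in range(L - k)) / (L - k)
        t2 = sum(h2[seq[i]] * h2[seq[i + k]] for i in range(L - k)) / (L - k)
        taus += [t1, t2]
    denom = sum(f) + w * sum(taus)
    return [x / denom for x in f] + [w * t / denom for t in taus]


def asdc(seq: str) -> list[float]:
    L = len(seq)
    counts = {a + b: 0 for a, b in product(AA, repeat=2)}
    for i in range(L - 1):
        for j in range(i + 1, L):
            counts[seq[i] + seq[j]] += 1
    total = sum(counts.values())
    return [counts[a + b] / total for a, b in product(AA, repeat=2)]


def ctd(seq: str, properties: dict[str, tuple[str, str, str]]) -> list[float]:
    L = len(seq)
    out = []
    for groups in properties.values():
        enc = []
        for ch in seq:
            for g, members in enumerate(groups, start=1):
                if ch in members:
                    enc.append(g)
        for s in (1, 2, 3):
            out.append(enc.count(s) / L)
        for s, t in ((1, 2), (1, 3), (2, 3)):
            n = sum(
                1
                for i in range(L - 1)
                if (enc[i], enc[i + 1]) in ((s, t), (t, s))
            )
            out.append(n / (L - 1))
        for g in (1, 2, 3):
            pos = [i + 1 for i, e in enumerate(enc) if e == g]
            if not pos:
                out += [0.0] * 5
                continue
            n = len(pos)
            for q in (None, 0.25, 0.5, 0.75, 1.0):
                idx = 1 if q is None else max(1, math.ceil(q * n))
                out.append(pos[idx - 1] / L)
    return out


def qso(seq: str, nlag: int, w: float, matrices: list[np.ndarray]) -> list[float]:
    L = len(seq)
    f = [seq.count(t) for t in AA]
    out = []
    for d in matrices:
        taus = []
        for q in range(1, nlag + 1):
            taus.append(
                sum(
                    d[AA.index(seq[i]), AA.index(seq[i + q])] ** 2
                    for i in range(L - q)
                )
            )
        denom = sum(f) + w * sum(taus)
        out += [x / denom for x in f] + [w * t / denom for t in taus]
    return out


def entropy_bits(counts) -> float:
    total = sum(counts)
    return -sum(
        (c / total) * math.log2(c / total) for c in counts if c > 0
    )


def information_gain(feature, labels) -> float:
    """IG of a binary feature by direct entropy arithmetic."""
    feature = list(feature)
    labels = list(labels)
    classes = sorted(set(labels))
    h_c = entropy_bits([labels.count(c) for c in classes])
    n = len(labels)
    ig = h_c
    for v in (0, 1):
        sub = [l for f, l in zip(feature, labels) if f == v]
        if sub:
            ig -= (len(sub) / n) * entropy_bits([sub.count(c) for c in classes])
    return ig


def auroc_concordance(labels, scores) -> float:
    """All-pairs concordance count with ties at one half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def confusion_metrics(tp, fn, tn, fp):
    """Sn/Sp/ACC/MCC/F1 by direct arithmetic."""
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + fn + tn + fp)
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if d == 0 else (tp * tn - fp * fn) / math.sqrt(d)
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 0.0 if sn + pre == 0 else 2 * sn * pre / (sn + pre)
    return sn, sp, acc, mcc, f1


def borderline_roles(pos: np.ndarray, neg: np.ndarray, m: int):
    """(danger, noise) masks by exhaustive distance computation."""
    combined = np.vstack([pos, neg])
    is_neg = [False] * len(pos) + [True] * len(neg)
    danger, noise = [], []
    for i, p in enumerate(pos):
        dists = [
            (np.linalg.norm(p - combined[j]), j)
            for j in range(len(combined))
            if j != i
        ]
        dists.sort()
        maj = sum(1 for _, j in dists[:m] if is_neg[j])
        noise.append(maj == m)
        danger.append(m / 2 <= maj < m)
    return np.array(danger), np.array(noise)


def random_sequence(rng: np.random.Generator, lo: int = 5, hi: int = 30) -> str:
    L = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AA), size=L))
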