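"""Sequence descriptor encoders and their fusion into one feature space.

Seven descriptor families turn a variable-length peptide into a
fixed-length numeric vector:

===========  ====  =======================================================
family       dim   summary
===========  ====  =======================================================
AAC            20  residue frequencies N(t)/L
CKSAAP       1600  k-spaced residue-pair frequencies, gaps 0..3
DDE           400  dipeptide deviation from codon-derived expectation
APAAC          24  residue frequencies + lagged hydropathy correlations
ASDC          400  skip-dipeptide frequencies over all gaps, jointly scaled
CTD           273  composition/transition/distribution over 13 properties
QSO            44  frequencies + squared-distance sequence-order coupling
===========  ====  =======================================================

Under the default configuration the fused space has
20+1600+400+24+400+273+44 = 2761 columns, named ``<FAMILY>_<i>`` with
1-based indices so individual features (e.g. ``CTD_23``, ``QSO_1``,
``APAAC_20``) are addressable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._tables import (
    ALPHABET,
    AA_INDEX,
    CODON_COUNTS,
    CODON_TOTAL,
    CTD_PROPERTY_SETS,
    GRANTHAM,
    H1,
    H2,
    PHYSCHEM,
    validate_grouping,
)
from .io import LabeledDataset, PeptideRecord, POSITIVE, NEGATIVE

#: Ordered residue pairs AA, AC, ..., YY (row-major over ALPHABET).
PAIRS: list[str] = [a + b for a, b in product(ALPHABET, repeat=2)]

#: Fixed fusion order of the descriptor families.
FAMILIES = ("AAC", "CKSAAP", "DDE", "APAAC", "ASDC", "CTD", "QSO")


class EncodingLengthError(ValueError):
    """Sequence too short for an encoder under the given configuration."""


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunable descriptor parameters.

    Defaults give the fused 2761-dimensional space: CKSAAP gaps 0..3,
    APAAC lambda=2 / weight 0.5, QSO 2 lags / weight 0.05, and the
    13-property CTD set.
    """

    cksaap_kmax: int = 3
    apaac_lambda: int = 2
    apaac_w: float = 0.5
    qso_nlag: int = 2
    qso_w: float = 0.05
    ctd_property_set: str = "13"

    def __post_init__(self) -> None:
        if self.cksaap_kmax < 0:
            raise ValueError("cksaap_kmax must be >= 0")
        if self.apaac_lambda < 1:
            raise ValueError("apaac_lambda must be >= 1")
        if self.qso_nlag < 1:
            raise ValueError("qso_nlag must be >= 1")
        if self.apaac_w <= 0 or self.qso_w <= 0:
            raise ValueError("descriptor weights must be positive")
        if self.ctd_property_set not in CTD_PROPERTY_SETS:
            raise ValueError(
                f"unknown CTD property set {self.ctd_property_set!r}; "
                f"choose from {sorted(CTD_PROPERTY_SETS)}"
            )

    @property
    def ctd_properties(self) -> Mapping[str, tuple[str, str, str]]:
        return CTD_PROPERTY_SETS[self.ctd_property_set]

    @property
    def dimensions(self) -> dict[str, int]:
        """Closed-form output length per family."""
        return {
            "AAC": 20,
            "CKSAAP": 400 * (self.cksaap_kmax + 1),
            "DDE": 400,
            "APAAC": 20 + 2 * self.apaac_lambda,
            "ASDC": 400,
            "CTD": 21 * len(self.ctd_properties),
            "QSO": 2 * (20 + self.qso_nlag),
        }

    @property
    def fused_dimension(self) -> int:
        return sum(self.dimensions.values())

    def column_names(self, families: Sequence[str] = FAMILIES) -> list[str]:
        dims = self.dimensions
        return [
            f"{fam}_{i}" for fam in families for i in range(1, dims[fam] + 1)
        ]


def _seq(record: PeptideRecord | str) -> str:
    return record.sequence if isinstance(record, PeptideRecord) else record


def encode_aac(record: PeptideRecord | str) -> np.ndarray:
    """Amino-acid composition: per-residue frequency N(t)/L. Sums to 1."""
    seq = _seq(record)
    out = np.zeros(20)
    for ch in seq:
        out[AA_INDEX[ch]] += 1.0
    return out / len(seq)


def encode_cksaap(record: PeptideRecord | str, kmax: int = 3) -> np.ndarray:
    """Composition of k-spaced residue pairs for gaps g = 0..kmax.

    For gap g the pair (s_i, s_{i+g+1}) is tallied over the
    N_total = L - g - 1 available positions and divided by N_total, so
    each 400-long gap block sums to 1.
    """
    seq = _seq(record)
    L = len(seq)
    if L < kmax + 2:
        raise EncodingLengthError(
            f"CKSAAP with kmax={kmax} needs length >= {kmax + 2}, got {L}"
        )
    blocks = []
    for g in range(kmax + 1):
        counts = np.zeros(400)
        n_total = L - g - 1
        for i in range(n_total):
            counts[AA_INDEX[seq[i]] * 20 + AA_INDEX[seq[i + g + 1]]] += 1.0
        blocks.append(counts / n_total)
    return np.concatenate(blocks)


def encode_dde(record: PeptideRecord | str) -> np.ndarray:
    """Dipeptide deviation from expected mean.

    For each ordered dipeptide (r, s):
    D_c = N(r,s)/(L-1), T_m = (C_r/C_N)(C_s/C_N) with codon counts of the
    standard genetic code (C_N = 61), T_v = T_m (1-T_m)/(L-1), and
    DDE = (D_c - T_m)/sqrt(T_v).
    """
    seq = _seq(record)
    L = len(seq)
    if L < 2:
        raise EncodingLengthError(f"DDE needs length >= 2, got {L}")
    dc = np.zeros(400)
    for i in range(L - 1):
        dc[AA_INDEX[seq[i]] * 20 + AA_INDEX[seq[i + 1]]] += 1.0
    dc /= L - 1
    frac = np.array([CODON_COUNTS[aa] / CODON_TOTAL for aa in ALPHABET])
    tm = np.outer(frac, frac).ravel()
    tv = tm * (1.0 - tm) / (L - 1)
    return (dc - tm) / np.sqrt(tv)


def encode_apaac(
    record: PeptideRecord | str, lam: int = 2, w: float = 0.5
) -> np.ndarray:
    """Amphiphilic pseudo-amino-acid composition.

    The first 20 components are residue frequencies, the last 2*lam are
    lagged correlation terms tau, alternating hydrophobicity and
    hydrophilicity products of the standardized scales:
    tau_{2k-1} = mean_i H1(s_i) H1(s_{i+k}),
    tau_{2k}   = mean_i H2(s_i) H2(s_{i+k}), k = 1..lam.
    Both parts share the denominator sum(f) + w * sum(tau).
    """
    seq = _seq(record)
    L = len(seq)
    if L <= lam:
        raise EncodingLengthError(f"APAAC with lambda={lam} needs length > {lam}")
    f = encode_aac(seq)
    idx = np.array([AA_INDEX[ch] for ch in seq])
    h1, h2 = H1[idx], H2[idx]
    taus = []
    for k in range(1, lam + 1):
        taus.append((h1[:-k] * h1[k:]).mean())
        taus.append((h2[:-k] * h2[k:]).mean())
    tau = np.array(taus)
    denom = f.sum() + w * tau.sum()
    return np.concatenate([f / denom, w * tau / denom])


def encode_asdc(record: PeptideRecord | str) -> np.ndarray:
    """Adaptive skip dipeptide composition.

    Every ordered residue pair (s_i, s_j) with i < j, at any gap, is
    tallied; frequencies are normalized by the total tally L(L-1)/2, so
    the 400 components sum to 1.
    """
    seq = _seq(record)
    L = len(seq)
    if L < 2:
        raise EncodingLengthError(f"ASDC needs length >= 2, got {L}")
    counts = np.zeros(400)
    for i in range(L - 1):
        a = AA_INDEX[seq[i]] * 20
        for j in range(i + 1, L):
            counts[a + AA_INDEX[seq[j]]] += 1.0
    return counts / counts.sum()


def _ctd_one_property(seq: str, groups: tuple[str, str, str]) -> np.ndarray:
    L = len(seq)
    code = np.empty(L, dtype=int)
    lookup = {}
    for g, members in enumerate(groups, start=1):
        for aa in members:
            lookup[aa] = g
    for i, ch in enumerate(seq):
        code[i] = lookup[ch]
    comp = np.array([(code == g).sum() / L for g in (1, 2, 3)])
    trans = np.zeros(3)
    if L > 1:
        a, b = code[:-1], code[1:]
        for t, (u, v) in enumerate(((1, 2), (1, 3), (2, 3))):
            trans[t] = (((a == u) & (b == v)) | ((a == v) & (b == u))).sum() / (
                L - 1
            )
    dist = np.zeros(15)
    for g in (1, 2, 3):
        pos = np.flatnonzero(code == g) + 1  # 1-based positions
        if len(pos) == 0:
            continue
        n = len(pos)
        picks = [1] + [max(1, math.ceil(q * n)) for q in (0.25, 0.5, 0.75, 1.0)]
        for x, p in enumerate(picks):
            dist[(g - 1) * 5 + x] = pos[p - 1] / L
    return np.concatenate([comp, trans, dist])


def encode_ctd(
    record: PeptideRecord | str,
    properties: Mapping[str, tuple[str, str, str]] | None = None,
) -> np.ndarray:
    """Composition/transition/distribution descriptor.

    Per property (default: the 13-property set, 273 features): the
    sequence is recoded into groups 1/2/3, then 3 composition values
    N_s/L, 3 transition values (N_st + N_ts)/(L-1) for st in
    {12, 13, 23}, and 15 distribution values P_i/L at the first, 25%,
    50%, 75% and 100% occurrence of each group (0 for an absent group).
    """
    seq = _seq(record)
    if properties is None:
        properties = CTD_PROPERTY_SETS["13"]
    for groups in properties.values():
        validate_grouping(groups)
    return np.concatenate(
        [_ctd_one_property(seq, groups) for groups in properties.values()]
    )


def encode_qso(
    record: PeptideRecord | str, nlag: int = 2, w: float = 0.05
) -> np.ndarray:
    """Quasi-sequence-order descriptor.

    For each of two residue distance matrices (physicochemical
    Schneider-Wrede-style, then Grantham), sequence-order coupling
    numbers tau_q = sum_i d(s_i, s_{i+q})^2 for q = 1..nlag are combined
    with residue frequencies: the block's first 20 components are
    f_r / (sum f + w sum tau) and the last nlag are
    w tau_q / (sum f + w sum tau); each block sums to 1.
    """
    seq = _seq(record)
    L = len(seq)
    if L <= nlag:
        raise EncodingLengthError(f"QSO with nlag={nlag} needs length > {nlag}")
    f = encode_aac(seq) * L  # raw counts; normalization cancels in the ratio
    idx = np.array([AA_INDEX[ch] for ch in seq])
    blocks = []
    for dmat in (PHYSCHEM, GRANTHAM):
        tau = np.array(
            [(dmat[idx[:-q], idx[q:]] ** 2).sum() for q in range(1, nlag + 1)]
        )
        denom = f.sum() + w * tau.sum()
        blocks.append(np.concatenate([f / denom, w * tau / denom]))
    return np.concatenate(blocks)


_ENCODERS = {
    "AAC": lambda seq, cfg: encode_aac(seq),
    "CKSAAP": lambda seq, cfg: encode_cksaap(seq, cfg.cksaap_kmax),
    "DDE": lambda seq, cfg: encode_dde(seq),
    "APAAC": lambda seq, cfg: encode_apaac(seq, cfg.apaac_lambda, cfg.apaac_w),
    "ASDC": lambda seq, cfg: encode_asdc(seq),
    "CTD": lambda seq, cfg: encode_ctd(seq, cfg.ctd_properties),
    "QSO": lambda seq, cfg: encode_qso(seq, cfg.qso_nlag, cfg.qso_w),
}


def encode_fused(
    data: LabeledDataset,
    config: DescriptorConfig | None = None,
    families: Sequence[str] = FAMILIES,
) -> pd.DataFrame:
    """Encode every record with the requested families and fuse column-wise.

    Returns a DataFrame indexed by peptide id with stable ``FAMILY_i``
    column names; under the default configuration and all seven families
    the result has 2761 columns.
    """
    if config is None:
        config = DescriptorConfig()
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown descriptor families: {sorted(unknown)}")
    families = [f for f in FAMILIES if f in families]
    rows = np.empty((len(data), sum(config.dimensions[f] for f in families)))
    for r, record in enumerate(data):
        try:
            rows[r] = np.concatenate(
                [_ENCODERS[fam](record.sequence, config) for fam in families]
            )
        except EncodingLengthError as exc:
            raise EncodingLengthError(f"record {record.id!r}: {exc}") from exc
    if not np.isfinite(rows).all():
        raise ValueError("non-finite descriptor values produced")
    return pd.DataFrame(rows, index=data.ids, columns=config.column_names(families))


def composition_report(
    pos: LabeledDataset, neg: LabeledDataset
) -> pd.DataFrame:
    """Per-class mean amino-acid composition and per-residue difference.

    Returns one row per residue with columns ``positive``, ``negative``
    and ``difference`` (positive minus negative); each class column sums
    to 1.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be nonempty")
    pos_mean = np.mean([encode_aac(r) for r in pos], axis=0)
    neg_mean = np.mean([encode_aac(r) for r in neg], axis=0)
    return pd.DataFrame(
        {
            "positive": pos_mean,
            "negative": neg_mean,
            "difference": pos_mean - neg_mean,
        },
        index=list(ALPHABET),
    )
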