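"""Physicochemical reference tables used by the descriptor encoders.

Everything here is derived from classical, widely reused amino-acid
property compilations: the Grantham (1974) residue composition/polarity/
volume values, the hydropathy scales of the original pseudo-amino-acid
composition definition (Tanford hydrophobicity, Hopp-Woods hydrophilicity,
side-chain mass), the standard genetic code, and the standard 13-property
three-group residue classification used by composition/transition/
distribution descriptors.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino-acid alphabet, alphabetical by one-letter code.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# ---------------------------------------------------------------------------
# Hydropathy scales (pseudo-amino-acid composition originals, unstandardized)
# ---------------------------------------------------------------------------

#: Tanford hydrophobicity.
HYDROPHOBICITY_RAW = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

#: Hopp-Woods hydrophilicity.
HYDROPHILICITY_RAW = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

#: Side-chain mass (Da), used only to build the synthetic stand-in
#: physicochemical distance matrix below.
SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def _standardize(scale: dict[str, float]) -> np.ndarray:
    """Zero-mean, unit-SD values over the 20 residues, in ALPHABET order."""
    v = np.array([scale[aa] for aa in ALPHABET], dtype=float)
    return (v - v.mean()) / v.std()


#: Standardized hydrophobicity H1 and hydrophilicity H2, ALPHABET order.
H1 = _standardize(HYDROPHOBICITY_RAW)
H2 = _standardize(HYDROPHILICITY_RAW)

# ---------------------------------------------------------------------------
# Codon counts (standard genetic code)
# ---------------------------------------------------------------------------


def _codon_counts() -> dict[str, int]:
    from Bio.Data.CodonTable import standard_dna_table

    counts: dict[str, int] = {aa: 0 for aa in ALPHABET}
    for codon, aa in standard_dna_table.forward_table.items():
        if aa in counts:
            counts[aa] += 1
    return counts


#: Number of sense codons per residue under the standard genetic code.
CODON_COUNTS: dict[str, int] = _codon_counts()
#: Total sense codons (61).
CODON_TOTAL: int = sum(CODON_COUNTS.values())

# ---------------------------------------------------------------------------
# Residue distance matrices for quasi-sequence-order
# ---------------------------------------------------------------------------

#: Grantham (1974) residue properties: composition c, polarity p, volume v.
_GRANTHAM_PROPS = {
    "A": (0.00, 8.1, 31.0), "C": (2.75, 5.5, 55.0), "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0), "F": (0.00, 5.2, 132.0), "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0), "I": (0.00, 5.2, 111.0), "K": (0.33, 11.3, 119.0),
    "L": (0.00, 4.9, 111.0), "M": (0.00, 5.7, 105.0), "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5), "Q": (0.89, 10.5, 85.0), "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0), "T": (0.71, 8.6, 61.0), "V": (0.00, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0), "Y": (0.20, 6.2, 136.0),
}


def _grantham_matrix() -> np.ndarray:
    """Grantham chemical distance, rebuilt from his formula.

    D_ij = rho * sqrt(alpha (c_i-c_j)^2 + beta (p_i-p_j)^2 + gamma (v_i-v_j)^2)
    with alpha=1.833, beta=0.1018, gamma=0.000399 and rho scaling the mean
    off-diagonal distance to 100, reproducing the published matrix to within
    rounding.
    """
    alpha, beta, gamma = 1.833, 0.1018, 0.000399
    c = np.array([_GRANTHAM_PROPS[aa][0] for aa in ALPHABET])
    p = np.array([_GRANTHAM_PROPS[aa][1] for aa in ALPHABET])
    v = np.array([_GRANTHAM_PROPS[aa][2] for aa in ALPHABET])
    d = np.sqrt(
        alpha * (c[:, None] - c[None, :]) ** 2
        + beta * (p[:, None] - p[None, :]) ** 2
        + gamma * (v[:, None] - v[None, :]) ** 2
    )
    off = d[~np.eye(20, dtype=bool)]
    return d * (100.0 / off.mean())


def _physchem_matrix() -> np.ndarray:
    """Synthetic stand-in for the Schneider-Wrede physicochemical distance.

    The original matrix has no citable machine-readable source here, so a
    physicochemical distance is constructed the same way the pseudo-amino-
    acid correlation functions weigh residues: Euclidean distance over
    standardized hydrophobicity, hydrophilicity, and side-chain mass, scaled
    to a maximum of 1. Symmetric, nonnegative, zero diagonal.
    """
    m = _standardize(SIDECHAIN_MASS)
    props = np.stack([H1, H2, m], axis=1)
    diff = props[:, None, :] - props[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return d / d.max()


#: 20x20 Grantham chemical distance matrix, ALPHABET order.
GRANTHAM: np.ndarray = _grantham_matrix()
#: 20x20 physicochemical distance matrix (synthetic Schneider-Wrede stand-in).
PHYSCHEM: np.ndarray = _physchem_matrix()

# ---------------------------------------------------------------------------
# CTD three-group residue classifications
# ---------------------------------------------------------------------------

#: property name -> (group1, group2, group3); each group a string of residues,
#: the three groups partitioning the 20-letter alphabet. The first seven are
#: the classical Dubchak-style attribute groupings (charge, one hydrophobicity
#: scale, van der Waals volume, polarity, polarizability, secondary structure,
#: solvent accessibility); the remaining six are further standard
#: hydrophobicity groupings completing the 13-property set (13 x 21 = 273
#: features).
CTD_PROPERTIES_13: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

#: The seven classically tabulated attributes (subset of the 13).
CTD_PROPERTIES_7: dict[str, tuple[str, str, str]] = {
    name: CTD_PROPERTIES_13[name]
    for name in (
        "charge",
        "hydrophobicity_PRAM900101",
        "normwaalsvolume",
        "polarity",
        "polarizability",
        "secondarystruct",
        "solventaccess",
    )
}

CTD_PROPERTY_SETS = {"13": CTD_PROPERTIES_13, "7": CTD_PROPERTIES_7}


def validate_grouping(groups: tuple[str, str, str]) -> None:
    """Raise ValueError unless the three groups partition the alphabet."""
    joined = "".join(groups)
    if sorted(joined) != sorted(ALPHABET):
        raise ValueError(
            f"residue groups {groups!r} do not partition the 20-letter alphabet"
        )


for _name, _groups in CTD_PROPERTIES_13.items():
    validate_grouping(_groups)
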