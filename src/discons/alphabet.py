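"""Amino-acid and nucleotide vocabularies, background frequencies and scales.

Everything downstream works on the canonical 20-letter alphabet in the fixed
order ``ARNDCQEGHILKMFPSTWYV``; ``X`` is tolerated as an unknown residue.
"""

from __future__ import annotations

import numpy as np

#: Canonical one-letter amino-acid alphabet (fixed order used for all vectors).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
UNKNOWN = "X"
GAP = "-"

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common non-standard residues mapped to their parents
    "MSE": "M", "SEC": "C", "PYL": "K",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items() if k not in ("MSE", "SEC", "PYL")}

#: Residue-name vocabularies used for polymer typing of structure chains.
PROTEIN_RESIDUES = frozenset(AA_THREE_TO_ONE) | {"UNK"}
RNA_RESIDUES = frozenset({"A", "C", "G", "U", "I", "N"})
DNA_RESIDUES = frozenset({"DA", "DC", "DG", "DT", "DU", "DI", "DN"})
NUCLEOTIDE_RESIDUES = RNA_RESIDUES | DNA_RESIDUES
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# BLOSUM62 marginal amino-acid frequencies (Capra & Singh conservation-scoring
# background), order AMINO_ACIDS; renormalized to sum exactly to 1.
_BLOSUM62_RAW = np.array([
    0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
    0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072,
])
BLOSUM62_BACKGROUND = _BLOSUM62_RAW / _BLOSUM62_RAW.sum()
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

BACKGROUNDS = {
    "blosum62": BLOSUM62_BACKGROUND,
    "uniform": UNIFORM_BACKGROUND,
}

# TOP-IDP disorder-propensity scale (Campen et al. 2008), order AMINO_ACIDS.
# Positive values are disorder-promoting, negative values order-promoting.
TOP_IDP = {
    "A": 0.060, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.020,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

#: Net side-chain charge at neutral pH (His counted as half-protonated).
CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE.update({"R": 1.0, "K": 1.0, "H": 0.5, "D": -1.0, "E": -1.0})


def background_distribution(name_or_vector) -> np.ndarray:
    """Resolve a background distribution by name or validate a 20-vector."""
    if isinstance(name_or_vector, str):
        try:
            return BACKGROUNDS[name_or_vector]
        except KeyError:
            raise ValueError(
                f"unknown background {name_or_vector!r}; choose from {sorted(BACKGROUNDS)}"
            ) from None
    vec = np.asarray(name_or_vector, dtype=float)
    if vec.shape != (20,) or not np.isclose(vec.sum(), 1.0) or (vec < 0).any():
        raise ValueError("background must be a 20-dim probability vector")
    return vec
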