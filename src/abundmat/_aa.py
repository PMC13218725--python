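"""Amino-acid constants shared across the package."""

from __future__ import annotations

import numpy as np

#: Canonical one-letter codes, alphabetical. This is the storage order of all
#: 20x20 matrices; display reordering is a presentation concern only.
AA_ORDER: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Kyte-Doolittle hydropathy (unitless) and Zamyatnin side-chain volumes (A^3);
# used only by the synthetic generator to shape plausible mean-effect matrices.
KD_HYDROPATHY: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9,
    "G": 60.1, "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7,
    "M": 162.9, "N": 114.1, "P": 112.7, "Q": 143.8, "R": 173.4,
    "S": 89.0, "T": 116.1, "V": 140.0, "W": 227.8, "Y": 193.6,
}


def aa_codes(seq) -> np.ndarray:
    """Map an iterable of one-letter codes to integer indices in AA_ORDER."""
    return np.asarray([AA_INDEX[a] for a in seq], dtype=np.intp)
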