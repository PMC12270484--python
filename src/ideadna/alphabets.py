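"""Closed residue alphabets and index maps shared across the package.

The canonical feature space is the outer product of the 20 standard amino
acids and the 4 deoxyribonucleotides, flattened row-major (amino-acid-major)
to a vector of length :data:`N_FEATURES`.
"""

from __future__ import annotations

import numpy as np

#: One-letter amino-acid alphabet, alphabetical; fixes the row order of
#: every 20x4 matrix in the package.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Nucleotide column order (one-letter); corresponds to residue names
#: DA, DT, DC, DG.
NT_ALPHABET: str = "ATCG"

#: PDB residue names matching NT_ALPHABET order.
NT_NAMES: tuple[str, ...] = ("DA", "DT", "DC", "DG")

N_AA = len(AA_ALPHABET)
N_NT = len(NT_ALPHABET)
#: Flattened feature dimension (20 x 4).
N_FEATURES = N_AA * N_NT

AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
NT_INDEX = {n: i for i, n in enumerate(NT_ALPHABET)}
NT_NAME_INDEX = {n: i for i, n in enumerate(NT_NAMES)}

#: Watson-Crick complement on the one-letter alphabet.
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def aa_codes(seq: str) -> np.ndarray:
    """Encode an amino-acid string as integer row indices."""
    try:
        return np.array([AA_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"unknown amino-acid letter {exc.args[0]!r}") from None


def nt_codes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as integer column indices."""
    try:
        return np.array([NT_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown nucleotide letter {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq.upper()))
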