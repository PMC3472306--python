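"""Low-level DNA alphabet helpers shared across the package.

Everything downstream works on uppercase ACGT. IUPAC degeneracy codes are
allowed only in motif consensus strings, never in scored instances.
"""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(DNA_BASES)}
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# IUPAC nucleotide codes -> set of compatible concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# (len(IUPAC-alphabet), 4) boolean compatibility table, row order below
IUPAC_LETTERS = "ACGTRYSWKMBDHVN"
IUPAC_INDEX = {c: i for i, c in enumerate(IUPAC_LETTERS)}
IUPAC_COMPAT = np.zeros((len(IUPAC_LETTERS), 4), dtype=bool)
for _c, _bases in IUPAC.items():
    for _b in _bases:
        IUPAC_COMPAT[IUPAC_INDEX[_c], BASE_INDEX[_b]] = True


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_dna(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 index array (A=0,C=1,G=2,T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in DNA sequence")
    return out


def decode_dna(indices: np.ndarray) -> str:
    return "".join(DNA_BASES[i] for i in indices)


def encode_iupac(consensus: str) -> np.ndarray:
    """Encode an IUPAC consensus as row indices into IUPAC_COMPAT."""
    try:
        return np.array([IUPAC_INDEX[c] for c in consensus], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in consensus") from None


def revcomp_indices(indices: np.ndarray) -> np.ndarray:
    return (3 - indices)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and all(c in BASE_INDEX for c in seq)


def is_protein(seq: str) -> bool:
    return bool(seq) and all(c in PROTEIN_ALPHABET for c in seq)
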