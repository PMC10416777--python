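"""Canonical amino-acid alphabet shared by every module.

The residue ordering is the one used by PAML-style empirical model files
(A R N D C Q E G H I L K M F P S T W Y V); exchangeability vectors, rate
matrices and composition vectors all follow it.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"
N_STATES: int = 20
#: number of unordered residue pairs (lower triangle of a 20x20 matrix)
N_PAIRS: int = N_STATES * (N_STATES - 1) // 2
#: free exchangeability parameters once the vector is confined to the simplex
N_FREE_EXCHANGEABILITIES: int = N_PAIRS - 1

INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: residues treated as fully missing in likelihood computations
MISSING_SYMBOLS = frozenset("XBZJUO-?.*~")

# (i, j) index pairs for the lower triangle, in dat-file row order:
# row i of a dat file lists rates to residues 0..i-1.
PAIR_INDICES = [(i, j) for i in range(1, N_STATES) for j in range(i)]
_PAIR_I = np.array([p[0] for p in PAIR_INDICES])
_PAIR_J = np.array([p[1] for p in PAIR_INDICES])


def pairs_to_matrix(values: np.ndarray) -> np.ndarray:
    """Expand a 190-vector of pair rates into a symmetric 20x20 matrix
    with zero diagonal."""
    values = np.asarray(values, dtype=float)
    if values.shape != (N_PAIRS,):
        raise ValueError(f"expected {N_PAIRS} pair rates, got shape {values.shape}")
    m = np.zeros((N_STATES, N_STATES))
    m[_PAIR_I, _PAIR_J] = values
    m[_PAIR_J, _PAIR_I] = values
    return m


def matrix_to_pairs(m: np.ndarray) -> np.ndarray:
    """Extract the lower-triangle 190-vector from a symmetric matrix."""
    m = np.asarray(m, dtype=float)
    return m[_PAIR_I, _PAIR_J].copy()


def encode_sequence(seq: str) -> np.ndarray:
    """Map a residue string to integer codes; missing/ambiguous symbols
    become N_STATES (20)."""
    out = np.empty(len(seq), dtype=np.int8)
    for k, ch in enumerate(seq.upper()):
        idx = INDEX.get(ch)
        if idx is None:
            if ch not in MISSING_SYMBOLS:
                raise ValueError(f"unknown residue symbol {ch!r} at position {k}")
            out[k] = N_STATES
        else:
            out[k] = idx
    return out
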