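"""Integer encoding of aligned nucleotide sequences.

Sequences are stored as uint8 matrices (rows = samples, columns = alignment
positions) with A,C,G,T -> 0..3.  Purines are {A=0, G=2}, pyrimidines
{C=1, T=3}, so a substitution i -> j is a transition iff (i + j) % 2 == 0
and i != j.  N and '-' map to 4 and are treated as ambiguous.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
_LUT = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_LUT[ord("-")] = 4

AMBIG = 4  # code for N or gap


def encode(seqs) -> np.ndarray:
    """Encode an iterable of equal-length strings into a uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    mat = _LUT[raw].reshape(len(seqs), lengths.pop())
    if (mat == 255).any():
        bad = chr(raw[(_LUT[raw] == 255).argmax()])
        raise ValueError(f"invalid sequence character {bad!r}")
    return mat


def decode(mat: np.ndarray) -> list[str]:
    """Inverse of :func:`encode` (ambiguous code renders as N)."""
    return ["".join(BASES[b] for b in row) for row in np.asarray(mat, dtype=np.uint8)]


def is_transition(i: int, j: int) -> bool:
    return i != j and (int(i) + int(j)) % 2 == 0
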