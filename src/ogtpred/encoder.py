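"""One-hot encoding of amino-acid sequences into fixed-shape matrices.

Each sequence becomes an ``L_max × 20`` binary matrix with the residue
channels in alphabetical single-letter order (A, C, D, …, Y).  The unknown
symbol encodes as an all-zero row (no 21st channel); sequences longer than
``L_max`` are truncated at the C-terminus, shorter ones zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ogtpred.corpus import STANDARD_AA, UNKNOWN_AA, ProteinRecord

#: residue → column index; the unknown symbol is deliberately absent.
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

DEFAULT_L_MAX = 1000


@dataclass(frozen=True)
class EncodedSequence:
    matrix: np.ndarray  # (L_max, 20) float32 in {0, 1}
    true_length: int    # residues actually encoded (<= L_max)
    protein_id: str


def one_hot_encode(sequence: str, l_max: int = DEFAULT_L_MAX, protein_id: str = "") -> EncodedSequence:
    """Encode one sequence.

    Raises ``ValueError`` on an empty sequence, ``l_max < 1``, or a residue
    outside the normalised alphabet (20 standard letters + unknown).
    """
    if l_max < 1:
        raise ValueError(f"l_max must be >= 1, got {l_max}")
    if len(sequence) == 0:
        raise ValueError(f"cannot encode empty sequence (protein {protein_id!r})")
    matrix = np.zeros((l_max, 20), dtype=np.float32)
    clipped = sequence[:l_max]
    for pos, aa in enumerate(clipped):
        col = AA_INDEX.get(aa)
        if col is not None:
            matrix[pos, col] = 1.0
        elif aa != UNKNOWN_AA:
            raise ValueError(
                f"residue {aa!r} at position {pos} of protein {protein_id!r} "
                "is outside the normalised alphabet"
            )
    return EncodedSequence(matrix=matrix, true_length=len(clipped), protein_id=protein_id)


def decode(encoded: EncodedSequence) -> str:
    """Inverse of :func:`one_hot_encode` up to truncation: all-zero rows
    within ``true_length`` decode to the unknown symbol."""
    out = []
    for row in encoded.matrix[: encoded.true_length]:
        hits = np.flatnonzero(row)
        out.append(STANDARD_AA[hits[0]] if hits.size else UNKNOWN_AA)
    return "".join(out)


def encode_batch(
    proteins: Sequence[ProteinRecord], l_max: int = DEFAULT_L_MAX
) -> tuple[np.ndarray, dict[str, int]]:
    """Stack encodings of ``proteins`` in input order.

    Returns the ``(N, L_max, 20)`` tensor and a protein_id → row index map.
    Per-sequence failures are re-raised with the protein id attached.
    """
    if len(proteins) == 0:
        raise ValueError("cannot encode an empty batch")
    batch = np.zeros((len(proteins), l_max, 20), dtype=np.float32)
    index: dict[str, int] = {}
    for row, protein in enumerate(proteins):
        try:
            enc = one_hot_encode(protein.sequence, l_max, protein.protein_id)
        except ValueError as exc:
            raise ValueError(f"encoding failed for {protein.protein_id!r}: {exc}") from exc
        batch[row] = enc.matrix
        index[protein.protein_id] = row
    return batch, index
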