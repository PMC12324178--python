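"""Integer encoding and batch padding of nucleotide sequences."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: token values: 0 = pad, A=1, C=2, G=3, T=4, N=5
_LUT = np.zeros(256, dtype=np.int32)
for i, base in enumerate("ACGTN", start=1):
    _LUT[ord(base)] = i
    _LUT[ord(base.lower())] = i


class EncodingError(ValueError):
    pass


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a nucleotide string (case-insensitive) as integers 1-5.

    A, C, G, T, N map to 1..5; any other character raises
    :class:`EncodingError` naming the offending position.
    """
    raw = np.frombuffer(sequence.encode(), dtype=np.uint8)
    tokens = _LUT[raw]
    if len(tokens) and tokens.min() == 0:
        pos = int(np.flatnonzero(tokens == 0)[0])
        raise EncodingError(
            f"invalid character {sequence[pos]!r} at position {pos}"
        )
    return tokens


@dataclass
class EncodedBatch:
    """A padded batch of integer-encoded reads.

    ``tokens`` is (batch, max_len) with 0 exactly at padded positions,
    ``mask`` marks real bases, ``lengths`` the per-read true lengths.
    """

    tokens: np.ndarray
    mask: np.ndarray
    lengths: np.ndarray

    def unpad(self) -> list[np.ndarray]:
        return [self.tokens[i, : n] for i, n in enumerate(self.lengths)]


def pad_batch(sequences: Sequence[np.ndarray]) -> EncodedBatch:
    """Right-pad encoded reads with 0 to the within-batch maximum length."""
    if len(sequences) == 0:
        raise ValueError("empty batch")
    lengths = np.array([len(s) for s in sequences], dtype=np.int64)
    width = int(lengths.max()) if len(lengths) else 0
    tokens = np.zeros((len(sequences), width), dtype=np.int32)
    for i, s in enumerate(sequences):
        tokens[i, : len(s)] = s
    mask = np.arange(width)[None, :] < lengths[:, None]
    return EncodedBatch(tokens=tokens, mask=mask, lengths=lengths)
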