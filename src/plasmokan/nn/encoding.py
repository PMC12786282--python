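"""Sinusoidal positional encoding for the spectral patch sequence.

The angle rate for patch position ``pos`` and dimension-pair index ``i`` is
``pos / 10000**(2i / d_model)``; even embedding dimensions carry the sine and
odd dimensions the cosine of that angle.  The rate is evaluated directly (not
through logarithms) so position 0 is well defined.
"""

from __future__ import annotations

import numpy as np


def positional_encoding(num_positions: int, d_model: int) -> np.ndarray:
    """Encoding matrix of shape ``(num_positions, d_model)`` with entries in [-1, 1]."""
    if num_positions < 1:
        raise ValueError("num_positions must be >= 1")
    if d_model < 2 or d_model % 2:
        raise ValueError("d_model must be a positive even integer")
    pos = np.arange(num_positions, dtype=float)[:, None]
    i = np.arange(d_model // 2, dtype=float)[None, :]
    angle = pos / 10000.0 ** (2.0 * i / d_model)
    enc = np.empty((num_positions, d_model))
    enc[:, 0::2] = np.sin(angle)
    enc[:, 1::2] = np.cos(angle)
    return enc
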