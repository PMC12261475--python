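"""Fixed-length model inputs: padding and sliding-window extraction.

Training positives shorter than the 40-residue input are *prepadded*
with residues sampled from a background frequency table (the pad mimics
noise in front of the motif). Scan-time inputs shorter than the window
are *zero postpadded* with the PAD token. Longer sequences are processed
with a sliding window of size 40 and step 1. The asymmetry between the
two padding modes is deliberate and preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import PAD_INDEX
from .background import BackgroundFreqTable
from .io import SequenceRecord

WINDOW_SIZE = 40


@dataclass(frozen=True)
class Window:
    """A fixed-length token window over a parent sequence.

    ``start``/``end`` are 0-based half-open coordinates in the parent.
    For a postpadded short sequence, ``end`` is the true sequence length
    (< window size) while ``tokens`` has the full window length.
    """

    parent_id: str
    start: int
    end: int
    tokens: np.ndarray

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window interval [{self.start}, {self.end})")
        if len(self.tokens) != WINDOW_SIZE:
            raise ValueError(f"window tokens must have length {WINDOW_SIZE}")


def prepad_random(
    tokens: np.ndarray,
    freqs: BackgroundFreqTable,
    rng: np.random.Generator,
    target_len: int = WINDOW_SIZE,
) -> np.ndarray:
    """Left-pad with residue tokens sampled i.i.d. from ``freqs``.

    The suffix of the result is the input, unchanged; pad positions are
    real residue tokens (never PAD). Deterministic given the generator
    state.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    n = len(tokens)
    if n == 0:
        raise ValueError("cannot pad an empty token list")
    if n > target_len:
        raise ValueError(
            f"sequence of length {n} exceeds target {target_len}; window it instead"
        )
    if n == target_len:
        return tokens.copy()
    pad = freqs.sample_tokens(target_len - n, rng)
    return np.concatenate([pad, tokens])


def postpad_zero(tokens: np.ndarray, target_len: int = WINDOW_SIZE) -> np.ndarray:
    """Right-pad with the PAD token (index 0) up to ``target_len``."""
    tokens = np.asarray(tokens, dtype=np.int64)
    n = len(tokens)
    if n == 0:
        raise ValueError("cannot pad an empty token list")
    if n > target_len:
        raise ValueError(
            f"sequence of length {n} exceeds target {target_len}; window it instead"
        )
    out = np.full(target_len, PAD_INDEX, dtype=np.int64)
    out[:n] = tokens
    return out


def make_windows(
    record: SequenceRecord,
    tokens: np.ndarray,
    size: int = WINDOW_SIZE,
    step: int = 1,
) -> list[Window]:
    """Slide a window of ``size`` with ``step`` over an encoded sequence.

    A sequence shorter than the window yields exactly one zero-postpadded
    window spanning the whole sequence.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    tokens = np.asarray(tokens, dtype=np.int64)
    n = len(tokens)
    if n != len(record.residues):
        raise ValueError("token length does not match record length")
    if n < size:
        return [Window(record.id, 0, n, postpad_zero(tokens, size))]
    return [
        Window(record.id, s, s + size, tokens[s : s + size])
        for s in range(0, n - size + 1, step)
    ]


def window_count(length: int, size: int = WINDOW_SIZE, step: int = 1) -> int:
    """Number of windows a sequence of ``length`` produces."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return max(1, (length - size) // step + 1)
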