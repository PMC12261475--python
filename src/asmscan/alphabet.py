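"""Residue alphabet and integer encoding of protein sequences.

The scanner's embedding layer works on a fixed 26-token vocabulary:
index 0 is reserved for the padding token (PAD), indices 1-25 cover the
20 canonical amino acids plus the extended IUPAC letters B, Z, X, U, O.
Cleaned sequences never contain PAD; it only appears through explicit
zero postpadding of short scan inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: canonical 20 amino acids followed by extended letters
RESIDUE_LETTERS = "ACDEFGHIKLMNPQRSTVWYBZXUO"

PAD_SYMBOL = "-"
PAD_INDEX = 0


@dataclass(frozen=True)
class Alphabet:
    """Bijective symbol <-> index map over PAD plus 25 residue letters."""

    symbols: tuple[str, ...] = (PAD_SYMBOL,) + tuple(RESIDUE_LETTERS)
    index_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.symbols) != 26:
            raise ValueError(f"alphabet must have 26 tokens, got {len(self.symbols)}")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.symbols[0] != PAD_SYMBOL:
            raise ValueError("index 0 must be the PAD token")
        object.__setattr__(
            self, "index_of", {s: i for i, s in enumerate(self.symbols)}
        )

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def residues(self) -> str:
        """The 25 residue letters (everything except PAD)."""
        return "".join(self.symbols[1:])


DEFAULT_ALPHABET = Alphabet()

_RESIDUE_SET = frozenset(RESIDUE_LETTERS)


def clean_sequence(raw: str) -> str:
    """Normalize a raw sequence string to the residue alphabet.

    Uppercases, strips whitespace, and maps any character outside the 25
    residue letters (gaps ``-``/``.``, stops ``*``, ambiguity codes such
    as ``J``) to ``X``. Substitutions are logged with a count.

    Raises
    ------
    ValueError
        If the cleaned sequence is empty.
    """
    out = []
    n_subst = 0
    for ch in raw.upper():
        if ch.isspace():
            continue
        if ch in _RESIDUE_SET:
            out.append(ch)
        else:
            out.append("X")
            n_subst += 1
    if not out:
        raise ValueError("sequence empty after cleaning")
    if n_subst:
        logger.debug("clean_sequence: %d non-standard characters mapped to X", n_subst)
    return "".join(out)


def encode(residues: str, alphabet: Alphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """Encode a cleaned sequence into token indices (each in 1..25)."""
    if not residues:
        raise ValueError("cannot encode an empty sequence")
    try:
        idx = np.fromiter(
            (alphabet.index_of[ch] for ch in residues), dtype=np.int64, count=len(residues)
        )
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not in alphabet") from None
    if (idx == PAD_INDEX).any():
        raise ValueError("PAD symbol present in a cleaned sequence")
    return idx


def decode(tokens: np.ndarray | list[int], alphabet: Alphabet = DEFAULT_ALPHABET) -> str:
    """Inverse of :func:`encode`; PAD tokens decode to the PAD symbol."""
    return "".join(alphabet.symbols[int(t)] for t in tokens)
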