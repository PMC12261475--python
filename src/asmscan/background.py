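"""Background amino-acid frequency tables.

The bundled default reproduces the residue composition of
UniProtKB/Swiss-Prot (release statistics, rounded to 4 decimals and
renormalized); it drives the random prepadding of short training
sequences and the sampling of background negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .alphabet import DEFAULT_ALPHABET, Alphabet


@dataclass(frozen=True)
class BackgroundFreqTable:
    """Residue letter -> probability map (sums to 1)."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        probs = self.probabilities
        if not probs:
            raise ValueError("empty frequency table")
        bad = [r for r in probs if r not in DEFAULT_ALPHABET.index_of or r == "-"]
        if bad:
            raise ValueError(f"unknown residues in frequency table: {bad}")
        vals = np.array(list(probs.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("negative probability in frequency table")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {vals.sum():.12f}, expected 1")

    def as_arrays(self, alphabet: Alphabet = DEFAULT_ALPHABET) -> tuple[np.ndarray, np.ndarray]:
        """Token indices and probabilities, aligned, for vectorized sampling."""
        letters = sorted(self.probabilities)
        idx = np.array([alphabet.index_of[r] for r in letters], dtype=np.int64)
        p = np.array([self.probabilities[r] for r in letters], dtype=float)
        return idx, p

    def sample_tokens(self, n: int, rng: np.random.Generator,
                      alphabet: Alphabet = DEFAULT_ALPHABET) -> np.ndarray:
        """Draw ``n`` residue tokens i.i.d. from the table (never PAD)."""
        idx, p = self.as_arrays(alphabet)
        return rng.choice(idx, size=n, p=p)


def _normalize(probs: dict[str, float]) -> dict[str, float]:
    total = sum(probs.values())
    return {r: v / total for r, v in probs.items()}


def load_freq_table(path: str | Path) -> BackgroundFreqTable:
    """Read a 2-column TSV (residue, probability); renormalizes exactly to 1."""
    probs: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        probs[parts[0]] = float(parts[1])
    return BackgroundFreqTable(_normalize(probs))


def swissprot_background() -> BackgroundFreqTable:
    """The bundled Swiss-Prot residue frequency table."""
    ref = resources.files("asmscan").joinpath("data/swissprot_freqs.tsv")
    with resources.as_file(ref) as path:
        return load_freq_table(path)


def uniform_background() -> BackgroundFreqTable:
    """Uniform distribution over the 20 canonical residues."""
    return BackgroundFreqTable({r: 1 / 20 for r in "ACDEFGHIKLMNPQRSTVWY"})
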