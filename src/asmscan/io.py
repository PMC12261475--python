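"""FASTA input/output for protein sequence records."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .alphabet import clean_sequence


@dataclass(frozen=True)
class SequenceRecord:
    """An identified protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    the full header is kept in ``description``. ``source`` optionally tags
    the dataset split or motif family the record belongs to.
    """

    id: str
    residues: str
    description: str = ""
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, source: str | None = None) -> list[SequenceRecord]:
    """Read a (plain or gzipped) FASTA file into cleaned records.

    Order is preserved. Sequences are normalized with
    :func:`~asmscan.alphabet.clean_sequence`.

    Raises
    ------
    ValueError
        On malformed FASTA (sequence data before any header), an empty
        sequence, or a duplicate id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        # reject leading junk before the first header with a line number
        pos = handle.tell()
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before any FASTA header"
                )
            break
        handle.seek(pos)
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {entry.id!r}")
            seen.add(entry.id)
            raw = str(entry.seq)
            if not raw.strip():
                raise ValueError(f"{path}: entry {entry.id!r} has an empty sequence")
            records.append(
                SequenceRecord(
                    id=entry.id,
                    residues=clean_sequence(raw),
                    description=entry.description,
                    source=source,
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA with 60-character sequence lines."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with _open_maybe_gzip(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio)
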