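"""Scan sequences with the cross-validation ensemble.

The k fold models act as one *combined* scorer: every 40-residue window
of a sequence is scored by every fold in inference mode, the k
probabilities are averaged per window, and the per-sequence score is the
maximum window mean (max-pooling over the sequence). Ties between
windows with equal means are broken toward the smallest start.
Coordinates are 0-based half-open internally and 1-based inclusive in
output tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import encode
from .io import SequenceRecord, read_fasta
from .model import BiLSTMClassifier, FoldModel, ModelConfig
from .windows import Window, make_windows

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class WindowScore:
    """Per-window fold probabilities and their mean."""

    parent_id: str
    start: int
    end: int
    fold_probs: tuple[float, ...]
    mean_prob: float


@dataclass(frozen=True)
class SequenceHit:
    """Max-pooled per-sequence result."""

    parent_id: str
    length: int
    best_start: int
    best_end: int
    max_prob: float
    detected: bool
    n_windows: int
    fold_probs: tuple[float, ...]


@dataclass(frozen=True)
class MotifShift:
    """Best-window position relative to an annotated motif.

    ``begin_shift`` = window start - motif start (negative: the window
    begins before the motif); ``end_shift`` = window end - motif end
    (positive: the window extends past the motif); ``coverage`` is the
    fraction of motif residues inside the best window.
    """

    begin_shift: int
    end_shift: int
    coverage: float


def combine(fold_probs: Sequence[float]) -> float:
    """Arithmetic mean of the fold probabilities."""
    probs = np.asarray(list(fold_probs), dtype=float)
    if probs.size == 0:
        raise ValueError("cannot combine an empty probability list")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("fold probabilities must lie in [0, 1]")
    return float(probs.mean())


class CombinedModel:
    """The ensemble of cross-validation fold models acting as one scorer."""

    def __init__(self, folds: Sequence[FoldModel], model_config: ModelConfig):
        if len(folds) < 2:
            raise ValueError("a combined model needs at least 2 folds")
        self.folds = list(folds)
        self.model_config = model_config

    @property
    def k(self) -> int:
        return len(self.folds)

    def predict_fold_probs(self, tokens: np.ndarray) -> np.ndarray:
        """Per-fold probabilities for a (n, 40) window batch -> (k, n)."""
        return np.stack([f.model.predict_proba(tokens) for f in self.folds])

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path, extra: dict | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for fold in self.folds:
            fold.model.save(directory / f"fold_{fold.fold_index}.npz")
        manifest = {
            "model_config": self.model_config.__dict__,
            "k_folds": self.k,
            "fold_indices": [f.fold_index for f in self.folds],
            "val_metrics": [f.val_metrics for f in self.folds],
            **(extra or {}),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CombinedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = ModelConfig(**manifest["model_config"])
        val_metrics = manifest.get("val_metrics") or [{}] * len(manifest["fold_indices"])
        folds = []
        for i, vm in zip(manifest["fold_indices"], val_metrics):
            model = BiLSTMClassifier.load(directory / f"fold_{i}.npz", config)
            folds.append(FoldModel(fold_index=i, model=model, val_metrics=vm))
        return cls(folds, config)


def _score_windows(
    model: CombinedModel, windows: list[Window]
) -> list[WindowScore]:
    tokens = np.stack([w.tokens for w in windows])
    fold_probs = model.predict_fold_probs(tokens)  # (k, n)
    means = fold_probs.mean(axis=0)
    return [
        WindowScore(
            parent_id=w.parent_id,
            start=w.start,
            end=w.end,
            fold_probs=tuple(float(p) for p in fold_probs[:, j]),
            mean_prob=float(means[j]),
        )
        for j, w in enumerate(windows)
    ]


def _max_pool(
    record: SequenceRecord, scores: list[WindowScore], threshold: float
) -> SequenceHit:
    means = np.array([s.mean_prob for s in scores])
    best = int(np.argmax(means))  # argmax returns the first (leftmost) maximum
    s = scores[best]
    return SequenceHit(
        parent_id=record.id,
        length=len(record),
        best_start=s.start,
        best_end=s.end,
        max_prob=s.mean_prob,
        detected=bool(s.mean_prob >= threshold),
        n_windows=len(scores),
        fold_probs=s.fold_probs,
    )


def scan_sequence(
    model: CombinedModel,
    record: SequenceRecord,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[WindowScore], SequenceHit]:
    """Score every window of one sequence and max-pool."""
    tokens = encode(record.residues)
    windows = make_windows(record, tokens, size=model.model_config.window_len)
    scores = _score_windows(model, windows)
    return scores, _max_pool(record, scores, threshold)


def scan_records(
    model: CombinedModel,
    records: Sequence[SequenceRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SequenceHit]:
    """Scan many records, batching all windows through each fold once."""
    all_windows: list[Window] = []
    counts: list[int] = []
    for rec in records:
        ws = make_windows(rec, encode(rec.residues), size=model.model_config.window_len)
        all_windows.extend(ws)
        counts.append(len(ws))
    scored = _score_windows(model, all_windows)
    hits = []
    pos = 0
    for rec, n in zip(records, counts):
        hits.append(_max_pool(rec, scored[pos : pos + n], threshold))
        pos += n
    return hits


def hits_to_table(hits: Iterable[SequenceHit]) -> pd.DataFrame:
    """Hit table with 1-based inclusive best-window coordinates."""
    rows = [
        {
            "seq_id": h.parent_id,
            "length": h.length,
            "best_start": h.best_start + 1,
            "best_end": h.best_end,
            "max_prob": h.max_prob,
            "detected": h.detected,
            "fold_probs": ",".join(f"{p:.6f}" for p in h.fold_probs),
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "length", "best_start", "best_end",
            "max_prob", "detected", "fold_probs",
        ],
    )


def scan_fasta(
    model: CombinedModel,
    fasta_path: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Scan a FASTA file; one row per sequence, input order preserved."""
    records = read_fasta(fasta_path)
    hits = scan_records(model, records, threshold=threshold)
    table = hits_to_table(hits)
    logger.info(
        "scanned %d sequences from %s: %d with hits above threshold %.3f",
        len(records), fasta_path, int(table["detected"].sum()), threshold,
    )
    return table


def locate_motif_shift(
    hit: SequenceHit, motif_start: int, motif_end: int
) -> MotifShift:
    """Best-window shifts and coverage against a known motif interval
    (0-based half-open coordinates)."""
    if not 0 <= motif_start < motif_end <= hit.length:
        raise ValueError(
            f"invalid motif interval [{motif_start}, {motif_end}) "
            f"for sequence of length {hit.length}"
        )
    overlap = max(
        0, min(hit.best_end, motif_end) - max(hit.best_start, motif_start)
    )
    return MotifShift(
        begin_shift=hit.best_start - motif_start,
        end_shift=hit.best_end - motif_end,
        coverage=overlap / (motif_end - motif_start),
    )
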