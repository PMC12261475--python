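"""High-level modelling interface.

`AmyloidMotifModel` holds the labeled training sequences and the
architecture/optimization configuration; `fit()` runs the k-fold
cross-validation training and returns an `AmyloidMotifResults` carrying
the combined (ensemble) scorer, per-fold validation metrics, and the
scanning, evaluation, and embedding methods.

Example
-------
>>> from asmscan import AmyloidMotifModel
>>> model = AmyloidMotifModel.from_fasta("positives.fasta", "negatives.fasta")
>>> res = model.fit()
>>> print(res.summary())
>>> hits = res.scan_fasta("proteome.fasta", threshold=0.5)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import encode
from .background import BackgroundFreqTable, swissprot_background
from .embedding import EmbeddingMatrix, best_window_embeddings
from .io import SequenceRecord, read_fasta
from .metrics import (
    ScoredLabelSet,
    auroc,
    average_precision,
    recall_at_fpr,
    roc_curve,
)
from .model import (
    FoldModel,
    ModelConfig,
    TrainConfig,
    count_trainable_params,
    cv_split,
    train_fold,
)
from .scanner import (
    DEFAULT_THRESHOLD,
    CombinedModel,
    SequenceHit,
    hits_to_table,
    scan_records,
)
from .windows import prepad_random

__all__ = ["AmyloidMotifModel", "AmyloidMotifResults"]


def _encode_training(
    records: Sequence[SequenceRecord],
    freqs: BackgroundFreqTable,
    rng: np.random.Generator,
    window_len: int,
) -> np.ndarray:
    """Encode and random-prepad training sequences to the window length.

    Any training sequence shorter than the window (positive or negative)
    is prepadded with background residues; over-length input is an error
    because training items are motifs or 40-mers, not whole proteins.
    """
    out = np.empty((len(records), window_len), dtype=np.int64)
    for i, rec in enumerate(records):
        out[i] = prepad_random(encode(rec.residues), freqs, rng, target_len=window_len)
    return out


class AmyloidMotifModel:
    """Trainable detector of amyloid signaling motifs.

    Parameters
    ----------
    positives : motif sequences (up to 40 residues each).
    negatives : background sequences (up to 40 residues each).
    model_config, train_config : architecture and optimization settings.
    background : frequency table for random prepadding (Swiss-Prot
        composition by default).
    """

    def __init__(
        self,
        positives: Sequence[SequenceRecord],
        negatives: Sequence[SequenceRecord],
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        background: BackgroundFreqTable | None = None,
    ):
        if not positives or not negatives:
            raise ValueError("both positive and negative training sets are required")
        self.positives = list(positives)
        self.negatives = list(negatives)
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.background = background or swissprot_background()

    @classmethod
    def from_fasta(
        cls,
        positives_path: str | Path,
        negatives_path: str | Path,
        **kwargs,
    ) -> "AmyloidMotifModel":
        return cls(
            read_fasta(positives_path, source="pos"),
            read_fasta(negatives_path, source="neg"),
            **kwargs,
        )

    def fit(self, k: int = 6) -> "AmyloidMotifResults":
        """Train the k-fold cross-validation ensemble.

        Pads are sampled once per run from the seeded stream; each fold
        model is initialized and trained reproducibly from the run seed
        and its fold index.
        """
        mc, tc = self.model_config, self.train_config
        ss = np.random.SeedSequence([tc.seed, 0xA5])
        pad_ss, _ = ss.spawn(2)

        def encode_all(rng: np.random.Generator) -> np.ndarray:
            X_pos = _encode_training(self.positives, self.background, rng, mc.window_len)
            X_neg = _encode_training(self.negatives, self.background, rng, mc.window_len)
            return np.concatenate([X_pos, X_neg])

        X = encode_all(np.random.default_rng(pad_ss))
        y = np.concatenate(
            [np.ones(len(self.positives)), np.zeros(len(self.negatives))]
        )
        ids = [r.id for r in self.positives] + [r.id for r in self.negatives]
        index_of = {rid: i for i, rid in enumerate(ids)}

        pos_ids = [r.id for r in self.positives]
        neg_ids = [r.id for r in self.negatives]
        splits = cv_split(pos_ids, neg_ids, k=k, seed=tc.seed)

        folds: list[FoldModel] = []
        for fold_index, (train_ids, val_ids) in enumerate(splits):
            tr = np.array([index_of[i] for i in train_ids])
            va = np.array([index_of[i] for i in val_ids])
            repad = None
            if tc.resample_pads_per_epoch:
                repad = lambda rng, tr=tr: encode_all(rng)[tr]  # noqa: E731
            folds.append(
                train_fold(
                    X[tr], y[tr], X[va], y[va],
                    model_config=mc, train_config=tc,
                    fold_index=fold_index,
                    train_ids=train_ids, val_ids=val_ids,
                    repad=repad,
                )
            )
        combined = CombinedModel(folds, mc)
        return AmyloidMotifResults(
            combined=combined,
            model_config=mc,
            train_config=tc,
            n_positives=len(self.positives),
            n_negatives=len(self.negatives),
        )


@dataclass
class AmyloidMotifResults:
    """Fitted ensemble with its diagnostics and downstream operations."""

    combined: CombinedModel
    model_config: ModelConfig
    train_config: TrainConfig
    n_positives: int = 0
    n_negatives: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def fold_models(self) -> list[FoldModel]:
        return self.combined.folds

    # -- reporting -----------------------------------------------------

    def fold_table(self) -> pd.DataFrame:
        rows = []
        for f in self.fold_models:
            rows.append({"fold": f.fold_index, **f.val_metrics})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        mc = self.model_config
        lines = [
            "Amyloid signaling motif detector — cross-validation ensemble",
            "=" * 62,
            f"folds: {self.combined.k}    window length: {mc.window_len}",
            f"architecture: embed {mc.embed_dim} | bi-recurrent {mc.bi_units}/dir "
            f"| uni-recurrent {mc.uni_units} | sigmoid out | dropout {mc.dropout:.0%}",
            f"trainable parameters per fold: {count_trainable_params(mc)}",
            f"training set: {self.n_positives} positives, {self.n_negatives} negatives",
            f"optimizer: Adam lr={self.train_config.learning_rate} "
            f"batch={self.train_config.batch_size} epochs={self.train_config.epochs}",
            "-" * 62,
        ]
        table = self.fold_table()
        if not table.empty:
            lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
            means = table.drop(columns="fold").mean()
            lines.append("-" * 62)
            lines.append(
                "mean: " + "  ".join(f"{k}={v:.4f}" for k, v in means.items())
            )
        return "\n".join(lines)

    # -- scanning ------------------------------------------------------

    def scan(
        self, records: Sequence[SequenceRecord], threshold: float = DEFAULT_THRESHOLD
    ) -> list[SequenceHit]:
        return scan_records(self.combined, records, threshold=threshold)

    def scan_fasta(
        self, path: str | Path, threshold: float = DEFAULT_THRESHOLD
    ) -> pd.DataFrame:
        from .scanner import scan_fasta

        return scan_fasta(self.combined, path, threshold=threshold)

    def max_pooled_scores(self, records: Sequence[SequenceRecord]) -> np.ndarray:
        """Per-sequence combined scores (max over window means)."""
        return np.array([h.max_prob for h in self.scan(records)])

    # -- evaluation ----------------------------------------------------

    def evaluate(
        self,
        pos_records: Sequence[SequenceRecord],
        neg_records: Sequence[SequenceRecord],
        fpr_targets: Sequence[float] = (1e-1, 1e-2, 1e-3),
    ) -> dict[str, float]:
        """AP, AUROC, and interpolated Recall@FPR of max-pooled scores."""
        pos = self.max_pooled_scores(pos_records)
        neg = self.max_pooled_scores(neg_records)
        data = ScoredLabelSet.from_pos_neg(pos, neg)
        curve = roc_curve(data)
        out = {
            "ap": average_precision(data),
            "auroc": auroc(data),
        }
        for f in fpr_targets:
            out[f"recall_at_fpr_{f:g}"] = recall_at_fpr(curve, f)
        return out

    # -- embeddings ----------------------------------------------------

    def embeddings(
        self,
        records: Sequence[SequenceRecord],
        groups: Mapping[str, str] | None = None,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> EmbeddingMatrix:
        return best_window_embeddings(
            self.combined, records, groups=groups, threshold=threshold
        )

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        self.combined.save(
            directory,
            extra={
                "train_config": {
                    k: v for k, v in self.train_config.__dict__.items()
                },
                "n_positives": self.n_positives,
                "n_negatives": self.n_negatives,
            },
        )

    @classmethod
    def load(cls, directory: str | Path) -> "AmyloidMotifResults":
        import json

        combined = CombinedModel.load(directory)
        manifest = json.loads((Path(directory) / "manifest.json").read_text())
        tc = TrainConfig(**manifest.get("train_config", {}))
        return cls(
            combined=combined,
            model_config=combined.model_config,
            train_config=tc,
            n_positives=manifest.get("n_positives", 0),
            n_negatives=manifest.get("n_negatives", 0),
        )
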