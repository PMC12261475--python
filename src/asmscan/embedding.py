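"""Model introspection: penultimate-layer embeddings of best windows,
2-D projection, and per-group retention summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import encode
from .io import SequenceRecord
from .model import FoldModel
from .scanner import DEFAULT_THRESHOLD, CombinedModel
from .windows import make_windows


@dataclass
class EmbeddingMatrix:
    """Ensemble embeddings of each sequence's best-scoring window.

    ``vectors`` is (n, k_folds * uni_units) when fold embeddings are
    concatenated (the default) or (n, uni_units) when averaged.
    """

    ids: list[str]
    vectors: np.ndarray
    detected: np.ndarray
    group: list[str]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.vectors.shape[0] != n or len(self.detected) != n or len(self.group) != n:
            raise ValueError("inconsistent row counts in EmbeddingMatrix")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding vectors must be finite")


def penultimate_embedding(fold: FoldModel, tokens: np.ndarray) -> np.ndarray:
    """Final-state output of the unidirectional layer for one window.

    Inference mode (dropout inactive), so this equals the representation
    at the final dropout position; entries lie in (-1, 1) (tanh state
    times a sigmoid gate).
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.ndim != 1:
        raise ValueError("penultimate_embedding takes a single window")
    return fold.model.penultimate(tokens[None, :])[0]


def best_window_embeddings(
    model: CombinedModel,
    records: Sequence[SequenceRecord],
    groups: Mapping[str, str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    average_folds: bool = False,
) -> EmbeddingMatrix:
    """Embed each record's best-scoring window with every fold.

    Per-fold penultimate vectors are concatenated (k * uni_units columns)
    unless ``average_folds`` is set. The detected flag uses the combined
    max-pooled probability against ``threshold``.
    """
    all_tokens = []
    counts = []
    for rec in records:
        ws = make_windows(rec, encode(rec.residues), size=model.model_config.window_len)
        all_tokens.extend(w.tokens for w in ws)
        counts.append(len(ws))
    stacked = np.stack(all_tokens)
    fold_probs = model.predict_fold_probs(stacked)  # (k, n_windows)
    means = fold_probs.mean(axis=0)

    best_tokens = np.empty((len(records), model.model_config.window_len), dtype=np.int64)
    detected = np.empty(len(records), dtype=bool)
    pos = 0
    for i, n in enumerate(counts):
        j = pos + int(np.argmax(means[pos : pos + n]))
        best_tokens[i] = stacked[j]
        detected[i] = means[j] >= threshold
        pos += n

    per_fold = np.stack([f.model.penultimate(best_tokens) for f in model.folds])
    vectors = per_fold.mean(axis=0) if average_folds else np.concatenate(list(per_fold), axis=1)
    ids = [rec.id for rec in records]
    group = [
        (groups or {}).get(rec.id, rec.source or "all") for rec in records
    ]
    return EmbeddingMatrix(ids=ids, vectors=vectors, detected=detected, group=group)


def project_2d(
    matrix: EmbeddingMatrix,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """UMAP projection of the embedding matrix to 2-D (row order kept)."""
    n = len(matrix.ids)
    if n < n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} exceeds the {n} available rows; "
            "lower n_neighbors"
        )
    import umap  # heavy import deferred

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    coords = np.asarray(reducer.fit_transform(matrix.vectors), dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("projection produced non-finite coordinates")
    return coords


def retention_by_group(matrix: EmbeddingMatrix) -> pd.DataFrame:
    """Per-group detection fractions (retention rates)."""
    if not matrix.group:
        raise ValueError("no group labels present")
    df = pd.DataFrame({"group": matrix.group, "detected": matrix.detected})
    out = (
        df.groupby("group", sort=True)["detected"]
        .agg(n="size", fraction_detected="mean")
        .reset_index()
    )
    out["fraction_detected"] = out["fraction_detected"].astype(float)
    return out


def plot_embedding(matrix: EmbeddingMatrix, coords: np.ndarray, path=None):
    """Scatter the 2-D projection: dots where the motif was detected,
    crosses where it was not, colored by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    groups = sorted(set(matrix.group))
    cmap = plt.get_cmap("tab10")
    group_arr = np.array(matrix.group)
    for gi, g in enumerate(groups):
        for det, marker, suffix in ((True, "o", "detected"), (False, "x", "not detected")):
            sel = (group_arr == g) & (matrix.detected == det)
            if sel.any():
                ax.scatter(
                    coords[sel, 0], coords[sel, 1],
                    marker=marker, s=18, color=cmap(gi % 10),
                    label=f"{g} ({suffix})",
                )
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
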