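"""Synthetic motif-family benchmark.

Generates data with the statistical structure of an amyloid-signaling-
motif study: several motif *families*, each defined by conserved anchor
residues at fixed relative positions over a family-specific residue
background; test motifs cut exactly, with 5/10-residue envelopes, and
implanted into 100-residue terminal domains; and background negatives
(40-mers approximating the whole protein space, and motif-free domains).

Two deliberate statistical choices make the benchmark behave like real
amyloid signaling sequences without copying any real sequence content:
anchors sit at fixed *relative* positions so family identity survives
length variation, and all families share a compositional bias toward
amyloidogenic residues (Q, N, G, S, Y) so that a model trained on some
families can generalize to held-out novel families, the way bacterial
motif training transfers to remotely related fungal motifs.

All randomness flows from one root seed through named substreams, so
regeneration is byte-identical and components can be re-drawn
independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import decode
from .background import BackgroundFreqTable, swissprot_background
from .io import SequenceRecord, write_fasta

AMYLOID_RESIDUE_POOL = "QNGSY"

#: fraction of amyloid-pool mass blended into family backgrounds
AMYLOID_BIAS = 0.4


def amyloid_biased_background(bias: float = AMYLOID_BIAS) -> BackgroundFreqTable:
    """Swiss-Prot frequencies blended with a uniform Q/N/G/S/Y component."""
    base = swissprot_background().probabilities
    probs = {r: (1 - bias) * p for r, p in base.items()}
    for r in AMYLOID_RESIDUE_POOL:
        probs[r] = probs.get(r, 0.0) + bias / len(AMYLOID_RESIDUE_POOL)
    total = sum(probs.values())
    return BackgroundFreqTable({r: p / total for r, p in probs.items()})


@dataclass(frozen=True)
class MotifFamilySpec:
    """A synthetic motif family.

    ``anchors`` is a list of (relative position in [0,1), residue
    distribution) pairs; each distribution concentrates >= 0.8 of its
    mass on one dominant residue. Non-anchor positions are drawn from
    ``background``.
    """

    family_id: str
    length_range: tuple[int, int]
    anchors: tuple[tuple[float, dict[str, float]], ...]
    background: BackgroundFreqTable

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi <= 40:
            raise ValueError("length_range must satisfy 1 <= min <= max <= 40")
        if len(self.anchors) > lo:
            raise ValueError("more anchors than the minimum motif length")
        for frac, dist in self.anchors:
            if not 0.0 <= frac < 1.0:
                raise ValueError("anchor positions must be fractions in [0, 1)")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("anchor distribution must be normalized")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def random_family(
    family_id: str,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (21, 40),
    n_anchors: int = 6,
    dominant_mass: float = 0.9,
    anchor_pool: str = AMYLOID_RESIDUE_POOL,
    background: BackgroundFreqTable | None = None,
) -> MotifFamilySpec:
    """Draw a family spec: anchor positions spread over the motif, each
    with a dominant residue from the shared amyloid-prone pool."""
    background = background or amyloid_biased_background()
    fracs = np.sort(rng.uniform(0.0, 1.0, size=n_anchors))
    others = [r for r in "ACDEFGHIKLMNPQRSTVWY"]
    anchors = []
    for frac in fracs:
        dom = anchor_pool[rng.integers(len(anchor_pool))]
        rest = [r for r in others if r != dom]
        dist = {dom: dominant_mass}
        spread = (1.0 - dominant_mass) / len(rest)
        for r in rest:
            dist[r] = spread
        anchors.append((float(frac), dist))
    return MotifFamilySpec(
        family_id=family_id,
        length_range=length_range,
        anchors=tuple(anchors),
        background=background,
    )


def _anchor_indices(spec: MotifFamilySpec, length: int) -> list[int]:
    """Scale relative anchor positions to a drawn length; resolve
    collisions to distinct indices by probing rightward (cyclically)."""
    used: set[int] = set()
    out = []
    for frac, _ in spec.anchors:
        idx = int(frac * length)
        while idx in used:
            idx = (idx + 1) % length
        used.add(idx)
        out.append(idx)
    return out


def _draw_from(dist: dict[str, float], rng: np.random.Generator) -> str:
    letters = sorted(dist)
    p = np.array([dist[r] for r in letters])
    return letters[rng.choice(len(letters), p=p / p.sum())]


def sample_motif(
    spec: MotifFamilySpec, rng: np.random.Generator, name: str | None = None
) -> SequenceRecord:
    """Sample one motif: length uniform over the family range, anchors
    from their distributions, other positions from the background."""
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    residues = list(decode(spec.background.sample_tokens(length, rng)))
    for idx, (_, dist) in zip(_anchor_indices(spec, length), spec.anchors):
        residues[idx] = _draw_from(dist, rng)
    return SequenceRecord(
        id=name or f"{spec.family_id}_motif",
        residues="".join(residues),
        source=spec.family_id,
    )


def sample_motifs(
    spec: MotifFamilySpec, n: int, rng: np.random.Generator, prefix: str = ""
) -> list[SequenceRecord]:
    return [
        sample_motif(spec, rng, name=f"{prefix}{spec.family_id}_{i:04d}")
        for i in range(n)
    ]


def sample_background(
    n: int,
    length: int | tuple[int, int],
    freqs: BackgroundFreqTable,
    rng: np.random.Generator,
    prefix: str = "bg",
) -> list[SequenceRecord]:
    """Draw ``n`` background records with i.i.d. residues from ``freqs``.

    ``length`` is either a fixed value or an inclusive (min, max) range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(length, tuple):
        lo, hi = length
        if not 1 <= lo <= hi:
            raise ValueError("invalid length range")
        lengths = rng.integers(lo, hi + 1, size=n)
    else:
        if length < 1:
            raise ValueError("length must be >= 1")
        lengths = np.full(n, length, dtype=int)
    return [
        SequenceRecord(
            id=f"{prefix}_{i:05d}",
            residues=decode(freqs.sample_tokens(int(L), rng)),
        )
        for i, L in enumerate(lengths)
    ]


def implant_motif(
    motif: SequenceRecord,
    rng: np.random.Generator,
    domain_length: int = 100,
    side: str = "N",
    freqs: BackgroundFreqTable | None = None,
) -> tuple[SequenceRecord, int, int]:
    """Embed a motif into a background-filled domain of fixed length.

    The insertion offset is uniform over the feasible offsets whose motif
    midpoint falls in the half of the domain nearest the chosen terminus
    ("N" or "C"). Returns the domain record and the motif's 0-based
    half-open coordinates within it.
    """
    freqs = freqs or swissprot_background()
    L = len(motif)
    if L > domain_length:
        raise ValueError(f"motif of length {L} exceeds domain length {domain_length}")
    feasible = domain_length - L
    half = domain_length // 2 - L // 2
    if side == "N":
        lo, hi = 0, max(0, min(feasible, half))
    elif side == "C":
        lo, hi = min(feasible, max(0, half)), feasible
    else:
        raise ValueError("side must be 'N' or 'C'")
    start = int(rng.integers(lo, hi + 1))
    bg = decode(freqs.sample_tokens(domain_length, rng))
    residues = bg[:start] + motif.residues + bg[start + L :]
    rec = SequenceRecord(
        id=f"{motif.id}|dom", residues=residues, source=motif.source
    )
    return rec, start, start + L


def make_envelope(
    context: SequenceRecord, start: int, end: int, e: int
) -> SequenceRecord:
    """Cut the motif interval out of its context with ``e`` flanking
    residues on each side, clipped at the context boundaries. ``e = 0``
    returns exactly the motif."""
    if e < 0:
        raise ValueError("envelope size must be >= 0")
    if not 0 <= start < end <= len(context):
        raise ValueError(f"invalid interval [{start}, {end}) in context of length {len(context)}")
    lo = max(0, start - e)
    hi = min(len(context), end + e)
    return SequenceRecord(
        id=f"{context.id}|env{e}",
        residues=context.residues[lo:hi],
        source=context.source,
    )


@dataclass(frozen=True)
class SyntheticBenchmarkConfig:
    """Shape of the generated benchmark.

    Defaults mirror a desk-scale version of the study design: 8 training
    families of BASS-like motifs (21-40 residues, 120 each), 2 held-out
    novel families, 20,000 background 40-mers for training, 100-residue
    domain contexts, and envelope sizes 0/5/10.
    """

    n_train_families: int = 8
    n_heldout_families: int = 2
    motifs_per_family: int = 120
    test_motifs_per_family: int = 40
    n_negative_windows: int = 20000
    n_test_negative_windows: int = 2000
    n_negative_domains: int = 500
    domain_length: int = 100
    envelope_sizes: tuple[int, ...] = (0, 5, 10)
    terminus_side: str = "N"
    length_range: tuple[int, int] = (21, 40)
    n_anchors: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_train_families, self.n_heldout_families,
            self.motifs_per_family, self.test_motifs_per_family,
            self.n_negative_windows, self.n_test_negative_windows,
            self.n_negative_domains,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all benchmark counts must be >= 1")
        if self.domain_length < 40:
            raise ValueError("domain_length must be >= 40")
        if self.terminus_side not in ("N", "C"):
            raise ValueError("terminus_side must be 'N' or 'C'")


@dataclass
class BenchmarkBundle:
    """In-memory benchmark dataset plus its manifest."""

    config: SyntheticBenchmarkConfig
    train_families: list[MotifFamilySpec]
    heldout_families: list[MotifFamilySpec]
    train_pos: list[SequenceRecord]
    train_neg: list[SequenceRecord]
    test_envelopes: dict[str, dict[int, list[SequenceRecord]]]
    test_domains: dict[str, list[SequenceRecord]]
    annotations: dict[str, list[tuple[str, int, int, str]]]
    test_neg_windows: list[SequenceRecord]
    neg_domains: list[SequenceRecord]
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTA splits, annotation TSVs (1-based inclusive
        coordinates), and a manifest with per-file checksums."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files: dict[str, Path] = {}

        def dump(name: str, records: list[SequenceRecord]) -> None:
            path = out / f"{name}.fasta"
            write_fasta(records, path)
            files[name] = path

        dump("train_pos", self.train_pos)
        dump("train_neg", self.train_neg)
        for split, by_env in self.test_envelopes.items():
            for e, recs in by_env.items():
                dump(f"test_{split}_env{e}", recs)
        for split, recs in self.test_domains.items():
            dump(f"test_{split}_dom", recs)
        dump("test_neg_windows", self.test_neg_windows)
        dump("neg_domains", self.neg_domains)

        for split, rows in self.annotations.items():
            path = out / f"test_{split}_dom.annotations.tsv"
            lines = ["seq_id\tmotif_start\tmotif_end\tfamily"]
            lines += [f"{sid}\t{s + 1}\t{e}\t{fam}" for sid, s, e, fam in rows]
            path.write_text("\n".join(lines) + "\n")
            files[f"{split}_annotations"] = path

        manifest = dict(self.manifest)
        manifest["files"] = {
            name: {
                "path": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for name, p in sorted(files.items())
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        files["manifest"] = manifest_path
        return files


def build_benchmark(config: SyntheticBenchmarkConfig) -> BenchmarkBundle:
    """Generate the full benchmark bundle, reproducibly from the seed.

    Training and held-out family ids are disjoint; held-out ("novel")
    families never contribute training motifs. Every test motif also
    appears implanted in a domain context (with its true coordinates
    recorded) and cut with each configured envelope size.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ["families", "train_motifs", "train_negatives",
             "test_motifs", "implants", "test_negatives", "negative_domains"],
            root.spawn(7),
        )
    }
    bg = swissprot_background()

    fam_rng = streams["families"]
    train_families = [
        random_family(
            f"fam{i:02d}", fam_rng,
            length_range=config.length_range, n_anchors=config.n_anchors,
        )
        for i in range(config.n_train_families)
    ]
    heldout_families = [
        random_family(
            f"novel{i:02d}", fam_rng,
            length_range=config.length_range, n_anchors=config.n_anchors,
        )
        for i in range(config.n_heldout_families)
    ]

    train_pos = [
        rec
        for spec in train_families
        for rec in sample_motifs(spec, config.motifs_per_family, streams["train_motifs"], prefix="tr_")
    ]
    train_neg = sample_background(
        config.n_negative_windows, 40, bg, streams["train_negatives"], prefix="pb40"
    )

    test_sets = {
        "same": [
            rec
            for spec in train_families
            for rec in sample_motifs(spec, config.test_motifs_per_family, streams["test_motifs"], prefix="ts_")
        ],
        "novel": [
            rec
            for spec in heldout_families
            for rec in sample_motifs(spec, config.test_motifs_per_family, streams["test_motifs"], prefix="ts_")
        ],
    }

    test_envelopes: dict[str, dict[int, list[SequenceRecord]]] = {}
    test_domains: dict[str, list[SequenceRecord]] = {}
    annotations: dict[str, list[tuple[str, int, int, str]]] = {}
    imp_rng = streams["implants"]
    for split, motifs in test_sets.items():
        test_envelopes[split] = {e: [] for e in config.envelope_sizes}
        test_domains[split] = []
        annotations[split] = []
        for motif in motifs:
            domain, start, end = implant_motif(
                motif, imp_rng,
                domain_length=config.domain_length,
                side=config.terminus_side, freqs=bg,
            )
            test_domains[split].append(domain)
            annotations[split].append((domain.id, start, end, motif.source or ""))
            for e in config.envelope_sizes:
                test_envelopes[split][e].append(make_envelope(domain, start, end, e))

    test_neg_windows = sample_background(
        config.n_test_negative_windows, 40, bg, streams["test_negatives"], prefix="pb40t"
    )
    neg_domains = sample_background(
        config.n_negative_domains, config.domain_length, bg,
        streams["negative_domains"], prefix="nlreff",
    )

    manifest = {
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in config.__dict__.items()
        },
        "train_family_ids": [f.family_id for f in train_families],
        "heldout_family_ids": [f.family_id for f in heldout_families],
        "counts": {
            "train_pos": len(train_pos),
            "train_neg": len(train_neg),
            "test_same": len(test_sets["same"]),
            "test_novel": len(test_sets["novel"]),
            "test_neg_windows": len(test_neg_windows),
            "neg_domains": len(neg_domains),
        },
    }
    return BenchmarkBundle(
        config=config,
        train_families=train_families,
        heldout_families=heldout_families,
        train_pos=train_pos,
        train_neg=train_neg,
        test_envelopes=test_envelopes,
        test_domains=test_domains,
        annotations=annotations,
        test_neg_windows=test_neg_windows,
        neg_domains=neg_domains,
        manifest=manifest,
    )
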