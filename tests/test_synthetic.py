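import json

import numpy as np
import pytest
from scipy import stats

from asmscan.background import swissprot_background, uniform_background
from asmscan.io import SequenceRecord, read_fasta
from asmscan.synthetic import (
    MotifFamilySpec,
    SyntheticBenchmarkConfig,
    amyloid_biased_background,
    build_benchmark,
    implant_motif,
    make_envelope,
    random_family,
    sample_background,
    sample_motif,
    sample_motifs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def degenerate_family(residue="G", positions=(0.1, 0.5, 0.9)):
    """A family whose anchors force one residue with probability 1."""
    return MotifFamilySpec(
        family_id="deg",
        length_range=(21, 40),
        anchors=tuple((p, {residue: 1.0}) for p in positions),
        background=swissprot_background(),
    )


class TestSampleBackground:
    def test_shapes_and_lengths(self, rng):
        recs = sample_background(10, 40, swissprot_background(), rng)
        assert len(recs) == 10
        assert all(len(r) == 40 for r in recs)

    def test_length_range(self, rng):
        recs = sample_background(200, (11, 30), swissprot_background(), rng)
        lengths = {len(r) for r in recs}
        assert lengths <= set(range(11, 31))
        assert min(lengths) <= 13 and max(lengths) >= 28

    def test_uniform_frequencies_converge(self, rng):
        recs = sample_background(2500, 40, uniform_background(), rng)
        joined = "".join(r.residues for r in recs)
        counts = np.array([joined.count(a) for a in "ACDEFGHIKLMNPQRSTVWY"])
        freqs = counts / counts.sum()
        assert np.abs(freqs - 0.05).max() < 0.01

    def test_same_seed_identical(self):
        a = sample_background(5, 40, swissprot_background(), np.random.default_rng(3))
        b = sample_background(5, 40, swissprot_background(), np.random.default_rng(3))
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            sample_background(0, 40, swissprot_background(), rng)
        with pytest.raises(ValueError):
            sample_background(1, (10, 5), swissprot_background(), rng)


class TestSampleMotif:
    def test_degenerate_anchor_always_present(self, rng):
        spec = degenerate_family("G")
        for i in range(50):
            motif = sample_motif(spec, rng)
            L = len(motif)
            for frac in (0.1, 0.5, 0.9):
                assert motif.residues[int(frac * L)] == "G"

    def test_lengths_cover_range_approximately_uniformly(self, rng):
        spec = degenerate_family()
        lengths = [len(sample_motif(spec, rng)) for _ in range(1000)]
        lo, hi = spec.length_range
        observed = np.bincount(lengths, minlength=hi + 1)[lo : hi + 1]
        assert (observed > 0).all()
        assert stats.chisquare(observed).pvalue > 0.01

    def test_family_tag_recorded(self, rng):
        assert sample_motif(degenerate_family(), rng).source == "deg"

    def test_disjoint_anchor_families_are_more_similar_within(self, rng):
        fam_a = degenerate_family("G", positions=(0.1, 0.3, 0.5, 0.7, 0.9))
        fam_b = MotifFamilySpec(
            family_id="b",
            length_range=(25, 25),
            anchors=tuple((p, {"W": 1.0}) for p in (0.1, 0.3, 0.5, 0.7, 0.9)),
            background=swissprot_background(),
        )
        fam_a = MotifFamilySpec(
            family_id="a",
            length_range=(25, 25),
            anchors=fam_a.anchors,
            background=swissprot_background(),
        )

        def identity(x, y):
            return np.mean([a == b for a, b in zip(x.residues, y.residues)])

        sa = sample_motifs(fam_a, 20, rng)
        sb = sample_motifs(fam_b, 20, rng)
        within = np.mean([identity(x, y) for x in sa for y in sa if x.id != y.id])
        between = np.mean([identity(x, y) for x in sa for y in sb])
        assert within > between

    def test_more_anchors_than_min_length_is_error(self):
        with pytest.raises(ValueError, match="anchors"):
            MotifFamilySpec(
                family_id="x",
                length_range=(2, 10),
                anchors=tuple((p, {"G": 1.0}) for p in (0.1, 0.4, 0.8)),
                background=swissprot_background(),
            )


class TestRandomFamily:
    def test_anchor_distributions_have_dominant_residue(self, rng):
        spec = random_family("f", rng, n_anchors=6)
        assert spec.n_anchors == 6
        for _, dist in spec.anchors:
            assert max(dist.values()) >= 0.8
            assert abs(sum(dist.values()) - 1.0) < 1e-9

    def test_biased_background_enriches_amyloid_pool(self):
        base = swissprot_background().probabilities
        biased = amyloid_biased_background().probabilities
        for r in "QNGSY":
            assert biased[r] > base[r]
        assert abs(sum(biased.values()) - 1.0) < 1e-9


class TestImplantMotif:
    def test_domain_contains_motif_at_reported_interval(self, rng):
        motif = SequenceRecord(id="m", residues="W" * 25, source="fam")
        domain, s, e = implant_motif(motif, rng, domain_length=100)
        assert len(domain) == 100
        assert (e - s) == 25
        assert domain.residues[s:e] == motif.residues

    def test_domain_equal_to_motif_length_spans_all(self, rng):
        motif = SequenceRecord(id="m", residues="W" * 40)
        domain, s, e = implant_motif(motif, rng, domain_length=40)
        assert (s, e) == (0, 40)
        assert domain.residues == motif.residues

    @pytest.mark.parametrize("side", ["N", "C"])
    def test_intervals_feasible_and_biased_to_terminus(self, rng, side):
        motif = SequenceRecord(id="m", residues="W" * 25)
        mids = []
        for _ in range(1000):
            _, s, e = implant_motif(motif, rng, domain_length=100, side=side)
            assert 0 <= s < e <= 100
            mids.append((s + e) / 2)
        if side == "N":
            assert max(mids) <= 50 + 13
        else:
            assert min(mids) >= 50 - 13

    def test_motif_longer_than_domain_is_error(self, rng):
        with pytest.raises(ValueError):
            implant_motif(SequenceRecord(id="m", residues="W" * 50), rng, domain_length=40)


class TestMakeEnvelope:
    def test_zero_envelope_is_motif(self):
        ctx = SequenceRecord(id="d", residues="A" * 20 + "W" * 25 + "A" * 55)
        env = make_envelope(ctx, 20, 45, 0)
        assert env.residues == "W" * 25

    def test_envelope_interval_arithmetic(self):
        ctx = SequenceRecord(id="d", residues="".join("AW"[20 <= i < 45] for i in range(100)))
        env = make_envelope(ctx, 20, 45, 5)
        assert len(env) == 35
        assert env.residues == ctx.residues[15:50]

    def test_left_clipping_at_origin(self):
        ctx = SequenceRecord(id="d", residues="W" * 25 + "A" * 75)
        env = make_envelope(ctx, 0, 25, 10)
        assert env.residues == ctx.residues[0:35]

    def test_invalid_interval_is_error(self):
        ctx = SequenceRecord(id="d", residues="A" * 50)
        with pytest.raises(ValueError):
            make_envelope(ctx, 30, 20, 5)


SMALL_CONFIG = SyntheticBenchmarkConfig(
    n_train_families=2,
    n_heldout_families=1,
    motifs_per_family=10,
    test_motifs_per_family=5,
    n_negative_windows=50,
    n_test_negative_windows=20,
    n_negative_domains=10,
    seed=7,
)


class TestBuildBenchmark:
    def test_counts_match_manifest(self):
        bench = build_benchmark(SMALL_CONFIG)
        counts = bench.manifest["counts"]
        assert counts["train_pos"] == 20 == len(bench.train_pos)
        assert counts["train_neg"] == 50
        assert counts["test_same"] == 10
        assert counts["test_novel"] == 5
        assert len(bench.test_domains["same"]) == 10
        assert all(len(bench.test_envelopes["same"][e]) == 10 for e in (0, 5, 10))

    def test_train_and_heldout_family_ids_disjoint(self):
        bench = build_benchmark(SMALL_CONFIG)
        train_ids = {f.family_id for f in bench.train_families}
        heldout_ids = {f.family_id for f in bench.heldout_families}
        assert train_ids.isdisjoint(heldout_ids)
        train_sources = {r.source for r in bench.train_pos}
        assert train_sources == train_ids

    def test_domain_annotation_matches_envelope_zero(self):
        bench = build_benchmark(SMALL_CONFIG)
        for split in ("same", "novel"):
            domains = {r.id: r for r in bench.test_domains[split]}
            env0 = {r.id: r for r in bench.test_envelopes[split][0]}
            for sid, s, e, fam in bench.annotations[split]:
                dom = domains[sid]
                assert dom.residues[s:e] == env0[f"{sid}|env0"].residues
                assert dom.source == fam

    def test_written_files_are_reproducible_and_consistent(self, tmp_path):
        bench = build_benchmark(SMALL_CONFIG)
        files1 = bench.write(tmp_path / "a")
        files2 = build_benchmark(SMALL_CONFIG).write(tmp_path / "b")
        for name in files1:
            assert files1[name].read_bytes() == files2[name].read_bytes()
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        train_pos = read_fasta(tmp_path / "a" / "train_pos.fasta")
        assert len(train_pos) == manifest["counts"]["train_pos"]
        ann = (tmp_path / "a" / "test_same_dom.annotations.tsv").read_text().splitlines()
        assert ann[0] == "seq_id\tmotif_start\tmotif_end\tfamily"
        assert len(ann) == 1 + manifest["counts"]["test_same"]

    def test_different_seed_changes_content(self):
        import dataclasses

        a = build_benchmark(SMALL_CONFIG)
        b = build_benchmark(dataclasses.replace(SMALL_CONFIG, seed=8))
        assert a.train_pos[0].residues != b.train_pos[0].residues

    def test_infeasible_config_is_error(self):
        with pytest.raises(ValueError):
            SyntheticBenchmarkConfig(n_heldout_families=0)
        with pytest.raises(ValueError):
            SyntheticBenchmarkConfig(domain_length=30)
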