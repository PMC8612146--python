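import numpy as np
import pytest
from Bio.Seq import Seq

from oracles import merge_oracle
from phagetf import homologs, libraries
from phagetf import simulate as sim
from phagetf.io_formats import GenomeRecord, GenomicInterval, ProteinRecord
from phagetf.simulate import back_translate, revcomp


def _random_genome(length, rng, gid="g"):
    return GenomeRecord(
        genome_id=gid, sequence="".join(rng.choice(list("ACGT"), length))
    )


def _hit(gid, s, e):
    return homologs.SearchHit(
        query_id="q",
        interval=GenomicInterval(gid, s, e),
        frame=1, raw_score=100.0, bitscore=30.0, evalue=1e-9,
    )


class TestTranslatedSearch:
    def test_planted_exact_match_found(self):
        rng = np.random.default_rng(10)
        query = ProteinRecord(protein_id="q", sequence=libraries.random_protein(60, rng))
        insert = back_translate(query.sequence, 0.5, rng)
        genome_seq = (
            "".join(rng.choice(list("ACGT"), 3000))
            + insert
            + "".join(rng.choice(list("ACGT"), 3000))
        )
        genome = GenomeRecord(genome_id="g", sequence=genome_seq)
        hits = homologs.translated_search(genome, [query], 1e-5)
        assert len(hits) >= 1
        best = min(hits, key=lambda h: h.evalue)
        assert best.evalue < 1e-20
        # the hit interval covers the implanted ORF body
        assert best.interval.start >= 3000 - 3
        assert best.interval.end <= 3000 + len(insert)

    def test_minus_strand_hit_round_trips(self):
        rng = np.random.default_rng(11)
        query = ProteinRecord(protein_id="q", sequence=libraries.random_protein(60, rng))
        insert = revcomp(back_translate(query.sequence, 0.5, rng))
        genome_seq = (
            "".join(rng.choice(list("ACGT"), 2001))
            + insert
            + "".join(rng.choice(list("ACGT"), 2000))
        )
        genome = GenomeRecord(genome_id="g", sequence=genome_seq)
        hits = homologs.translated_search(genome, [query], 1e-5)
        best = min(hits, key=lambda h: h.evalue)
        assert best.interval.strand == "-"
        sub = revcomp(genome.sequence[best.interval.start:best.interval.end])
        translated = str(Seq(sub).translate(table=11))
        assert translated in query.sequence or query.sequence in translated

    def test_random_genomes_rarely_hit(self):
        rng = np.random.default_rng(12)
        query = ProteinRecord(protein_id="q", sequence=libraries.random_protein(60, rng))
        false_pos = 0
        for i in range(20):
            genome = _random_genome(20_000, rng, f"g{i}")
            if homologs.translated_search(genome, [query], 1e-5):
                false_pos += 1
        assert false_pos <= 1

    def test_empty_query_library_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError):
            homologs.translated_search(_random_genome(1000, rng), [], 1e-5)


class TestMergeLoci:
    def test_overlap_chain_merges(self):
        merged = homologs.merge_loci(
            [_hit("g", 100, 200), _hit("g", 150, 300), _hit("g", 400, 500)]
        )
        assert [(m.start, m.end) for m in merged] == [(100, 300), (400, 500)]

    def test_disjoint_unchanged(self):
        merged = homologs.merge_loci([_hit("g", 0, 10), _hit("g", 20, 30)])
        assert [(m.start, m.end) for m in merged] == [(0, 10), (20, 30)]

    def test_bookended_intervals_fuse(self):
        merged = homologs.merge_loci([_hit("g", 0, 100), _hit("g", 100, 200)])
        assert [(m.start, m.end) for m in merged] == [(0, 200)]

    def test_matches_covered_position_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            n = rng.integers(1, 20)
            raw = []
            for _ in range(n):
                s = int(rng.integers(0, 500))
                raw.append((s, s + int(rng.integers(1, 80))))
            merged = homologs.merge_loci([_hit("g", s, e) for s, e in raw])
            assert [(m.start, m.end) for m in merged] == merge_oracle(raw)

    def test_mixed_genomes_rejected(self):
        with pytest.raises(ValueError):
            homologs.merge_loci([_hit("g1", 0, 10), _hit("g2", 0, 10)])


class TestExtendLocus:
    def test_padding(self):
        iv = homologs.extend_locus(GenomicInterval("g", 9_700, 10_000), 500, 50_000)
        assert (iv.start, iv.end) == (9_200, 10_500)

    def test_clamped_at_origin(self):
        iv = homologs.extend_locus(GenomicInterval("g", 200, 400), 5_000, 50_000)
        assert (iv.start, iv.end) == (0, 5_400)

    def test_zero_pad_identity(self):
        iv = GenomicInterval("g", 5, 10)
        assert homologs.extend_locus(iv, 0, 100) == iv

    def test_interval_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            homologs.extend_locus(GenomicInterval("g", 90, 120), 10, 100)


class TestExtractOrfProtein:
    def test_minimal_orf(self):
        genome = GenomeRecord(genome_id="g", sequence="CCATGAAATAACC")
        orfs = homologs.extract_orf_protein(
            genome, GenomicInterval("g", 0, 13), min_len_aa=1
        )
        assert any(o.protein == "MK" and o.strand == "+" for o in orfs)

    def test_reverse_strand_symmetry(self):
        rng = np.random.default_rng(15)
        prot = libraries.random_protein(40, rng)
        orf_nt = back_translate(prot, 0.5, rng)
        pad1 = "".join(rng.choice(list("ACGT"), 100))
        pad2 = "".join(rng.choice(list("ACGT"), 100))
        fwd = GenomeRecord(genome_id="f", sequence=pad1 + orf_nt + pad2)
        rev = GenomeRecord(genome_id="r", sequence=revcomp(pad1 + orf_nt + pad2))
        span_f = GenomicInterval("f", 0, fwd.length_bp)
        span_r = GenomicInterval("r", 0, rev.length_bp)
        fwd_orfs = {o.protein for o in
                    homologs.extract_orf_protein(fwd, span_f, 30)}
        rev_orfs = {o.protein for o in
                    homologs.extract_orf_protein(rev, span_r, 30)}
        # the implant is recovered (possibly extended to an earlier
        # in-frame start codon in the flanking sequence)
        assert any(o.endswith(prot[1:]) for o in fwd_orfs)
        assert fwd_orfs == rev_orfs

    def test_min_length_filter(self):
        # 20-aa ORF dropped at a 50-aa floor
        rng = np.random.default_rng(16)
        prot = libraries.random_protein(20, rng)
        seq = "CC" + back_translate(prot, 0.5, rng) + "CC"
        genome = GenomeRecord(genome_id="g", sequence=seq)
        span = GenomicInterval("g", 0, len(seq))
        assert homologs.extract_orf_protein(genome, span, 50) == []
        found = homologs.extract_orf_protein(genome, span, 20)
        assert any(o.protein == prot for o in found)


class TestReciprocalFilter:
    def test_identical_candidate_passes_with_identity_one(self):
        rng = np.random.default_rng(17)
        library = libraries.whib_library()
        cand = homologs.OrfCandidate(
            GenomicInterval("g", 0, 303), "+", library[0].sequence
        )
        best, qid, ident, evalue, passed = homologs.reciprocal_filter(
            [cand], library, 1e-5
        )
        assert passed and best is cand
        assert qid == library[0].protein_id
        assert ident == pytest.approx(1.0)

    def test_random_candidate_fails(self):
        rng = np.random.default_rng(18)
        cand = homologs.OrfCandidate(
            GenomicInterval("g", 0, 303), "+", libraries.random_protein(100, rng)
        )
        *_, passed = homologs.reciprocal_filter([cand], libraries.whib_library(), 1e-5)
        assert not passed

    def test_best_matching_candidate_retained(self):
        rng = np.random.default_rng(19)
        library = libraries.lsr2_library()
        good = homologs.OrfCandidate(
            GenomicInterval("g", 0, 348), "+", library[1].sequence
        )
        junk = homologs.OrfCandidate(
            GenomicInterval("g", 400, 703), "+", libraries.random_protein(100, rng)
        )
        best, qid, *_ , passed = homologs.reciprocal_filter(
            [junk, good], library, 1e-5
        )
        assert passed and best is good and qid == library[1].protein_id

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            homologs.reciprocal_filter([], [], 1e-5)


class TestRunDetection:
    def test_recovers_truth_with_copies(self):
        cfg = sim.SimulationConfig(
            n_clusters=3, genomes_per_cluster=2, cluster_gc=[0.5, 0.55, 0.6],
            implant_plan=[sim.ImplantSpec(0, "whiB-like", 1, 0.2),
                          sim.ImplantSpec(1, "whiB-like", 2, 0.25)],
            seed=21,
        )
        genomes, meta, truth = sim.simulate_collection(cfg)
        table, summary = homologs.run_detection(
            genomes, libraries.whib_library(), metadata=meta
        )
        detected = table.groupby("genome_id")["locus_id"].count().to_dict()
        expected = {
            gid: len(t.implants)
            for gid, t in truth.genomes.items() if t.implants
        }
        assert detected == expected
        assert summary["n_carriers"] == len(expected)
        assert summary["by_cluster"]["C"]["carriers"] == 0

    def test_deterministic_locus_table(self):
        cfg = sim.SimulationConfig(
            n_clusters=1, genomes_per_cluster=2, cluster_gc=[0.5],
            implant_plan=[sim.ImplantSpec(0, "lsr2-like", 1, 0.3)],
            seed=22,
        )
        genomes, _, _ = sim.simulate_collection(cfg)
        t1, _ = homologs.run_detection(genomes, libraries.lsr2_library())
        t2, _ = homologs.run_detection(genomes, libraries.lsr2_library())
        assert t1.to_csv() == t2.to_csv()

    def test_detected_orf_matches_truth_interval(self):
        cfg = sim.SimulationConfig(
            n_clusters=1, genomes_per_cluster=1, cluster_gc=[0.5],
            implant_plan=[sim.ImplantSpec(0, "whiB-like", 1, 0.1)],
            seed=23,
        )
        genomes, _, truth = sim.simulate_collection(cfg)
        table, _ = homologs.run_detection(genomes, libraries.whib_library())
        im = truth.genomes[genomes[0].genome_id].implants[0]
        row = table.iloc[0]
        # called ORF overlaps the implant and has the right strand
        assert row.orf_start < im.interval.end and im.interval.start < row.orf_end
        assert row.strand == im.strand


def test_six_frame_translation_covers_implant():
    rng = np.random.default_rng(24)
    prot = libraries.random_protein(50, rng)
    nt = back_translate(prot, 0.5, rng)
    seq = "A" + nt  # shift into frame +2
    frames = dict(homologs.six_frame_translations(seq))
    assert prot in frames[2]
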