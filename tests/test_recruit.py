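"""Translated homology search: frames, seeds, extensions, recruitment."""

import pytest

from mscout._util import blosum62
from mscout.errors import InputError
from mscout.recruit import (
    AlignmentHit,
    Seed,
    extend_hit,
    find_seed_hits,
    recruit_reads,
    sixframe_translate,
    ungapped_extend,
    word_neighborhood,
)
from mscout.simulate import (
    ReadRecord,
    ReadSet,
    SimConfig,
    evolve_homolog,
    simulate_genome,
    simulate_reads,
)


class TestSixFrame:
    def test_forward_frame(self):
        assert sixframe_translate("ATGAAA")[1] == "MK"

    def test_reverse_frame_is_revcomp_translation(self):
        assert sixframe_translate("ATGAAA")[-1] == "FH"  # translate("TTTCAT")

    def test_n_translates_to_x(self):
        assert sixframe_translate("ATGNAA")[1] == "MX"

    def test_empty_input_gives_six_empty_frames(self):
        frames = sixframe_translate("")
        assert set(frames) == {1, 2, 3, -1, -2, -3}
        assert all(v == "" for v in frames.values())

    def test_partial_codons_dropped(self):
        frames = sixframe_translate("ATGAAAC")
        assert frames[1] == "MK"  # trailing C dropped
        assert len(frames[2]) == 2  # "TGAAAC" -> 2 codons


class TestSeeds:
    def test_identical_tryptophan_word_seeds(self):
        seeds = find_seed_hits("WWW", {1: "GGWWWGG"})
        assert Seed(0, 1, 2) in seeds
        assert 3 * blosum62("W", "W") == 33  # self-score comfortably over 11

    def test_weak_word_does_not_seed(self):
        assert find_seed_hits("AAA", {1: "DDD"}) == []

    def test_empty_frames_give_no_seeds(self):
        assert find_seed_hits("MKLV", {f: "" for f in (1, 2, 3, -1, -2, -3)}) == []

    def test_word_longer_than_query(self):
        assert find_seed_hits("MK", {1: "MKLV"}, word_size=3) == []

    def test_empty_query_rejected(self):
        with pytest.raises(InputError):
            find_seed_hits("", {1: "MKLV"})


class TestExtension:
    def test_identity_alignment_spans_frame(self):
        q = "MKWVLLRRAGDE"
        frames = {1: q}
        hit = extend_hit(Seed(0, 1, 0), q, frames, nt_len=3 * len(q))
        self_score = sum(blosum62(c, c) for c in q)
        assert hit.score == self_score
        assert hit.query_span == (0, len(q))
        assert hit.pident == 100.0

    def test_single_mismatch_score_is_hand_sum(self):
        left = "WWWWWWWWWW"
        right = "YYYYYYYYYY"
        q = left + "A" + right
        s = left + "D" + right
        hit = extend_hit(Seed(0, 1, 0), q, {1: s}, nt_len=3 * len(s))
        expected = (
            sum(blosum62(c, c) for c in left + right) + blosum62("A", "D")
        )
        assert hit.score == expected
        assert hit.mismatches == 1

    def test_extension_never_scores_below_seed_word(self):
        q = "MKW"
        s = "DDMKWDD"
        seed_score = sum(blosum62(a, b) for a, b in zip("MKW", "MKW"))
        hit = extend_hit(Seed(0, 1, 2), q, {1: s}, nt_len=21)
        assert hit.score >= seed_score

    def test_ungapped_xdrop_agrees_on_exact_match(self):
        q = "MKWVLLR"
        score, qs, qe, ss, se = ungapped_extend(q, "AA" + q + "AA", 0, 2)
        assert (qs, qe) == (0, len(q)) and (ss, se) == (2, 2 + len(q))
        assert score >= sum(blosum62(c, c) for c in q)

    def test_reverse_frame_nt_span_maps_to_forward_strand(self):
        from mscout._util import revcomp

        prot = "MKWVLLRR"
        nt = "".join({"M": "ATG", "K": "AAA", "W": "TGG", "V": "GTT",
                      "L": "CTG", "R": "AGA"}[c] for c in prot)
        rc = revcomp(nt)
        frames = sixframe_translate(rc)
        assert frames[-1] == prot
        hit = extend_hit(Seed(0, -1, 0), prot, frames, nt_len=len(rc))
        assert hit.subject_nt_span == (0, len(rc))


def _paired_reads(seqs):
    reads = []
    from mscout._util import revcomp

    for i, (a, b) in enumerate(seqs):
        reads.append(ReadRecord(f"p{i}/1", f"p{i}/2", a, "I" * len(a)))
        reads.append(ReadRecord(f"p{i}/2", f"p{i}/1", b, "I" * len(b)))
    return ReadSet("male", reads)


class TestRecruit:
    def test_mate_closure_includes_homology_free_mates(self, rng):
        from mscout._util import random_dna

        orf_nt = "ATGAAATGGGTTCTGCTGAGAAGAGCTGGTGATGAA" * 4
        prot = sixframe_translate(orf_nt)[1]
        junk = random_dna(rng, len(orf_nt))
        rs = _paired_reads([(orf_nt, junk)])
        rec = recruit_reads({"q": prot}, rs, min_score=35)
        assert {r.read_id for r in rec.reads} == {"p0/1", "p0/2"}
        assert rec.n_direct == 1 and rec.n_mates == 1

    def test_no_shared_seed_recruits_nothing(self, rng):
        from mscout._util import random_dna

        rs = _paired_reads([(random_dna(rng, 90), random_dna(rng, 90))])
        rec = recruit_reads({"q": "W" * 40}, rs, min_score=20)
        assert len(rec.reads) == 0

    def test_no_queries_is_an_error(self, rng):
        rs = _paired_reads([("ACGT" * 20, "ACGT" * 20)])
        with pytest.raises(InputError):
            recruit_reads({}, rs)

    def test_score_threshold_monotonicity(self, small_sim):
        cfg, genome, male, _ = small_sim
        query = evolve_homolog(genome.orf_protein, 0.6, 3)
        loose = {r.read_id for r in recruit_reads({"q": query}, male, min_score=30).reads}
        strict = {r.read_id for r in recruit_reads({"q": query}, male, min_score=60).reads}
        assert strict <= loose

    def test_divergent_query_recruits_orf_reads(self):
        """A query at ~52% identity to the planted protein still recruits
        >= 90% of the reads overlapping the ORF (checked against truth
        metadata over several seeds)."""
        total_true = total_found = 0
        for seed in range(3):
            cfg = SimConfig(seed=seed)
            genome = simulate_genome(cfg)
            male = simulate_reads(genome, cfg, "male")
            query = evolve_homolog(genome.orf_protein, 0.52, seed + 100)
            rec = recruit_reads({"q": query}, male)
            got = {r.read_id for r in rec.reads}
            gs, ge = genome.gene_span
            true = [
                r.read_id for r in male
                if r.source_haplotype == "M_hap"
                and min(r.end, ge) - max(r.start, gs) >= 60
            ]
            total_true += len(true)
            total_found += sum(1 for rid in true if rid in got)
        assert total_true > 300
        assert total_found / total_true >= 0.90


class TestHitReporting:
    def test_hits_tsv_layout(self, tmp_path, rng):
        from mscout._util import random_dna
        from mscout.recruit import hits_to_tsv

        orf_nt = "ATGAAATGGGTTCTGCTGAGAAGAGCTGGTGATGAA" * 4
        prot = sixframe_translate(orf_nt)[1]
        rs = _paired_reads([(orf_nt, random_dna(rng, len(orf_nt)))])
        rec = recruit_reads({"q": prot}, rs, min_score=35, keep_hits=True)
        assert rec.hits and rec.hits[0].query_id == "q"
        out = tmp_path / "hits.tsv"
        hits_to_tsv(rec.hits, out, query_lengths={"q": len(prot)},
                    db_len_nt=rs.total_bases, include_evalue=True)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t")[0] == "qseqid"
        assert len(lines) == 1 + len(rec.hits)
        row = lines[1].split("\t")
        assert row[0] == "q" and float(row[-1]) >= 0  # evalue column

    def test_iterative_recruitment_extends_query_set(self, small_sim):
        cfg, genome, male, _ = small_sim
        query = evolve_homolog(genome.orf_protein, 0.6, 3)
        once = recruit_reads({"q": query}, male, iterations=1)
        twice = recruit_reads({"q": query}, male, iterations=2)
        assert {r.read_id for r in once.reads} <= {r.read_id for r in twice.reads}
        assert len(twice.queries_used) > len(once.queries_used)
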