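"""Chromosome Quotient: arithmetic, classification, and hit counting
against truth metadata."""

import logging

import pytest
from hypothesis import given, strategies as st

from mscout.cq import (
    AUTOSOMAL_LIKE,
    MALE_SPECIFIC,
    NO_DATA,
    UNDETERMINED,
    HitParams,
    chromosome_quotient,
    classify_linkage,
    count_hits,
    count_hits_multi,
)
from mscout.errors import InputError
from mscout.simulate import ReadRecord, ReadSet, SimConfig, simulate_genome, simulate_reads
from mscout._util import random_dna, revcomp

import numpy as np


def _readset(seqs, sex="male"):
    reads = []
    for i, s in enumerate(seqs):
        reads.append(ReadRecord(f"r{i}/1", f"r{i}/2", s, "I" * len(s)))
        reads.append(ReadRecord(f"r{i}/2", f"r{i}/1", revcomp(s), "I" * len(s)))
    return ReadSet(sex, reads)


class TestQuotient:
    def test_zero_female_hits(self):
        r = chromosome_quotient(0, 175)
        assert r.cq == 0.0 and r.cq_rounded == 0.0

    def test_autosomal_ratio_rounds_to_two_decimals(self):
        r = chromosome_quotient(260, 276)
        assert r.cq_rounded == 0.94

    def test_small_quotients_stay_below_printed_bound(self):
        assert chromosome_quotient(1, 116).cq < 0.01
        assert chromosome_quotient(1, 139).cq < 0.01
        assert chromosome_quotient(1, 116).display_cq() == "<0.01"

    def test_no_male_hits_is_reported_not_raised(self):
        r = chromosome_quotient(5, 0)
        assert r.cq is None and r.classification == NO_DATA

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            chromosome_quotient(-1, 5)

    def test_normalizer_scales_quotient(self):
        r = chromosome_quotient(50, 100, normalizer=2.0)
        assert r.cq == 1.0 and r.normalized

    @given(
        f=st.integers(min_value=1, max_value=10_000),
        m=st.integers(min_value=1, max_value=10_000),
    )
    def test_label_swap_reciprocity(self, f, m):
        assert chromosome_quotient(f, m).cq * chromosome_quotient(m, f).cq == pytest.approx(1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "f,m,expected",
        [
            (0, 175, MALE_SPECIFIC),
            (260, 276, AUTOSOMAL_LIKE),
            (0, 5, NO_DATA),
            (50, 100, AUTOSOMAL_LIKE),
            (40, 100, UNDETERMINED),  # CQ 0.4: neither specific nor autosomal
            (300, 100, UNDETERMINED),
        ],
    )
    def test_linkage_labels(self, f, m, expected):
        assert classify_linkage(chromosome_quotient(f, m)) == expected

    def test_min_male_hits_floor(self):
        assert classify_linkage(chromosome_quotient(0, 19)) == NO_DATA
        assert classify_linkage(chromosome_quotient(0, 20)) == MALE_SPECIFIC


class TestCountHits:
    def test_exact_substrings_all_hit(self, rng):
        ref = random_dna(rng, 500)
        seqs = [ref[i * 40 : i * 40 + 100] for i in range(10)]
        rs = ReadSet("male", [
            ReadRecord(f"x{i}/1", f"x{i}/1", s, "I" * len(s)) for i, s in enumerate(seqs)
        ])
        assert count_hits(rs, ref) == 10

    def test_unrelated_reads_no_hits(self, rng):
        ref = random_dna(rng, 500)
        other = random_dna(rng, 2000)
        rs = ReadSet("male", [
            ReadRecord(f"x{i}/1", f"x{i}/1", other[i * 150 : i * 150 + 100], "I" * 100)
            for i in range(8)
        ])
        assert count_hits(rs, ref) == 0

    def test_empty_read_set_warns_and_returns_zero(self, caplog):
        rs = ReadSet("male", [])
        with caplog.at_level(logging.WARNING):
            assert count_hits(rs, "ACGT" * 30) == 0
        assert any("empty read set" in m for m in caplog.messages)

    def test_non_dna_reference_rejected(self):
        rs = _readset(["ACGT" * 30])
        with pytest.raises(InputError):
            count_hits(rs, "MKLV" * 10)

    def test_counts_match_truth_metadata(self):
        """Reads simulated at 1% error: hits equal the truth count of
        reads overlapping the reference sufficiently, within 2% summed
        over 10 seeds."""
        got_total = truth_total = 0
        params = HitParams()
        for seed in range(10):
            cfg = SimConfig(
                seed=seed, autosome_length=2500, n_autosomal_loci=1,
                m_locus_length=1500, planted_orf_length=600, depth=8.0,
            )
            g = simulate_genome(cfg)
            reads = simulate_reads(g, cfg, "male")
            name, s, e = g.autosomal_loci[0]
            ref = g.haplotypes["autosome_hap1"][s:e]
            got_total += count_hits(reads, ref, params)
            need = params.min_read_coverage * cfg.read_length
            truth_total += sum(
                1 for r in reads
                if r.source_haplotype in ("autosome_hap1", "autosome_hap2")
                and min(r.end, e) - max(r.start, s) >= need
            )
        assert truth_total > 200
        assert abs(got_total - truth_total) <= 0.02 * truth_total

    def test_min_identity_monotonicity(self, small_sim):
        _, genome, male, _ = small_sim
        name, s, e = genome.autosomal_loci[0]
        ref = genome.haplotypes["autosome_hap1"][s:e]
        counts = [
            count_hits(male, ref, HitParams(min_identity=mi))
            for mi in (0.90, 0.95, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_multi_reference_counts_match_single(self, small_sim):
        _, genome, male, _ = small_sim
        refs = {
            name: genome.haplotypes["autosome_hap1"][s:e]
            for name, s, e in genome.autosomal_loci
        }
        multi = count_hits_multi(male, refs)
        for name, seq in refs.items():
            assert multi[name] == count_hits(male, seq)


def test_cq_table_with_normalization(small_sim):
    from mscout.cq import cq_table

    cfg, genome, male, female = small_sim
    refs = {
        name: genome.haplotypes["autosome_hap1"][s:e]
        for name, s, e in genome.autosomal_loci
    }
    raw = cq_table(male, female, refs)
    norm = cq_table(male, female, refs, normalize=True)
    assert list(raw.columns) == [
        "seq_name", "seq_length", "female_hits", "male_hits", "CQ",
        "classification",
    ]
    # equal sequencing effort in both pools: normalization is ~ a no-op
    scale = male.total_bases / female.total_bases
    for r, n in zip(raw.to_dict("records"), norm.to_dict("records")):
        assert float(n["CQ"]) == pytest.approx(float(r["CQ"]) * scale, abs=0.011)
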