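"""Synthetic sex-specific sequencing data with a planted hemizygous M locus.

Culicine mosquitoes carry a dominant male-determining locus (the M locus)
on an otherwise homomorphic chromosome pair: males are Mm, females mm. A
male-determining gene planted on the M haplotype is therefore present in a
single copy in males and absent from females, which is exactly the signal
the Chromosome Quotient and homology-recruitment stages exploit. This
module builds such genomes, draws uniform-coverage paired-end reads from
them, and produces diverged protein homologs and omega-controlled codon
pairs for testing the downstream comparative analyses.

Coordinates in all truth metadata are 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._util import (
    DNA,
    SENSE_CODONS,
    CODON_TO_AA,
    derive_seed,
    preferred_substitutions,
    random_dna,
    revcomp,
    translate,
)
from .errors import ConfigurationError, InputError

PLACEHOLDER_QUALITY = "I"  # base qualities are never used downstream

MALE_HAPLOTYPES = ("autosome_hap1", "autosome_hap2", "M_hap", "m_hap")
FEMALE_HAPLOTYPES = ("autosome_hap1", "autosome_hap2", "m_hap", "m_hap")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated dataset.

    Defaults encode the conditions the downstream analyses are validated
    under: 30x per-haploid-copy coverage of 150 bp paired reads with a 1%
    per-base substitution error, an 816 nt planted open reading frame, and
    query homologs at 52% protein identity (the divergence observed between
    the two M-factor proteins known before the broader survey).
    """

    seed: int = 0
    autosome_length: int = 6000
    n_autosomal_loci: int = 3
    m_locus_length: int = 3000
    planted_orf_length: int = 816
    intron_length: int = 0
    depth: float = 30.0
    read_length: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.01
    target_protein_identity: float = 0.52
    omega: float = 0.25

    def validate(self) -> None:
        if self.planted_orf_length % 3 != 0:
            raise ConfigurationError("planted_orf_length must be a multiple of 3")
        if self.planted_orf_length < 9:
            raise ConfigurationError("planted_orf_length must be at least 9 nt")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigurationError("error_rate must satisfy 0 <= e < 0.5")
        if self.intron_length != 0 and self.intron_length < 4:
            raise ConfigurationError(
                "intron_length must be 0 or >= 4 (room for GT..AG)"
            )
        if not (0 < self.target_protein_identity <= 1):
            raise ConfigurationError("target_protein_identity must be in (0, 1]")
        if self.omega < 0:
            raise ConfigurationError("omega must be >= 0")
        if self.depth <= 0 or self.read_length < 20:
            raise ConfigurationError("depth must be > 0 and read_length >= 20")
        if self.insert_mean < self.read_length:
            raise ConfigurationError("insert_mean must be >= read_length")
        # gene region (ORF + intron + stop) plus margins must fit the M locus
        gene = self.planted_orf_length + self.intron_length + 3
        if gene + 200 > self.m_locus_length:
            raise ConfigurationError(
                "m_locus_length too small for the planted gene plus flanks"
            )
        if self.autosome_length < self.read_length or self.m_locus_length < self.read_length:
            raise ConfigurationError("haplotypes must be at least one read long")
        if self.n_autosomal_loci < 0:
            raise ConfigurationError("n_autosomal_loci must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SimConfig keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class GenomeTruth:
    """Ground-truth genomes plus planted feature coordinates."""

    haplotypes: dict[str, str]
    gene_span: tuple[int, int]  # on M_hap; includes the intron if present
    orf_cdna: str  # contiguous coding sequence, stop codon excluded
    intron_span: Optional[tuple[int, int]]  # on M_hap
    intron_codon_index: Optional[int]
    intron_phase: Optional[int]
    autosomal_loci: list[tuple[str, int, int]]  # (name, start, end) on the autosome

    @property
    def orf_protein(self) -> str:
        return translate(self.orf_cdna)

    def haplotypes_for_sex(self, sex: str) -> tuple[str, ...]:
        if sex == "male":
            return MALE_HAPLOTYPES
        if sex == "female":
            return FEMALE_HAPLOTYPES
        raise InputError(f"unknown sex label: {sex!r}")

    def locus_sequence(self, name: str) -> str:
        for lname, s, e in self.autosomal_loci:
            if lname == name:
                return self.haplotypes["autosome_hap1"][s:e]
        raise InputError(f"unknown autosomal locus: {name!r}")


@dataclass
class ReadRecord:
    read_id: str
    mate_id: str
    sequence: str
    quality: str
    # truth metadata (None when reads were loaded from plain FASTQ)
    source_haplotype: Optional[str] = None
    start: Optional[int] = None  # span on the source haplotype, forward coords
    end: Optional[int] = None
    strand: Optional[str] = None


@dataclass
class ReadSet:
    """A sex-labelled collection of paired reads with resolvable mates."""

    sex: str
    reads: list[ReadRecord] = field(default_factory=list)

    def __post_init__(self):
        self._by_id = {r.read_id: r for r in self.reads}

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def get(self, read_id: str) -> ReadRecord:
        return self._by_id[read_id]

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._by_id

    def mate(self, read_id: str) -> ReadRecord:
        return self._by_id[self._by_id[read_id].mate_id]

    @property
    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)

    def subset(self, read_ids: Iterable[str]) -> "ReadSet":
        wanted = set(read_ids)
        return ReadSet(self.sex, [r for r in self.reads if r.read_id in wanted])

    def validate(self) -> None:
        for r in self.reads:
            if r.mate_id not in self._by_id:
                raise InputError(f"unresolved mate {r.mate_id!r} for {r.read_id!r}")

    def write_fastq(self, path_r1, path_r2) -> None:
        """Write /1 reads to path_r1 and /2 reads to path_r2."""
        with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
            for r in self.reads:
                fh = f1 if r.read_id.endswith("/1") else f2
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq_pair(path_r1, path_r2, sex: str = "unknown") -> ReadSet:
    """Load paired FASTQ files written in the /1,/2 id-suffix dialect."""
    from Bio import SeqIO

    reads: list[ReadRecord] = []
    for path in (path_r1, path_r2):
        for rec in SeqIO.parse(str(path), "fastq"):
            rid = rec.id
            if rid.endswith("/1"):
                mate = rid[:-2] + "/2"
            elif rid.endswith("/2"):
                mate = rid[:-2] + "/1"
            else:
                raise InputError(f"read id {rid!r} lacks a /1 or /2 suffix")
            reads.append(
                ReadRecord(rid, mate, str(rec.seq).upper(), PLACEHOLDER_QUALITY * len(rec))
            )
    rs = ReadSet(sex, reads)
    rs.validate()
    return rs


def _random_orf(rng: np.random.Generator, n_nt: int) -> str:
    """A stop-free open reading frame of n_nt: ATG followed by sense codons."""
    n_codons = n_nt // 3
    codons = ["ATG"]
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    codons.extend(SENSE_CODONS[i] for i in idx)
    return "".join(codons)


def simulate_genome(config: SimConfig) -> GenomeTruth:
    """Build male/female haplotypes with a planted M-locus gene.

    The male genome is {autosome_hap1, autosome_hap2, M_hap, m_hap}; the
    female genome is {autosome_hap1, autosome_hap2, m_hap, m_hap}. The two
    autosomal haplotypes are identical (an inbred-line idealisation), so
    autosomal loci appear at twice haploid depth in both sexes while the
    planted gene on M_hap is hemizygous in males and absent in females.
    """
    config.validate()
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))

    autosome = random_dna(rng, config.autosome_length)
    m_hap = random_dna(rng, config.m_locus_length)
    backbone = random_dna(rng, config.m_locus_length)

    orf = _random_orf(rng, config.planted_orf_length)
    intron_span = None
    codon_index = None
    phase = None
    gene = orf
    if config.intron_length > 0:
        n_codons = config.planted_orf_length // 3
        # keep the intron away from the ORF ends so spliced anchors exist
        codon_index = int(rng.integers(8, max(9, n_codons - 8)))
        phase = int(rng.integers(1, 3))  # split a codon: phase 1 or 2
        cut = 3 * codon_index + phase
        intron = "GT" + random_dna(rng, config.intron_length - 4) + "AG"
        gene = orf[:cut] + intron + orf[cut:]
    gene = gene + "TAA"  # terminator after the recorded ORF span

    margin = 100
    pos = int(rng.integers(margin, config.m_locus_length - len(gene) - margin))
    M_hap = backbone[:pos] + gene + backbone[pos + len(gene):]
    gene_end = pos + len(gene) - 3  # exclude the stop codon from the span
    if config.intron_length > 0:
        cut = 3 * codon_index + phase
        intron_span = (pos + cut, pos + cut + config.intron_length)

    loci = []
    if config.n_autosomal_loci > 0:
        locus_len = min(600, config.autosome_length // (2 * config.n_autosomal_loci))
        stride = config.autosome_length // config.n_autosomal_loci
        for i in range(config.n_autosomal_loci):
            s = i * stride + (stride - locus_len) // 2
            loci.append((f"locus_{i + 1}", s, s + locus_len))

    return GenomeTruth(
        haplotypes={
            "autosome_hap1": autosome,
            "autosome_hap2": autosome,
            "M_hap": M_hap,
            "m_hap": m_hap,
        },
        gene_span=(pos, gene_end),
        orf_cdna=orf,
        intron_span=intron_span,
        intron_codon_index=codon_index,
        intron_phase=phase,
        autosomal_loci=loci,
    )


def simulate_reads(genome: GenomeTruth, config: SimConfig, sex: str = "male") -> ReadSet:
    """Draw uniform-coverage paired-end reads at ``depth`` per haploid copy.

    Because males carry a single M haplotype, M-locus positions receive
    half the coverage of autosomal positions — the asymmetry behind the
    Chromosome Quotient. Insert sizes are Normal(insert_mean, insert_sd)
    truncated to [read_length, haplotype length]; substitution errors are
    applied per base at ``error_rate``; no indel errors are modelled.
    """
    config.validate()
    haps = genome.haplotypes_for_sex(sex)
    rng = np.random.default_rng(derive_seed(config.seed, "reads", sex))
    rl = config.read_length
    reads: list[ReadRecord] = []
    pair_no = 0
    for copy_idx, hap in enumerate(haps):
        seq = genome.haplotypes[hap]
        L = len(seq)
        if rl > L:
            raise ConfigurationError(f"read_length {rl} exceeds {hap} length {L}")
        # fragments start uniformly in [0, L - insert]; normalising by the
        # start domain (not L) keeps interior per-base coverage at `depth`
        effective = max(L - config.insert_mean + 1, rl)
        n_pairs = int(round(config.depth * effective / (2 * rl)))
        inserts = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
        inserts = np.clip(np.rint(inserts).astype(int), rl, L)
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)
        flips = rng.random(n_pairs) < 0.5
        err = config.error_rate
        for k in range(n_pairs):
            ins = int(inserts[k])
            s = int(starts[k])
            frag = seq[s : s + ins]
            fwd = frag[:rl]
            rev = revcomp(frag[-rl:])
            fwd_span = (s, s + rl)
            rev_span = (s + ins - rl, s + ins)
            if flips[k]:
                r1_seq, r1_span, r1_strand = rev, rev_span, "-"
                r2_seq, r2_span, r2_strand = fwd, fwd_span, "+"
            else:
                r1_seq, r1_span, r1_strand = fwd, fwd_span, "+"
                r2_seq, r2_span, r2_strand = rev, rev_span, "-"
            pair_no += 1
            base = f"{sex}_{copy_idx}_{hap}_{pair_no}"
            for suffix, rseq, span, strand in (
                ("/1", r1_seq, r1_span, r1_strand),
                ("/2", r2_seq, r2_span, r2_strand),
            ):
                if err > 0:
                    mask = rng.random(rl) < err
                    if mask.any():
                        chars = list(rseq)
                        for i in np.flatnonzero(mask):
                            old = chars[i]
                            choices = [b for b in DNA if b != old]
                            chars[i] = choices[int(rng.integers(0, 3))]
                        rseq = "".join(chars)
                reads.append(
                    ReadRecord(
                        read_id=base + suffix,
                        mate_id=base + ("/2" if suffix == "/1" else "/1"),
                        sequence=rseq,
                        quality=PLACEHOLDER_QUALITY * rl,
                        source_haplotype=hap,
                        start=span[0],
                        end=span[1],
                        strand=strand,
                    )
                )
    return ReadSet(sex, reads)


def evolve_homolog(protein: str, target_identity: float, seed: int) -> str:
    """Mutate a protein to a stated identity, preferring favourable exchanges.

    Substitutions are placed at distinct positions (so the realised identity
    is exactly ``1 - n_subs/len``) and drawn from positive-score BLOSUM62
    partners of the original residue, emulating the kind of divergence seen
    between orthologues rather than random noise.
    """
    if not protein:
        raise InputError("empty protein sequence")
    if not (0 < target_identity <= 1):
        raise InputError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(derive_seed(seed, "homolog"))
    L = len(protein)
    n_subs = int(round((1 - target_identity) * L))
    if n_subs == 0:
        return protein
    positions = rng.choice(L, size=n_subs, replace=False)
    chars = list(protein)
    for p in sorted(int(x) for x in positions):
        options = preferred_substitutions(chars[p]) if chars[p] in set(
            "ACDEFGHIKLMNPQRSTVWY"
        ) else ("A",)
        chars[p] = options[int(rng.integers(0, len(options)))]
    return "".join(chars)


def evolve_codon_pair(
    codon_seq: str, omega: float, n_events: int, seed: int
) -> tuple[str, str]:
    """Evolve a descendant from ``codon_seq`` under a fixed dN/dS ratio.

    Single-nucleotide substitutions are proposed uniformly; stop-creating
    changes are rejected outright; nonsynonymous proposals are accepted with
    relative probability omega (synonymous = 1). Exactly ``n_events``
    accepted substitutions are applied. Returns (ancestor, descendant).
    """
    if omega < 0:
        raise InputError("omega must be >= 0")
    if len(codon_seq) % 3 != 0 or not codon_seq:
        raise InputError("codon_seq must be non-empty with length % 3 == 0")
    prot = translate(codon_seq)
    if "*" in prot:
        raise InputError("codon_seq must be stop-free")
    rng = np.random.default_rng(derive_seed(seed, "codonpair"))
    seq = list(codon_seq)
    accepted = 0
    attempts = 0
    max_attempts = 10000 * max(n_events, 1)
    syn_p = 1.0 if omega >= 1 else 1.0
    if omega > 1:
        syn_p = 1.0 / omega
    while accepted < n_events:
        attempts += 1
        if attempts > max_attempts:
            raise InputError(
                "could not apply the requested number of events "
                "(omega may be too small for this sequence)"
            )
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        new = [b for b in DNA if b != old][int(rng.integers(0, 3))]
        ci = pos // 3
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        new_codon = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if CODON_TO_AA[new_codon] == "*":
            continue
        synonymous = CODON_TO_AA[new_codon] == CODON_TO_AA[codon]
        p_accept = syn_p if synonymous else (min(omega, 1.0) if omega <= 1 else 1.0)
        if p_accept < 1.0 and rng.random() >= p_accept:
            continue
        seq[pos] = new
        accepted += 1
    return codon_seq, "".join(seq)


def random_coding_sequence(n_codons: int, seed: int) -> str:
    """A random stop-free coding sequence of ``n_codons`` sense codons."""
    rng = np.random.default_rng(derive_seed(seed, "coding"))
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)
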