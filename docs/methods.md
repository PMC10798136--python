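# Methods

## The problem

Culicine mosquitoes determine sex with a dominant male-determining factor
carried on the M locus, a small male-specific region of an otherwise
homomorphic chromosome pair: males are Mm, females mm. The known M factor,
*Nix*, is an RNA-binding protein with three RNA-recognition motifs (RRMs);
its homologs are so divergent (the two first-known orthologues are only
~52% identical at the protein level) and its introns so large that finding
it in a new species from a genome assembly is unreliable. The practical
route is to work from unassembled sex-specific reads: recruit reads by
translated homology to known M-factor peptides, assemble them into
candidate contigs, discard paralogs, and then test male-specificity
directly from the male/female read pools. `mscout` implements that
workflow as a library and CLI, together with the comparative analyses used
to characterise candidates (intron position conservation, Nei–Gojobori
dN/dS, BIONJ distance trees) and a synthetic-data generator that plants a
ground-truth M locus so every stage can be validated end to end.

## Chromosome Quotient (CQ)

For a candidate sequence, `CQ = female_hits / male_hits`, where a hit is a
read with a seeded, banded alignment to the candidate at ≥95% identity
over ≥90% of the read (a deliberate proxy for a short-read mapper run
with defaults; seeds are exact 21-mers, the banded identity check uses
edit distance). A hemizygous male-specific sequence receives male hits at
haploid depth and essentially no female hits (CQ ≈ 0, called
`male_specific` when CQ < 0.01 with ≥20 male hits); an autosomal sequence
is hit equally (CQ ≈ 1, `autosomal_like` in [0.5, 1.5]). Fewer than 20
male hits is `no_data` — the floor is a package convention chosen below
the smallest confident male-specific count published for this statistic
(23); anything else is `undetermined`. `male_hits == 0` yields an
undefined quotient, reported rather than raised. An optional normaliser
(male/female total bases) compensates unequal sequencing effort; it is off
by default because the published tables report raw counts.

## Translated homology recruitment

A BLAST-style seed-and-extend in protein space: reads are translated in
six frames; 3-residue words scoring ≥11 (BLOSUM62) against any query word
seed a diagonal; seeded diagonals are scored by the best ungapped segment
(computed exactly, via a single cumulative-sum pass over all seeded
diagonals); scores within 4 of the threshold get a banded affine
Smith–Waterman rescue (gap open 11, extend 1 — the standard protein
convention). A read is recruited when any hit reaches the raw-score
threshold (default 35), and recruitment is closed under mate pairs, since
a mate of a gene-derived read is physically linked to the locus whatever
its own homology. Significance is a raw score, not an E-value: E-values
depend on database size and these searches run against small read pools;
a Karlin–Altschul E-value with fixed ungapped BLOSUM62 constants
(λ=0.3176, K=0.134) is available as a report column. At default
conditions a query at 52% identity recruits >90% of ORF-overlapping
reads (verified against truth metadata).

## Targeted assembly and paralog filtering

Recruited sets are tiny (hundreds of reads at one locus), so assembly is
greedy overlap-layout: repeatedly merge the pair of units (read or
contig, either orientation) with the longest suffix–prefix overlap
≥31 nt, discovered through shared exact 31-mers, with a deterministic
tie-break (longest overlap, then smallest id pair). Two mismatch modes
exist: exact (`max_mismatch`, default 0) and error-tolerant
(`mismatch_frac`, bounding mismatches by ceil(frac·overlap)). After each
pass, multi-read contigs are polished to the per-column majority base
(ties keep the earlier-placed base) and merging is retried to a fixed
point — polishing repairs overlap mismatches caused by single-read
errors that would otherwise block late contig–contig merges.

The pipeline default is `mismatch_frac = 0.06`. With per-base error e,
the expected mismatch rate in an overlap between two reads is ≈2e; at
e = 0.01 a bound of exactly 2% sits on the expectation and rejects about
half of all true merges, so the default adds ~3 binomial standard
deviations of headroom at typical overlap lengths. Chimeric joins are
not a practical risk at these settings because candidates require an
exact shared 31-mer.

Assembled contigs then compete against target and decoy proteins
(translated, best frame, same seed-extend machinery): a contig is kept
iff its best score is achieved by a target; ties are kept but flagged;
contigs hitting neither set are dropped as `no_homology`. The shipped
decoy generator emulates the related-protein families a low-stringency
translated search sweeps up: composition-matched shuffles (unrelated) and
homologs diverged to 35% identity (related). Genomic fragments separated
by an unassembled intron are never joined across the gap; an optional
helper concatenates ordered fragments with a fixed 100 N spacer to mark
the missing sequence (the spacer length is a package convention).

## Gene structure and intron conservation

`find_orfs` reports maximal ATG-to-stop (or stop-to-stop) frames on both
strands; spans exclude the stop codon. `spliced_align` chains maximal
exact anchors (k = 20) of a cDNA on genomic sequence colinearly
(diagonals non-decreasing, since introns only insert genomic sequence),
then places each junction by trying every split point consistent with
the alignment and taking the leftmost donor that yields a canonical
GT..AG intron within the length limits; junctions with no canonical
placement are flagged, not silently shifted. For an exact splice
product the GT..AG-consistent boundary is unique up to rare sequence
coincidences, and the leftmost rule resolves those deterministically.
Each intron is annotated with its host codon index and phase
(phase = coding nucleotides upstream mod 3; phases 1 and 2 split a
codon). Intron conservation across a family maps each (codon index,
phase) onto protein-alignment columns by skipping gaps; two introns are
conserved iff they share both column and phase — the same codon must be
interrupted identically, not merely the same column.

## Nei–Gojobori dN/dS

Per codon, each position contributes the fraction of its non-stop
single-nucleotide changes that are synonymous, so S + N = 3 exactly.
Differences between codon pairs are averaged over all substitution
orderings, excluding pathways through stop codons (the SNAP behaviour);
when every pathway is blocked, the unrestricted average is used and
flagged. Proportions pS = sd/S and pN = nd/N are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3), with saturation (p ≥ 3/4) flagged rather than
clamped; ω = dN/dS is undefined (flagged) when dS = 0. Gap handling is
pairwise deletion of codon columns containing any gap or ambiguity —
the simplest defensible rule. Both dN/dS and dS/dN are reported. The
paired generator (`evolve_codon_pair`) proposes uniform single-nucleotide
changes, rejects stop-creating ones, and accepts nonsynonymous proposals
with relative probability ω; because NG86 site counting measures exactly
the proposal fractions, the estimator recovers the simulated ω
(verified: mean estimates within ±0.05 at ω ∈ {0.05, 0.25, 1.0} with 500
codons and 100 events).

## Distance phylogenetics

Protein distances are p-distance or Poisson-corrected (−ln(1 − p)) under
pairwise gap deletion; saturated pairs (p ≥ 1) are flagged and excluded,
never clamped. BIONJ agglomerates by the neighbour-joining Q criterion
with variance-weighted matrix reduction (λ chosen to minimise the
variance of the reduced distances, clamped to [0, 1]; initial variances
equal the distances); ties resolve to the smallest label pair, and
negative branch estimates are set to zero with the deficit transferred
to the sibling. On additive matrices the reconstruction is exact (path
distances reproduced to ≤1e−9 up to 10 taxa; topology agrees with
brute-force least squares over all topologies for n ≤ 6). Bootstrap
support resamples alignment columns, rebuilds the tree per replicate,
and maps the percentage of replicates containing each internal
bipartition onto the original tree (not a consensus). The clade
branch-length contrast roots the tree conceptually at the edge
separating two taxon sets and reports each clade's mean tip path length
from its own attachment node (the separating edge counts for neither
side) and their ratio. The default distance model is Poisson and is
recorded in run metadata.

## Synthetic data: what it emulates, and what it does not

`simulate_genome` builds a diploid autosome (two identical haplotypes —
an inbred-line idealisation), an m haplotype, and an M haplotype carrying
a planted stop-free ORF (ATG + sense codons; 816 nt by default, a
published candidate-ORF length), optionally split by a GT..AG intron at a
recorded codon and phase ∈ {1, 2}. Males are {A, A, M, m}; females
{A, A, m, m}. `simulate_reads` draws paired reads at `depth` per haploid
copy (so the M locus gets half the autosomal depth in males), with
Normal(300, 30) inserts truncated to [read length, haplotype length],
uniform fragment starts normalised by the start domain so interior
coverage equals the configured depth, both orientations, and per-base
substitution errors. Quality strings are constant placeholders: every
analysis here is count- or score-based. Defaults — 30× depth, 150 bp
reads, 1% error, query homolog at 52% protein identity, ω = 0.25 — are
the validation conditions; sequencing depth is not stated in the source
study, so 30× is a package choice typical of such surveys.

Deliberately not modelled: indel sequencing errors, GC/coverage bias,
RNA-seq expression levels, heterozygosity on the autosomes, repeats, and
the 100 kb-scale introns real M-locus genes can carry. Passing tests
therefore demonstrate the pipeline's logic and its statistical behaviour
under idealised Illumina-like data, not robustness to real-library
artefacts; on real data the alignment-based stages (recruitment, CQ)
tolerate indels via their banded alignments, but the greedy assembler
assumes substitution-only errors.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from one global seed by hashing, so reruns are
bit-identical and manifests carry SHA-256 checksums of every artefact.
Validation problem sizes (6 kb autosome, 3 kb M locus, 20 pipeline
replicates; 100 random trees for tree exactness; 30 simulated pairs per
ω regime; 1,000 codon pairs for the pathway oracle) were chosen to make
the full suite a desk-scale computation while keeping every statistical
check comfortably powered.
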