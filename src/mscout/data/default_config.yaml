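# Default end-to-end run: simulate a male/female read pool pair with a
# planted hemizygous M-locus gene, then recruit, assemble, filter,
# annotate, score male-specificity, and build the comparative summaries.
seed: 0
outdir: mscout_run

stages:
  simulate: true
  recruit: true
  assemble: true
  filter_paralogs: true
  annotate: true
  cq: true
  dnds: true
  tree: true

simulate:
  autosome_length: 6000
  n_autosomal_loci: 3
  m_locus_length: 3000
  planted_orf_length: 816
  intron_length: 0
  depth: 30.0
  read_length: 150
  insert_mean: 300.0
  insert_sd: 30.0
  error_rate: 0.01
  target_protein_identity: 0.52
  omega: 0.25

recruit:
  min_score: 35
  iterations: 1

assemble:
  min_overlap: 31
  mismatch_frac: 0.06   # ~2e + headroom for per-base error e = 0.01
  min_contig_length: 200

filter_paralogs:
  n_random_decoys: 5
  n_related_decoys: 3
  related_decoy_identity: 0.35
  min_score: 35

annotate:
  min_orf_length: 300
  require_atg: true

cq:
  kmer_seed_length: 21
  min_identity: 0.95
  min_read_coverage: 0.90
  min_male_hits: 20
  normalize: false

dnds:
  n_events: 100

tree:
  bootstrap: 100
  model: poisson
  taxon_identities: [0.9, 0.8, 0.7, 0.6, 0.52]
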