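"""End-to-end orchestration: simulate -> recruit -> assemble -> filter ->
annotate -> CQ -> dN/dS -> tree, with manifests and a structured report.

One global seed deterministically derives every per-stage seed, so a rerun
with the same configuration is bit-identical. Every file a run writes is
recorded in a manifest with its SHA-256 checksum, and each stage echoes
its parameters into the report so a run can be reconstructed from its
outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import annotate as annotate_mod
from . import assemble as assemble_mod
from . import cq as cq_mod
from .dnds import dnds_matrix
from . import phylo as phylo_mod
from . import recruit as recruit_mod
from . import simulate as sim_mod
from ._util import derive_seed, sha256_of_file
from .errors import ConfigurationError

log = logging.getLogger(__name__)

STAGES = (
    "simulate", "recruit", "assemble", "filter_paralogs", "annotate",
    "cq", "dnds", "tree",
)

_DEFAULTS: dict[str, dict[str, Any]] = {
    "recruit": {"min_score": 35, "iterations": 1},
    # the pipeline's reads carry sequencing errors: with per-base error e the
    # expected overlap mismatch rate is ~2e, so the tolerant mode needs
    # headroom above that (0.06 ~ 2e + 3 sd at typical overlaps for e=0.01)
    "assemble": {
        "min_overlap": 31,
        "mismatch_frac": 0.06,
        "min_contig_length": 200,
    },
    "filter_paralogs": {
        "n_random_decoys": 5,
        "n_related_decoys": 3,
        "related_decoy_identity": 0.35,
        "min_score": 35,
    },
    "annotate": {"min_orf_length": 300, "require_atg": True},
    "cq": {
        "kmer_seed_length": 21,
        "min_identity": 0.95,
        "min_read_coverage": 0.90,
        "min_male_hits": 20,
        "normalize": False,
    },
    "dnds": {"n_events": 100},
    "tree": {
        "bootstrap": 100,
        "model": "poisson",
        "taxon_identities": [0.9, 0.8, 0.7, 0.6, 0.52],
    },
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "mscout_run"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    simulate: dict[str, Any] = field(default_factory=dict)
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def stage_params(self, stage: str) -> dict[str, Any]:
        merged = dict(_DEFAULTS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged

    def sim_config(self) -> sim_mod.SimConfig:
        return sim_mod.SimConfig.from_dict({"seed": self.seed, **self.simulate})

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cfg = cls(
            seed=int(d.pop("seed", 0)),
            outdir=str(d.pop("outdir", "mscout_run")),
        )
        stages = d.pop("stages", None)
        if stages is not None:
            unknown = set(stages) - set(STAGES)
            if unknown:
                raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
            cfg.stages = {s: bool(stages.get(s, False)) for s in STAGES}
        cfg.simulate = dict(d.pop("simulate", {}) or {})
        for stage in STAGES:
            if stage == "simulate":
                continue
            if stage in d:
                block = d.pop(stage) or {}
                allowed = set(_DEFAULTS.get(stage, {})) | (
                    {"max_mismatch"} if stage == "assemble" else set()
                )
                unknown = set(block) - allowed
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys in section {stage!r}: {sorted(unknown)}"
                    )
                cfg.params[stage] = block
        if d:
            raise ConfigurationError(f"unknown config keys: {sorted(d)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(payload)


def validate_config(path) -> list[str]:
    """Schema and invariant checks for a config file; returns a list of
    violations (empty means OK). Never touches data files."""
    errors: list[str] = []
    try:
        cfg = RunConfig.from_yaml(path)
    except ConfigurationError as exc:
        return [str(exc)]
    except Exception as exc:  # malformed YAML etc.
        return [f"unreadable config: {exc}"]
    try:
        cfg.sim_config()
    except ConfigurationError as exc:
        errors.append(f"simulate: {exc}")
    cq_p = cfg.stage_params("cq")
    try:
        cq_mod.HitParams(
            cq_p["kmer_seed_length"], cq_p["min_identity"], cq_p["min_read_coverage"]
        ).validate()
    except Exception as exc:
        errors.append(f"cq: {exc}")
    if cfg.stage_params("tree")["model"] not in ("p", "poisson"):
        errors.append("tree: model must be 'p' or 'poisson'")
    return errors


@dataclass
class RunReport:
    seed: int
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "stages": self.stages,
            "manifest": self.manifest,
            "errors": self.errors,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    A stage whose upstream products are missing (disabled or failed) is
    recorded as skipped with a structured error instead of raising.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    def record(path: Path) -> None:
        report.manifest[path.name] = sha256_of_file(path)

    genome = None
    male_reads = female_reads = None
    query_protein = None
    recruited = None
    contigs = None
    kept = None
    orfs_by_contig: dict[str, annotate_mod.OrfModel] = {}

    # ---- simulate -------------------------------------------------------
    if config.stages.get("simulate"):
        sim_cfg = config.sim_config()
        genome = sim_mod.simulate_genome(sim_cfg)
        male_reads = sim_mod.simulate_reads(genome, sim_cfg, "male")
        female_reads = sim_mod.simulate_reads(genome, sim_cfg, "female")
        query_protein = sim_mod.evolve_homolog(
            genome.orf_protein,
            sim_cfg.target_protein_identity,
            derive_seed(config.seed, "query_homolog"),
        )
        _write_fasta(outdir / "genome.fasta", genome.haplotypes)
        male_reads.write_fastq(outdir / "male_1.fastq", outdir / "male_2.fastq")
        female_reads.write_fastq(outdir / "female_1.fastq", outdir / "female_2.fastq")
        _write_fasta(outdir / "query.fasta", {"query_homolog": query_protein})
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("feature\thaplotype\tstart\tend\textra\n")
            fh.write(
                f"planted_gene\tM_hap\t{genome.gene_span[0]}\t{genome.gene_span[1]}\t.\n"
            )
            if genome.intron_span:
                fh.write(
                    f"intron\tM_hap\t{genome.intron_span[0]}\t{genome.intron_span[1]}"
                    f"\tcodon={genome.intron_codon_index};phase={genome.intron_phase}\n"
                )
            for name, s, e in genome.autosomal_loci:
                fh.write(f"{name}\tautosome_hap1\t{s}\t{e}\t.\n")
        for p in ("genome.fasta", "male_1.fastq", "male_2.fastq",
                  "female_1.fastq", "female_2.fastq", "query.fasta", "truth.tsv"):
            record(outdir / p)
        report.stages["simulate"] = {
            "params": dataclasses.asdict(sim_cfg),
            "male_reads": len(male_reads),
            "female_reads": len(female_reads),
            "male_total_bases": male_reads.total_bases,
            "female_total_bases": female_reads.total_bases,
            "planted_orf_length": len(genome.orf_cdna),
        }

    # ---- recruit --------------------------------------------------------
    if config.stages.get("recruit"):
        if male_reads is None or query_protein is None:
            report.errors["recruit"] = "stage skipped: upstream failed"
        else:
            p = config.stage_params("recruit")
            rec = recruit_mod.recruit_reads(
                {"query_homolog": query_protein}, male_reads,
                min_score=p["min_score"], iterations=p["iterations"],
            )
            recruited = rec.reads
            recruited.write_fastq(
                outdir / "recruited_1.fastq", outdir / "recruited_2.fastq"
            )
            record(outdir / "recruited_1.fastq")
            record(outdir / "recruited_2.fastq")
            report.stages["recruit"] = {
                "params": p,
                "n_recruited": len(recruited),
                "n_direct": rec.n_direct,
                "n_mates": rec.n_mates,
            }

    # ---- assemble -------------------------------------------------------
    if config.stages.get("assemble"):
        if recruited is None:
            report.errors["assemble"] = "stage skipped: upstream failed"
        else:
            p = config.stage_params("assemble")
            asm = assemble_mod.greedy_assemble(
                recruited, min_overlap=p["min_overlap"],
                mismatch_frac=p.get("mismatch_frac"),
                max_mismatch=p.get("max_mismatch", 0),
                min_contig_length=p["min_contig_length"],
            )
            contigs = asm.contigs
            _write_fasta(
                outdir / "contigs.fasta", {c.contig_id: c.sequence for c in contigs}
            )
            record(outdir / "contigs.fasta")
            report.stages["assemble"] = {
                "params": p,
                "n_contigs": len(contigs),
                "n_unplaced": len(asm.unplaced),
                "longest_contig": max((len(c) for c in contigs), default=0),
            }

    # ---- paralog filter -------------------------------------------------
    if config.stages.get("filter_paralogs"):
        if contigs is None or genome is None or query_protein is None:
            report.errors["filter_paralogs"] = "stage skipped: upstream failed"
        else:
            p = config.stage_params("filter_paralogs")
            decoys = make_decoy_proteins(
                genome.orf_protein,
                n_random=p["n_random_decoys"],
                n_related=p["n_related_decoys"],
                related_identity=p["related_decoy_identity"],
                seed=derive_seed(config.seed, "decoys"),
            )
            kept, filt = assemble_mod.paralog_filter(
                contigs, {"query_homolog": query_protein}, decoys,
                min_score=p["min_score"],
            )
            filt.to_csv(outdir / "paralog_filter.tsv", sep="\t", index=False)
            record(outdir / "paralog_filter.tsv")
            report.stages["filter_paralogs"] = {
                "params": {k: v for k, v in p.items()},
                "n_in": len(contigs),
                "n_kept": len(kept),
                "n_dropped": len(contigs) - len(kept),
            }
    elif contigs is not None:
        kept = contigs

    # ---- annotate -------------------------------------------------------
    if config.stages.get("annotate"):
        if kept is None:
            report.errors["annotate"] = "stage skipped: upstream failed"
        else:
            p = config.stage_params("annotate")
            orf_records = {}
            for c in kept:
                found = annotate_mod.find_orfs(
                    c.sequence, min_len=p["min_orf_length"],
                    require_atg=p["require_atg"], contig_id=c.contig_id,
                )
                if found:
                    best = found[0]
                    orfs_by_contig[c.contig_id] = best
                    orf_seq = c.sequence[best.start : best.end]
                    if best.strand == "-":
                        from ._util import revcomp
                        orf_seq = revcomp(orf_seq)
                    orf_records[f"{c.contig_id}_orf"] = orf_seq
            _write_fasta(outdir / "orfs.fasta", orf_records)
            record(outdir / "orfs.fasta")
            report.stages["annotate"] = {
                "params": p,
                "n_orfs": len(orf_records),
                "orf_lengths": {k: len(v) for k, v in orf_records.items()},
            }

    # ---- CQ -------------------------------------------------------------
    if config.stages.get("cq"):
        if male_reads is None or female_reads is None or kept is None:
            report.errors["cq"] = "stage skipped: upstream failed"
        else:
            p = config.stage_params("cq")
            # candidates are the ORFs of surviving contigs (the statistic is
            # computed on candidate ORFs), plus autosomal loci as controls
            refs: dict[str, str] = {}
            for c in kept:
                orf = orfs_by_contig.get(c.contig_id)
                if orf is not None:
                    seq = c.sequence[orf.start : orf.end]
                    if orf.strand == "-":
                        from ._util import revcomp
                        seq = revcomp(seq)
                    refs[f"{c.contig_id}_orf"] = seq
            for name, s, e in genome.autosomal_loci:
                refs[name] = genome.haplotypes["autosome_hap1"][s:e]
            params = cq_mod.HitParams(
                p["kmer_seed_length"], p["min_identity"], p["min_read_coverage"]
            )
            table = cq_mod.cq_table(
                male_reads, female_reads, refs, params,
                min_male_hits=p["min_male_hits"], normalize=p["normalize"],
            )
            table.to_csv(outdir / "cq.tsv", sep="\t", index=False)
            record(outdir / "cq.tsv")
            report.stages["cq"] = {
                "params": p,
                "table": table.to_dict("records"),
                "n_male_specific": int((table["classification"] == "male_specific").sum()),
            }

    # ---- dN/dS ----------------------------------------------------------
    if config.stages.get("dnds"):
        if genome is None:
            report.errors["dnds"] = "stage skipped: upstream failed"
        else:
            p = config.stage_params("dnds")
            sim_cfg = config.sim_config()
            anc, desc = sim_mod.evolve_codon_pair(
                genome.orf_cdna, sim_cfg.omega, p["n_events"],
                derive_seed(config.seed, "dnds_pair"),
            )
            mat = dnds_matrix({"ancestor": anc, "descendant": desc})
            mat.to_csv(outdir / "dnds.tsv", sep="\t", index=False)
            record(outdir / "dnds.tsv")
            report.stages["dnds"] = {
                "params": {**p, "simulated_omega": sim_cfg.omega},
                "omega_estimate": (
                    None if mat["omega"].isna().all() else float(mat["omega"].iloc[0])
                ),
            }

    # ---- tree -----------------------------------------------------------
    if config.stages.get("tree"):
        if genome is None:
            report.errors["tree"] = "stage skipped: upstream failed"
        else:
            p = config.stage_params("tree")
            family = {"planted": genome.orf_protein}
            for i, ident in enumerate(p["taxon_identities"], 1):
                family[f"homolog_{i}"] = sim_mod.evolve_homolog(
                    genome.orf_protein, float(ident),
                    derive_seed(config.seed, "tree_taxon", i),
                )
            tree = phylo_mod.bootstrap_support(
                family, n_reps=int(p["bootstrap"]),
                seed=derive_seed(config.seed, "bootstrap"), model=p["model"],
            )
            newick = phylo_mod.tree_to_newick(tree)
            (outdir / "tree.nwk").write_text(newick + "\n")
            record(outdir / "tree.nwk")
            report.stages["tree"] = {
                "params": p,
                "newick": newick,
                "distance_model": p["model"],
            }

    with open(outdir / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report


def make_decoy_proteins(
    target_protein: str,
    n_random: int = 5,
    n_related: int = 3,
    related_identity: float = 0.35,
    seed: int = 0,
) -> dict[str, str]:
    """Synthetic decoy proteins for best-hit paralog competition.

    ``n_random`` composition-matched shuffles emulate unrelated proteins;
    ``n_related`` homologs diverged to ``related_identity`` emulate the
    related gene families (e.g. other RNA-binding proteins) that a
    low-stringency translated search sweeps up.
    """
    import numpy as np

    rng = np.random.default_rng(derive_seed(seed, "decoy_shuffle"))
    decoys: dict[str, str] = {}
    chars = list(target_protein)
    for i in range(n_random):
        perm = rng.permutation(len(chars))
        decoys[f"decoy_random_{i + 1}"] = "".join(chars[j] for j in perm)
    for i in range(n_related):
        decoys[f"decoy_related_{i + 1}"] = sim_mod.evolve_homolog(
            target_protein, related_identity, derive_seed(seed, "decoy_related", i)
        )
    return decoys
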