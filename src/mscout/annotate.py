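"""ORF finding, spliced cDNA-to-genomic alignment, intron conservation.

Intron positions are a phylogenetic character: an intron interrupting the
same alignment column with the same phase in two genes is strong evidence
of common ancestry, because independent insertions at the identical codon
position are improbable. This module finds open reading frames, infers
exon/intron structure by colinear anchor chaining of a cDNA against its
genomic sequence (canonical GT..AG junctions), and maps per-gene intron
(codon index, phase) annotations onto the columns of a protein multiple
alignment to call conserved intron positions.

Phase convention: an intron falling after t coding nucleotides has phase
t mod 3 — phase 0 lies between codons, phases 1 and 2 split the codon
with index t // 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._util import revcomp, translate
from .errors import InputError, UnalignableError

GAP_CHARS = set("-.")


@dataclass
class OrfModel:
    contig_id: str
    strand: str  # '+' or '-'
    start: int  # forward-strand coords, 0-based half-open; stop codon excluded
    end: int
    protein: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IntronAnnotation:
    gene_id: str
    start: int  # on the genomic sequence, 0-based half-open
    end: int
    donor: str
    acceptor: str
    codon_index: int  # 0-based residue index of the host codon
    phase: int  # 0, 1 or 2
    flags: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    gene_id: str
    exons: list[tuple[int, int]]  # genomic spans, 0-based half-open
    introns: list[IntronAnnotation]
    cdna_length: int
    coverage: float  # fraction of the cDNA covered by chained anchors
    flags: list[str] = field(default_factory=list)


def find_orfs(
    seq: str, min_len: int = 300, require_atg: bool = True, contig_id: str = ""
) -> list[OrfModel]:
    """All maximal ORFs of at least ``min_len`` nt on both strands.

    Spans cover the coding sequence only (the stop codon is excluded) and
    are reported in forward-strand coordinates, longest first.
    """
    seq = seq.upper()
    L = len(seq)
    orfs: list[OrfModel] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            prot = translate(s[frame:])
            seg_start = 0  # residue index where current stop-free segment starts
            for r in range(len(prot) + 1):
                at_end = r == len(prot)
                if at_end or prot[r] == "*":
                    seg = prot[seg_start:r]
                    first = 0
                    if require_atg:
                        first = seg.find("M")
                    if seg and first != -1:
                        res_start = seg_start + first
                        nt_start = frame + 3 * res_start
                        nt_end = frame + 3 * r
                        if nt_end - nt_start >= min_len:
                            if strand == "+":
                                fs, fe = nt_start, nt_end
                            else:
                                fs, fe = L - nt_end, L - nt_start
                            orfs.append(
                                OrfModel(contig_id, strand, fs, fe, seg[first:])
                            )
                    seg_start = r + 1
    orfs.sort(key=lambda o: (-(o.end - o.start), o.start, o.strand))
    return orfs


def _anchors(cdna: str, gdna: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal-ish exact matches as (c_start, g_start, length) from k-mer
    runs on shared diagonals."""
    index: dict[str, list[int]] = {}
    for i in range(len(gdna) - k + 1):
        index.setdefault(gdna[i : i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for c in range(len(cdna) - k + 1):
        for g in index.get(cdna[c : c + k], ()):
            by_diag.setdefault(g - c, []).append(c)
    anchors = []
    for d, cs in by_diag.items():
        cs.sort()
        run_start = cs[0]
        prev = cs[0]
        for c in cs[1:] + [None]:
            if c is not None and c == prev + 1:
                prev = c
                continue
            anchors.append((run_start, run_start + d, prev - run_start + k))
            if c is not None:
                run_start = prev = c
    return anchors


def _chain(anchors: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Highest-coverage colinear chain of anchors (quadratic DP)."""
    anchors = sorted(anchors, key=lambda a: (a[0], a[1]))
    n = len(anchors)
    if n == 0:
        return []
    best = [a[2] for a in anchors]
    prev = [-1] * n
    for i in range(n):
        ci, gi, li = anchors[i]
        for j in range(i):
            cj, gj, lj = anchors[j]
            # colinear: j before i in both sequences, with a non-decreasing
            # diagonal (genomic gaps only ever grow: introns insert gDNA)
            if (
                cj <= ci
                and gj <= gi
                and gj - cj <= gi - ci
                and cj + lj <= ci + li
            ):
                gain = min(li, ci + li - (cj + lj))  # new cdna coverage
                if gain <= 0:
                    continue
                if best[j] + gain > best[i]:
                    best[i] = best[j] + gain
                    prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -anchors[i][0]))
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    chain.reverse()
    # drop anchors on the same diagonal as their predecessor (merge runs)
    merged: list[tuple[int, int, int]] = []
    for a in chain:
        if merged:
            pc, pg, pl = merged[-1]
            if a[1] - a[0] == pg - pc:  # same diagonal: extend
                new_end = max(pc + pl, a[0] + a[2])
                merged[-1] = (pc, pg, new_end - pc)
                continue
        merged.append(a)
    return merged


def spliced_align(
    cdna: str,
    gdna: str,
    min_anchor: int = 20,
    min_intron: int = 40,
    max_intron: int = 200_000,
    orf_start: int = 0,
    gene_id: str = "gene",
    canonical: bool = True,
) -> GeneModel:
    """Infer exon/intron structure by chaining exact cDNA anchors on gDNA.

    Junction placement: between adjacent chained exon anchors every split
    point consistent with the alignment is tried and the leftmost donor
    giving a canonical GT..AG intron is chosen; junctions with no canonical
    placement are flagged ``noncanonical`` at the anchor boundary rather
    than silently shifted. Host codon index and phase are reported
    relative to the reading frame starting at ``orf_start`` on the cDNA.
    """
    cdna, gdna = cdna.upper(), gdna.upper()
    if not cdna or not gdna:
        raise InputError("cdna and gdna must be non-empty")
    chain = _chain(_anchors(cdna, gdna, min_anchor))
    if not chain:
        raise UnalignableError(f"{gene_id}: no colinear anchor chain found")
    covered = 0
    last_end = 0
    for c, g, l in chain:
        covered += max(0, c + l - max(c, last_end))
        last_end = max(last_end, c + l)
    coverage = covered / len(cdna)
    if coverage < 0.95:
        raise UnalignableError(
            f"{gene_id}: anchors cover only {coverage:.0%} of the cDNA"
        )

    exons: list[tuple[int, int]] = []
    introns: list[IntronAnnotation] = []
    flags: list[str] = []
    c0, g0, l0 = chain[0]
    exon_g_start = g0 - c0  # extrapolate exon 1 to the cDNA start
    if exon_g_start < 0:
        exon_g_start = g0
    cur_exon_start = exon_g_start
    for idx in range(1, len(chain)):
        pc, pg, pl = chain[idx - 1]
        nc, ng, nl = chain[idx]
        d1 = pg - pc
        d2 = ng - nc
        intron_len = d2 - d1
        if intron_len <= 0:
            flags.append("out_of_order_anchors")
            continue
        lo = max(nc, 0)
        hi = min(pc + pl, nc + nl)
        t_chosen = None
        for t in range(lo, hi + 1):
            ds, de = t + d1, t + d2
            if ds < 0 or de > len(gdna):
                continue
            if gdna[ds : ds + 2] == "GT" and gdna[de - 2 : de] == "AG":
                t_chosen = t
                break  # leftmost donor
        junction_flags = []
        if t_chosen is None:
            t_chosen = pc + pl  # anchor boundary, not shifted
            junction_flags.append("noncanonical")
        if not (min_intron <= intron_len <= max_intron):
            junction_flags.append("length_out_of_range")
        ds, de = t_chosen + d1, t_chosen + d2
        t_rel = t_chosen - orf_start
        introns.append(
            IntronAnnotation(
                gene_id=gene_id,
                start=ds,
                end=de,
                donor=gdna[ds : ds + 2],
                acceptor=gdna[de - 2 : de],
                codon_index=t_rel // 3,
                phase=t_rel % 3,
                flags=junction_flags,
            )
        )
        exons.append((cur_exon_start, ds))
        cur_exon_start = de
    lc, lg, ll = chain[-1]
    exon_g_end = lg + ll + (len(cdna) - (lc + ll))  # extrapolate to cDNA end
    exon_g_end = min(exon_g_end, len(gdna))
    exons.append((cur_exon_start, exon_g_end))
    if canonical:
        flags.extend(
            f for i in introns for f in i.flags if f == "noncanonical"
        )
    return GeneModel(gene_id, exons, introns, len(cdna), coverage, flags)


def spliced_exon_sequence(model: GeneModel, gdna: str) -> str:
    """Concatenated exon sequence of a gene model (the predicted cDNA)."""
    return "".join(gdna[s:e] for s, e in model.exons)


def map_intron_to_alignment(
    introns: Mapping[str, Sequence[tuple[int, int]]],
    msa: Mapping[str, str],
) -> tuple[pd.DataFrame, list[dict]]:
    """Map per-sequence intron (codon_index, phase) onto alignment columns.

    Residue indices are converted to columns by skipping gap characters in
    each row. Two introns are conserved iff they land in the same column
    with the same phase; groups of co-located introns (size >= 2) are
    returned alongside the per-intron table.
    """
    rows = []
    for seq_id, annots in introns.items():
        if seq_id not in msa:
            raise InputError(f"sequence {seq_id!r} is not a row of the alignment")
        row = msa[seq_id]
        ungapped_positions = [i for i, ch in enumerate(row) if ch not in GAP_CHARS]
        for codon_index, phase in annots:
            if codon_index >= len(ungapped_positions):
                raise InputError(
                    f"{seq_id}: codon index {codon_index} beyond ungapped "
                    f"length {len(ungapped_positions)}"
                )
            column = ungapped_positions[codon_index]
            rows.append(
                {
                    "seq_id": seq_id,
                    "codon_index": codon_index,
                    "phase": phase,
                    "column": column,
                }
            )
    table = pd.DataFrame(rows, columns=["seq_id", "codon_index", "phase", "column"])
    groups: list[dict] = []
    if len(table):
        for (column, phase), grp in table.groupby(["column", "phase"]):
            members = sorted(grp["seq_id"])
            if len(members) >= 2:
                groups.append(
                    {"column": int(column), "phase": int(phase), "members": members}
                )
    groups.sort(key=lambda g: (-len(g["members"]), g["column"]))
    table["conserved"] = [
        any(r["seq_id"] in g["members"] and r["column"] == g["column"] and r["phase"] == g["phase"] for g in groups)
        for r in table.to_dict("records")
    ]
    return table, groups


def gene_models_to_gff3(models: Sequence[GeneModel], seq_ids: Mapping[str, str], path) -> None:
    """Write gene models as GFF3 (1-based, inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            seqid = seq_ids.get(m.gene_id, m.gene_id)
            start = min(s for s, _ in m.exons)
            end = max(e for _, e in m.exons)
            g1, g2 = to_gff_interval(start, end)
            fh.write(
                f"{seqid}\tmscout\tgene\t{g1}\t{g2}\t.\t+\t.\tID={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                e1, e2 = to_gff_interval(s, e)
                fh.write(
                    f"{seqid}\tmscout\texon\t{e1}\t{e2}\t.\t+\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


def to_gff_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open span to GFF3 1-based inclusive."""
    if end <= start:
        raise InputError(f"empty interval [{start}, {end})")
    return start + 1, end
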