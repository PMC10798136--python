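"""Greedy overlap assembly of recruited reads and best-hit paralog filtering.

Recruited read sets are tiny (hundreds of reads around one locus), where a
greedy overlap-layout assembler is simple, deterministic and easy to test.
At every step the pair of sequences (read or contig, either orientation)
with the longest qualifying suffix-prefix overlap is merged, with a fixed
tie-break, until no merge applies.

Contigs are then screened for paralogy by best-hit competition: each
contig is aligned in translated space against the target proteins and a
decoy protein set, and kept only if its best score is achieved by a
target. This removes related genes (e.g. other RNA-binding proteins) that
were swept up by the low-stringency recruitment.

Genomic contigs separated by an unassembled intron are NOT joined across
the gap; an optional helper concatenates ordered fragments with a fixed
run of Ns to mark the missing intronic sequence.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from ._util import revcomp
from .errors import InputError
from .recruit import DiagonalScorer, best_hit_for_sequence
from .simulate import ReadSet

N_SPACER_DEFAULT = 100


@dataclass
class Placement:
    read_id: str
    offset: int
    strand: str  # '+' or '-' relative to the contig sequence


@dataclass
class Contig:
    contig_id: str
    sequence: str
    placements: list[Placement] = field(default_factory=list)
    mean_coverage: float = 0.0  # supporting read bases / contig length

    @property
    def read_ids(self) -> list[str]:
        return [p.read_id for p in self.placements]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    unplaced: list[str]  # read ids left as short singletons


@dataclass
class _Node:
    seq: str
    placements: list[Placement]
    read_lengths: int


def _oriented(seq: str, orient: str) -> str:
    return seq if orient == "+" else revcomp(seq)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def greedy_assemble(
    reads,
    min_overlap: int = 31,
    max_mismatch: int = 0,
    mismatch_frac: Optional[float] = None,
    min_contig_length: int = 200,
) -> AssemblyResult:
    """Merge reads/contigs by longest suffix-prefix overlap until stable.

    ``max_mismatch`` bounds mismatches in each merged overlap; the
    error-tolerant mode (``mismatch_frac``) scales the bound with overlap
    length instead (ceil(frac * overlap)). Overlap candidates are found
    through shared ``min_overlap``-mers, so an overlap only qualifies if
    at least one exact shared k-mer survives in it. After each merging
    pass, contigs with two or more reads are polished to the per-column
    majority base (ties keep the earlier-placed base) and merging is
    retried, because polishing can repair overlap mismatches caused by
    single-read errors; the process runs to a fixed point. Ties between
    equal-length overlaps resolve to the smallest (id, id) pair. Unmerged
    singletons shorter than ``min_contig_length`` are reported as
    unplaced.
    """
    if isinstance(reads, ReadSet):
        items = [(r.read_id, r.sequence.upper()) for r in reads]
    else:
        items = [
            (getattr(r, "read_id", None) or r[0],
             (getattr(r, "sequence", None) or r[1]).upper())
            for r in reads
        ]
    if not items:
        return AssemblyResult([], [])
    items.sort(key=lambda t: t[0])

    def allowed_mismatches(ovl: int) -> int:
        if mismatch_frac is not None:
            return math.ceil(mismatch_frac * ovl)
        return max_mismatch

    read_seq = dict(items)
    read_len = {rid: len(seq) for rid, seq in items}

    # current assembly state: unit id -> (sequence, read-level placements)
    units: dict[str, tuple[str, list[Placement]]] = {
        rid: (seq, [Placement(rid, 0, "+")]) for rid, seq in items
    }
    for _pass in range(8):  # fixed point is reached in 2-3 passes
        pass_items = sorted((uid, seq) for uid, (seq, _) in units.items())
        merged_nodes = _merge_pass(pass_items, min_overlap, allowed_mismatches)
        if len(merged_nodes) == len(units):
            break
        new_units: dict[str, tuple[str, list[Placement]]] = {}
        for seq, unit_placements, origin_id in merged_nodes:
            composed: list[Placement] = []
            for up in unit_placements:
                sub_seq, sub_reads = units[up.read_id]
                L = len(sub_seq)
                for rp in sub_reads:
                    if up.strand == "+":
                        composed.append(
                            Placement(rp.read_id, up.offset + rp.offset, rp.strand)
                        )
                    else:
                        flipped = L - (rp.offset + read_len[rp.read_id])
                        composed.append(
                            Placement(
                                rp.read_id, up.offset + flipped, _flip(rp.strand)
                            )
                        )
            if len(composed) > 1:
                seq = _consensus(seq, composed, read_seq)
            new_units[origin_id] = (seq, composed)
        units = new_units

    contigs: list[Contig] = []
    unplaced: list[str] = []
    for uid in sorted(units):
        seq, placements = units[uid]
        if len(placements) == 1 and len(seq) < min_contig_length:
            unplaced.append(placements[0].read_id)
            continue
        total_read_bases = sum(read_len[p.read_id] for p in placements)
        contigs.append(
            Contig(
                uid,
                seq,
                sorted(placements, key=lambda p: (p.offset, p.read_id)),
                mean_coverage=total_read_bases / len(seq),
            )
        )
    contigs.sort(key=lambda c: (-len(c.sequence), c.contig_id))
    for i, c in enumerate(contigs, start=1):
        c.contig_id = f"contig_{i}"
    return AssemblyResult(contigs, unplaced)


def _merge_pass(items, k, allowed_mismatches):
    """One greedy longest-overlap-first merging pass over (id, seq) units.

    Returns a list of (sequence, placements-of-unit-ids, origin_id).
    """
    nodes: dict[int, _Node] = {}
    origin: dict[int, str] = {}  # node id -> smallest member id (tie-breaks)
    index: dict[str, list[tuple[int, int]]] = {}  # kmer -> [(node_id, pos)]
    alive: set[int] = set()
    heap: list[tuple] = []
    next_id = itertools.count()
    unit_len = {uid: len(seq) for uid, seq in items}

    def overlap_candidates(nid: int):
        seq = nodes[nid].seq
        seen: set[tuple] = set()
        for orient in "+-":
            s = _oriented(seq, orient)
            for q in range(len(s) - k + 1):
                for other, p in index.get(s[q : q + k], ()):
                    if other == nid or other not in alive:
                        continue
                    offset = p - q  # position of s's start in other's coords
                    if offset >= 0:
                        cand = (other, "+", nid, orient, offset)
                    else:
                        cand = (nid, orient, other, "+", -offset)
                    if cand in seen:
                        continue
                    seen.add(cand)
                    lead, lo, foll, fo, off = cand
                    ovl = min(len(nodes[lead].seq) - off, len(nodes[foll].seq))
                    if ovl < k:
                        continue
                    yield (
                        -ovl,
                        origin[lead], origin[foll], lo, fo, off, lead, foll,
                    )

    def push_candidates(nid: int):
        for cand in overlap_candidates(nid):
            heapq.heappush(heap, cand)

    def add_to_index(nid: int):
        seq = nodes[nid].seq
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((nid, pos))

    for uid, seq in items:
        nid = next(next_id)
        nodes[nid] = _Node(seq, [Placement(uid, 0, "+")], len(seq))
        origin[nid] = uid
        alive.add(nid)
        push_candidates(nid)
        add_to_index(nid)

    while heap:
        neg_ovl, _, _, lo, fo, off, lead, foll = heapq.heappop(heap)
        if lead not in alive or foll not in alive:
            continue
        lead_seq = _oriented(nodes[lead].seq, lo)
        foll_seq = _oriented(nodes[foll].seq, fo)
        ovl = min(len(lead_seq) - off, len(foll_seq))
        if ovl < k or -neg_ovl != ovl:
            continue
        mism = sum(
            1 for a, b in zip(lead_seq[off : off + ovl], foll_seq[:ovl]) if a != b
        )
        if mism > allowed_mismatches(ovl):
            continue
        # merge: the earlier-placed (lead) sequence wins in the overlap
        if len(foll_seq) > ovl:
            merged = lead_seq + foll_seq[ovl:]
        else:
            merged = lead_seq
        placements: list[Placement] = []
        for node, orient, shift in ((lead, lo, 0), (foll, fo, off)):
            src = nodes[node]
            L = len(src.seq)
            for p in src.placements:
                if orient == "+":
                    placements.append(Placement(p.read_id, shift + p.offset, p.strand))
                else:
                    new_off = L - (p.offset + unit_len[p.read_id])
                    placements.append(
                        Placement(p.read_id, shift + new_off, _flip(p.strand))
                    )
        nid = next(next_id)
        nodes[nid] = _Node(
            merged, placements, nodes[lead].read_lengths + nodes[foll].read_lengths
        )
        origin[nid] = min(origin[lead], origin[foll])
        alive.discard(lead)
        alive.discard(foll)
        alive.add(nid)
        push_candidates(nid)
        add_to_index(nid)

    out = []
    for nid in sorted(alive, key=lambda x: origin[x]):
        node = nodes[nid]
        out.append((node.seq, node.placements, origin[nid]))
    return out


def _consensus(
    seq: str, placements: list[Placement], read_seq: dict[str, str]
) -> str:
    """Majority vote across placed reads per column; ties keep the current
    (earlier-placed) base. Placements are gapless, so columns align 1:1."""
    votes: list[dict[str, int]] = [dict() for _ in range(len(seq))]
    for p in placements:
        r = read_seq[p.read_id]
        oriented = r if p.strand == "+" else revcomp(r)
        for t, base in enumerate(oriented):
            col = p.offset + t
            if 0 <= col < len(seq):
                votes[col][base] = votes[col].get(base, 0) + 1
    out = list(seq)
    for col, v in enumerate(votes):
        if not v:
            continue
        cur = out[col]
        best_base, best_n = cur, v.get(cur, 0)
        for base in sorted(v):
            if v[base] > best_n:
                best_base, best_n = base, v[base]
        out[col] = best_base
    return "".join(out)


def join_with_n(fragments: Sequence[str], spacer: int = N_SPACER_DEFAULT) -> str:
    """Concatenate ordered contig fragments with a fixed N spacer, marking
    unassembled (e.g. intronic) sequence between them."""
    return ("N" * spacer).join(fragments)


def paralog_filter(
    contigs: Sequence[Contig],
    target_proteins,
    decoy_proteins,
    min_score: int = 35,
    word_size: int = 3,
    neighborhood_min: int = 11,
) -> tuple[list[Contig], pd.DataFrame]:
    """Best-hit competition of contigs against targets versus decoys.

    Each contig is aligned (translated, best frame) against every target
    and decoy protein; it is kept iff its best score is achieved by a
    target. Score ties are kept but flagged. Contigs without a qualifying
    hit to either set are dropped and reported as ``no_homology``.
    """
    targets = _as_protein_dict(target_proteins, "target")
    decoys = _as_protein_dict(decoy_proteins, "decoy")
    if not targets or not decoys:
        raise InputError("both target and decoy protein sets must be non-empty")
    hoods = {
        name: DiagonalScorer(seq, word_size, neighborhood_min)
        for name, seq in {**targets, **decoys}.items()
    }
    kept: list[Contig] = []
    rows = []
    for contig in contigs:
        def best_against(prots: dict[str, str]) -> tuple[int, str]:
            best_score, best_name = 0, ""
            for name, prot in prots.items():
                hit = best_hit_for_sequence(
                    contig.sequence, prot, hood=hoods[name],
                    word_size=word_size, neighborhood_min=neighborhood_min,
                    min_keep=min_score, subject_id=contig.contig_id, query_id=name,
                )
                if hit and hit.score > best_score:
                    best_score, best_name = hit.score, name
            return best_score, best_name

        t_score, t_name = best_against(targets)
        d_score, d_name = best_against(decoys)
        if t_score < min_score and d_score < min_score:
            verdict, keep, flag = "no_homology", False, ""
        elif t_score > d_score:
            verdict, keep, flag = "target_best", True, ""
        elif t_score == d_score:
            verdict, keep, flag = "tie", True, "tie"
        else:
            verdict, keep, flag = "decoy_better", False, ""
        if keep:
            kept.append(contig)
        rows.append(
            {
                "contig_id": contig.contig_id,
                "length": len(contig.sequence),
                "best_target": t_name,
                "best_target_score": t_score,
                "best_decoy": d_name,
                "best_decoy_score": d_score,
                "verdict": verdict,
                "kept": keep,
                "flag": flag,
            }
        )
    return kept, pd.DataFrame(rows)


def _as_protein_dict(proteins, prefix: str) -> dict[str, str]:
    if isinstance(proteins, dict):
        return {str(k): str(v).upper() for k, v in proteins.items()}
    out = {}
    for i, item in enumerate(proteins):
        if hasattr(item, "id") and hasattr(item, "seq"):
            out[str(item.id)] = str(item.seq).upper()
        elif isinstance(item, (tuple, list)):
            out[str(item[0])] = str(item[1]).upper()
        else:
            out[f"{prefix}_{i + 1}"] = str(item).upper()
    return out
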