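"""Translated homology search: recruit reads related to query proteins.

This is a seed-and-extend search in the style of a protein-vs-translated-
nucleotide BLAST: each read is translated in six frames, three-residue
words scoring at least a neighbourhood threshold against any query word
seed candidate alignments, and seeds are extended (ungapped X-drop first,
then banded affine Smith-Waterman for borderline cases) under BLOSUM62.
Reads with a hit above a raw-score threshold are recruited together with
their mates, because a mate of a gene-derived read is physically linked to
the gene even when it carries no homology itself.

Significance is a raw-score threshold rather than an E-value: E-values are
database-size dependent and the searches here run against small recruited
read sets. A Karlin-Altschul E-value with fixed ungapped BLOSUM62 constants
is available as an optional report column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from ._util import AA20, blosum62, revcomp, translate
from .errors import InputError
from .simulate import ReadSet

_B62_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_B62_MATRIX = np.array(
    [
        [blosum62(a, b) for b in _B62_ALPHABET]
        for a in _B62_ALPHABET
    ],
    dtype=np.int16,
)
_CHAR_LUT = np.full(256, _B62_ALPHABET.index("X"), dtype=np.int16)
for _i, _c in enumerate(_B62_ALPHABET):
    _CHAR_LUT[ord(_c)] = _i


def _encode_protein(prot: str) -> np.ndarray:
    return _CHAR_LUT[np.frombuffer(prot.encode("ascii"), dtype=np.uint8)]


def _best_segment(values: np.ndarray) -> int:
    """Maximum-sum contiguous segment (0 when all negative)."""
    c = np.cumsum(values)
    shifted = np.concatenate(([0], c[:-1]))
    return int(np.max(c - np.minimum.accumulate(shifted), initial=0))


class DiagonalScorer:
    """Seeded ungapped diagonal scoring of one query against translated
    frames, vectorised over each seeded diagonal."""

    def __init__(self, query: str, word_size: int = 3, neighborhood_min: int = 11):
        self.query = query
        self.word_size = word_size
        self.hood = word_neighborhood(query, word_size, neighborhood_min)
        self.q_idx = _encode_protein(query)

    def seeded_diagonals(self, prot: str) -> set[int]:
        w = self.word_size
        hood = self.hood
        diags: set[int] = set()
        for j in range(len(prot) - w + 1):
            for qpos in hood.get(prot[j : j + w], ()):
                diags.add(j - qpos)
        return diags

    def seeds_for(self, prot: str, frame: int = 0) -> list[Seed]:
        """One representative seed per seeded diagonal, in diagonal order."""
        w = self.word_size
        out: dict[int, Seed] = {}
        for j in range(len(prot) - w + 1):
            for qpos in self.hood.get(prot[j : j + w], ()):
                d = j - qpos
                if d not in out:
                    out[d] = Seed(qpos, frame, j)
        return [out[d] for d in sorted(out)]

    def best_ungapped(self, prot: str, diags: Iterable[int] | None = None) -> int:
        """Best ungapped segment score over the seeded diagonals of one
        translated frame.

        All seeded diagonals are concatenated with large negative
        separators so one cumulative-sum pass yields the best segment (a
        segment can never profitably cross a separator).
        """
        if diags is None:
            diags = self.seeded_diagonals(prot)
        if not diags:
            return 0
        f_idx = _encode_protein(prot)
        n, m = len(self.q_idx), len(f_idx)
        scores = _B62_MATRIX[self.q_idx[:, None], f_idx[None, :]]
        flat = scores.ravel()
        sep = np.array([-10000], dtype=np.int16)
        pieces = []
        for d in diags:
            i0, j0 = (0, d) if d >= 0 else (-d, 0)
            length = min(n - i0, m - j0)
            if length < self.word_size:
                continue
            start = i0 * m + j0
            pieces.append(flat[start : start + length * (m + 1) : m + 1])
            pieces.append(sep)
        if not pieces:
            return 0
        v = np.concatenate(pieces[:-1]).astype(np.int64)
        return _best_segment(v)

FRAMES = (1, 2, 3, -1, -2, -3)

# Ungapped BLOSUM62 Karlin-Altschul constants (used only for the optional
# E-value column).
KA_LAMBDA = 0.3176
KA_K = 0.134


class Seed(NamedTuple):
    query_pos: int
    frame: int
    frame_pos: int


@dataclass
class AlignmentHit:
    """A scored local alignment of a protein query against one translated
    frame of a nucleotide subject."""

    query_id: str
    subject_id: str
    frame: int
    subject_nt_span: tuple[int, int]  # 0-based half-open on the forward strand
    query_span: tuple[int, int]  # residue coordinates on the query
    score: int
    pident: float
    length: int  # aligned columns (residues)
    mismatches: int = 0
    gap_opens: int = 0

    def evalue(self, query_len: int, db_len_nt: int) -> float:
        return KA_K * query_len * db_len_nt * math.exp(-KA_LAMBDA * self.score)


def sixframe_translate(nucseq: str) -> dict[int, str]:
    """Three forward and three reverse-complement protein frames.

    Codons containing N translate to X; trailing partial codons are
    dropped. Frame +n starts at offset n-1 of the forward strand; frame -n
    starts at offset n-1 of the reverse complement.
    """
    seq = nucseq.upper()
    rc = revcomp(seq)
    frames = {}
    for f in (1, 2, 3):
        frames[f] = translate(seq[f - 1 :])
        frames[-f] = translate(rc[f - 1 :])
    return frames


def word_neighborhood(
    query: str, word_size: int = 3, neighborhood_min: int = 11
) -> dict[str, list[int]]:
    """All words scoring >= neighborhood_min against some query word,
    mapped to the query positions they seed."""
    per_residue = {
        a: sorted(((blosum62(a, x), x) for x in AA20), reverse=True) for a in AA20
    }
    max_score = {a: per_residue[a][0][0] for a in AA20}
    hood: dict[str, list[int]] = {}
    for i in range(len(query) - word_size + 1):
        word = query[i : i + word_size]
        if any(c not in max_score for c in word):
            continue
        suffix_max = [0] * (word_size + 1)
        for j in range(word_size - 1, -1, -1):
            suffix_max[j] = suffix_max[j + 1] + max_score[word[j]]

        def expand(j: int, score: int, prefix: str):
            if j == word_size:
                hood.setdefault(prefix, []).append(i)
                return
            for s, x in per_residue[word[j]]:
                if score + s + suffix_max[j + 1] < neighborhood_min:
                    break
                expand(j + 1, score + s, prefix + x)

        expand(0, 0, "")
    return hood


def find_seed_hits(
    query: str,
    frames: Mapping[int, str],
    word_size: int = 3,
    neighborhood_min: int = 11,
) -> list[Seed]:
    """All (query_pos, frame, frame_pos) word pairs scoring >= the
    neighbourhood threshold under BLOSUM62."""
    if not query:
        raise InputError("empty query protein")
    if word_size > len(query):
        return []
    hood = word_neighborhood(query, word_size, neighborhood_min)
    seeds = []
    for frame, prot in frames.items():
        for j in range(len(prot) - word_size + 1):
            for qpos in hood.get(prot[j : j + word_size], ()):
                seeds.append(Seed(qpos, frame, j))
    return seeds


def ungapped_extend(
    query: str, subject: str, qpos: int, spos: int, word_size: int = 3, xdrop: int = 20
) -> tuple[int, int, int, int, int]:
    """X-drop ungapped extension of a seed word along its diagonal.

    Returns (score, qstart, qend, sstart, send) of the best-scoring
    ungapped segment containing the seed word.
    """
    # seed word score
    score = sum(blosum62(query[qpos + t], subject[spos + t]) for t in range(word_size))
    best = score
    qe, se = qpos + word_size, spos + word_size
    best_qe, best_se = qe, se
    cur = score
    while qe < len(query) and se < len(subject):
        cur += blosum62(query[qe], subject[se])
        qe += 1
        se += 1
        if cur > best:
            best, best_qe, best_se = cur, qe, se
        elif best - cur > xdrop:
            break
    qs, ss = qpos, spos
    best_qs, best_ss = qs, ss
    cur = best
    while qs > 0 and ss > 0:
        cur += blosum62(query[qs - 1], subject[ss - 1])
        qs -= 1
        ss -= 1
        if cur > best:
            best, best_qs, best_ss = cur, qs, ss
        elif best - cur > xdrop:
            break
    return best, best_qs, best_qe, best_ss, best_se


def _banded_sw(
    query: str, subject: str, diag: int, band: int, gap_open: int, gap_extend: int
) -> tuple[int, int, int, int, int, int, int, int]:
    """Banded affine local alignment restricted to |i - j - diag| <= band.

    i indexes the query, j the subject (both 1-based in the DP). Returns
    (score, qstart, qend, sstart, send, matches, aligned_len, gap_opens)
    with a deterministic tie-break: among equal-scoring cells the first in
    (i, j) scan order wins, which prefers the leftmost, then shortest
    alignment.
    """
    n, m = len(query), len(subject)
    NEG = -(10**9)
    M: dict[tuple[int, int], int] = {}
    Ix: dict[tuple[int, int], int] = {}
    Iy: dict[tuple[int, int], int] = {}
    ptr: dict[tuple[str, int, int], tuple[str, int, int] | None] = {}
    best_score, best_cell = 0, None
    for i in range(1, n + 1):
        j_lo = max(1, i - diag - band)
        j_hi = min(m, i - diag + band)
        for j in range(j_lo, j_hi + 1):
            sub = blosum62(query[i - 1], subject[j - 1])
            candidates = [
                (0, None),
                (M.get((i - 1, j - 1), NEG), ("M", i - 1, j - 1)),
                (Ix.get((i - 1, j - 1), NEG), ("X", i - 1, j - 1)),
                (Iy.get((i - 1, j - 1), NEG), ("Y", i - 1, j - 1)),
            ]
            pv, psrc = max(candidates, key=lambda t: t[0])
            m_score = pv + sub
            if m_score > 0:
                M[(i, j)] = m_score
                ptr[("M", i, j)] = psrc
                if m_score > best_score:
                    best_score, best_cell = m_score, (i, j)
            # gap in subject: consume a query residue
            x_open = M.get((i - 1, j), NEG) - gap_open
            x_ext = Ix.get((i - 1, j), NEG) - gap_extend
            if max(x_open, x_ext) > NEG // 2:
                if x_open >= x_ext:
                    Ix[(i, j)] = x_open
                    ptr[("X", i, j)] = ("M", i - 1, j)
                else:
                    Ix[(i, j)] = x_ext
                    ptr[("X", i, j)] = ("X", i - 1, j)
            # gap in query: consume a subject residue
            y_open = M.get((i, j - 1), NEG) - gap_open
            y_ext = Iy.get((i, j - 1), NEG) - gap_extend
            if max(y_open, y_ext) > NEG // 2:
                if y_open >= y_ext:
                    Iy[(i, j)] = y_open
                    ptr[("Y", i, j)] = ("M", i, j - 1)
                else:
                    Iy[(i, j)] = y_ext
                    ptr[("Y", i, j)] = ("Y", i, j - 1)
    if best_cell is None:
        return 0, 0, 0, 0, 0, 0, 0, 0
    qend, send = best_cell
    state, i, j = "M", best_cell[0], best_cell[1]
    matches = aligned = gap_opens = 0
    qstart = sstart = 0
    while True:
        aligned += 1
        if state == "M" and query[i - 1] == subject[j - 1]:
            matches += 1
        src = ptr[(state, i, j)]
        if src is None:  # local alignment starts with this M cell
            qstart, sstart = i - 1, j - 1
            break
        pstate, pi, pj = src
        if state in ("X", "Y") and pstate == "M":
            gap_opens += 1
        state, i, j = pstate, pi, pj
    return best_score, qstart, qend, sstart, send, matches, aligned, gap_opens


def _frame_nt_span(frame: int, p_start: int, p_end: int, nt_len: int) -> tuple[int, int]:
    """Map a residue span within a translated frame to forward-strand
    nucleotide coordinates (0-based, half-open)."""
    off = abs(frame) - 1
    s = off + 3 * p_start
    e = off + 3 * p_end
    if frame > 0:
        return s, e
    return nt_len - e, nt_len - s


def extend_hit(
    seed: Seed,
    query: str,
    frames: Mapping[int, str],
    nt_len: int,
    gap_open: int = 11,
    gap_extend: int = 1,
    band: int = 12,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Banded local (Smith-Waterman) extension around a seed.

    Returns the maximal-scoring local alignment on the seed's banded
    diagonal; ties resolve to the leftmost, then shortest alignment.
    """
    prot = frames[seed.frame]
    diag = seed.query_pos - seed.frame_pos
    score, qs, qe, ss, se, matches, aligned, gap_opens = _banded_sw(
        query, prot, diag, band, gap_open, gap_extend
    )
    nt_span = _frame_nt_span(seed.frame, ss, se, nt_len)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        frame=seed.frame,
        subject_nt_span=nt_span,
        query_span=(qs, qe),
        score=score,
        pident=100.0 * matches / aligned if aligned else 0.0,
        length=aligned,
        mismatches=aligned - matches,  # non-identical columns, gaps included
        gap_opens=gap_opens,
    )


@dataclass
class RecruitResult:
    reads: ReadSet
    hits: list[AlignmentHit] = field(default_factory=list)
    n_direct: int = 0
    n_mates: int = 0
    queries_used: list[str] = field(default_factory=list)


def _normalize_queries(queries) -> dict[str, str]:
    if isinstance(queries, Mapping):
        out = dict(queries)
    else:
        out = {}
        for item in queries:
            if hasattr(item, "id") and hasattr(item, "seq"):
                out[str(item.id)] = str(item.seq)
            else:
                name, seq = item
                out[str(name)] = str(seq)
    if not out:
        raise InputError("no query proteins given")
    return {k: v.upper() for k, v in out.items()}


def best_hit_for_sequence(
    nucseq: str,
    query: str,
    hood: "DiagonalScorer | None" = None,
    word_size: int = 3,
    neighborhood_min: int = 11,
    gap_open: int = 11,
    gap_extend: int = 1,
    xdrop: int = 20,
    band: int = 12,
    sw_trigger_margin: int = 12,
    min_keep: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Best-scoring alignment of a protein query to any frame of a
    nucleotide sequence, using the two-stage seed/extend machinery."""
    scorer = (
        hood
        if isinstance(hood, DiagonalScorer)
        else DiagonalScorer(query, word_size, neighborhood_min)
    )
    frames = sixframe_translate(nucseq)
    best: AlignmentHit | None = None
    for frame in FRAMES:
        prot = frames[frame]
        seeds = scorer.seeds_for(prot, frame)
        if not seeds:
            continue
        diags = {s.frame_pos - s.query_pos for s in seeds}
        ug_best = scorer.best_ungapped(prot, diags)
        if ug_best < min_keep - sw_trigger_margin:
            continue
        # exact spans/identity from the classic extension around each seed
        top = None
        for seed in seeds:
            ug, qs, qe, ss, se = ungapped_extend(
                query, prot, seed.query_pos, seed.frame_pos, word_size, xdrop
            )
            if top is None or ug > top[0]:
                top = (ug, qs, qe, ss, se, seed)
        ug, qs, qe, ss, se, seed = top
        if ug < min_keep:
            gapped = extend_hit(
                seed, query, frames, len(nucseq), gap_open, gap_extend, band,
                query_id=query_id, subject_id=subject_id,
            )
            if gapped.score > 0 and (best is None or gapped.score > best.score):
                best = gapped
            continue
        matches = sum(1 for t in range(qe - qs) if query[qs + t] == prot[ss + t])
        hit = AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            frame=frame,
            subject_nt_span=_frame_nt_span(frame, ss, se, len(nucseq)),
            query_span=(qs, qe),
            score=ug,
            pident=100.0 * matches / (qe - qs) if qe > qs else 0.0,
            length=qe - qs,
            mismatches=(qe - qs) - matches,
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def recruit_reads(
    queries,
    reads: ReadSet,
    min_score: int = 35,
    iterations: int = 1,
    word_size: int = 3,
    neighborhood_min: int = 11,
    gap_open: int = 11,
    gap_extend: int = 1,
    xdrop: int = 20,
    keep_hits: bool = False,
) -> RecruitResult:
    """Recruit reads homologous to any query protein, closed under mates.

    With ``iterations > 1`` the recruited reads are assembled between
    rounds and contig ORF translations join the query set, so divergent
    flanks reachable only through assembled sequence are also collected.
    """
    qdict = _normalize_queries(queries)
    reads.validate()
    current_queries = dict(qdict)
    recruited_ids: set[str] = set()
    direct_ids: set[str] = set()
    all_hits: list[AlignmentHit] = []

    for _round in range(max(1, iterations)):
        scorers = {
            name: DiagonalScorer(q, word_size, neighborhood_min)
            for name, q in current_queries.items()
        }
        for read in reads:
            if read.read_id in direct_ids:
                continue
            frames = sixframe_translate(read.sequence)
            hit_found = False
            for qname, q in current_queries.items():
                scorer = scorers[qname]
                for frame in FRAMES:
                    prot = frames[frame]
                    seeds = scorer.seeds_for(prot)
                    if not seeds:
                        continue
                    diags = {s.frame_pos - s.query_pos for s in seeds}
                    score = scorer.best_ungapped(prot, diags)
                    if min_score - 4 <= score < min_score:
                        # borderline: allow a gapped rescue around a seed
                        gapped = extend_hit(
                            seeds[0]._replace(frame=frame), q, frames,
                            len(read.sequence), gap_open, gap_extend, band=8,
                            query_id=qname, subject_id=read.read_id,
                        )
                        score = max(score, gapped.score)
                    if score >= min_score:
                        hit_found = True
                        if keep_hits:
                            best_seed = None
                            for s in seeds:
                                ug, qs, qe, ss, se = ungapped_extend(
                                    q, prot, s.query_pos, s.frame_pos,
                                    word_size, xdrop,
                                )
                                if best_seed is None or ug > best_seed[0]:
                                    best_seed = (ug, qs, qe, ss, se)
                            ug, qs, qe, ss, se = best_seed
                            matches = sum(
                                1 for t in range(qe - qs) if q[qs + t] == prot[ss + t]
                            )
                            all_hits.append(
                                AlignmentHit(
                                    query_id=qname,
                                    subject_id=read.read_id,
                                    frame=frame,
                                    subject_nt_span=_frame_nt_span(
                                        frame, ss, se, len(read.sequence)
                                    ),
                                    query_span=(qs, qe),
                                    score=max(ug, score),
                                    pident=100.0 * matches / (qe - qs) if qe > qs else 0.0,
                                    length=qe - qs,
                                    mismatches=(qe - qs) - matches,
                                )
                            )
                        break
                if hit_found:
                    break
            if hit_found:
                direct_ids.add(read.read_id)

        recruited_ids = set(direct_ids)
        for rid in list(direct_ids):
            recruited_ids.add(reads.get(rid).mate_id)

        if _round + 1 < iterations:
            from .assemble import greedy_assemble
            from .annotate import find_orfs

            sub = reads.subset(recruited_ids)
            asm = greedy_assemble(sub)
            for contig in asm.contigs:
                orfs = find_orfs(contig.sequence, min_len=150, require_atg=False)
                for idx, orf in enumerate(orfs[:2]):
                    current_queries[f"round{_round}_{contig.contig_id}_orf{idx}"] = orf.protein

    result_set = reads.subset(recruited_ids)
    return RecruitResult(
        reads=result_set,
        hits=all_hits,
        n_direct=len(direct_ids),
        n_mates=len(recruited_ids) - len(direct_ids),
        queries_used=sorted(current_queries),
    )


def hits_to_tsv(
    hits: Sequence[AlignmentHit], path, query_lengths: Mapping[str, int] | None = None,
    db_len_nt: int = 0, include_evalue: bool = False,
) -> None:
    """Write hits in a BLAST-tabular-like 12-column layout."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "frame", "score",
    ]
    if include_evalue:
        cols.append("evalue")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            row = [
                h.query_id, h.subject_id, f"{h.pident:.1f}", str(h.length),
                str(h.mismatches), str(h.gap_opens),
                str(h.query_span[0] + 1), str(h.query_span[1]),
                str(h.subject_nt_span[0] + 1), str(h.subject_nt_span[1]),
                str(h.frame), str(h.score),
            ]
            if include_evalue:
                qlen = (query_lengths or {}).get(h.query_id, 0)
                row.append(f"{h.evalue(qlen, db_len_nt):.2g}")
            fh.write("\t".join(row) + "\n")
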