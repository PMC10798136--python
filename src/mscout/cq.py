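"""Chromosome Quotient (CQ): male-specificity of candidate sequences.

The CQ of a candidate sequence is the number of female read hits divided by
the number of male read hits. A sequence on the male-specific (hemizygous)
M haplotype collects essentially no female hits (CQ ~ 0), whereas an
autosomal sequence is hit equally by both sexes (CQ ~ 1). Counting uses a
k-mer-seeded, banded alignment of each read against the candidate on either
strand, a deliberate proxy for a short-read mapper run with defaults.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import edlib
import pandas as pd

from ._util import revcomp
from .errors import InputError
from .simulate import ReadSet

log = logging.getLogger(__name__)

MALE_SPECIFIC = "male_specific"
AUTOSOMAL_LIKE = "autosomal_like"
UNDETERMINED = "undetermined"
NO_DATA = "no_data"

_DNA_OK = set("ACGTN")


@dataclass(frozen=True)
class HitParams:
    """Read-vs-candidate hit criteria.

    A read hits a candidate if a seeded, banded alignment on either strand
    reaches ``min_identity`` over at least ``min_read_coverage`` of the read.
    """

    kmer_seed_length: int = 21
    min_identity: float = 0.95
    min_read_coverage: float = 0.90

    def validate(self) -> None:
        if self.kmer_seed_length < 11:
            raise InputError("kmer_seed_length must be >= 11")
        if not (0 < self.min_identity <= 1):
            raise InputError("min_identity must be in (0, 1]")
        if not (0 < self.min_read_coverage <= 1):
            raise InputError("min_read_coverage must be in (0, 1]")


@dataclass
class CQResult:
    """Per-candidate hit counts and the derived quotient."""

    seq_name: str
    seq_length: int
    female_hits: int
    male_hits: int
    cq: Optional[float]  # None iff male_hits == 0
    normalized: bool = False
    classification: Optional[str] = None
    flags: list[str] = field(default_factory=list)

    @property
    def cq_rounded(self) -> Optional[float]:
        return None if self.cq is None else round(self.cq, 2)

    def display_cq(self) -> str:
        """Render the quotient the way male-specificity tables print it:
        two decimals, with small-but-nonzero values shown as '<0.01'."""
        if self.cq is None:
            return "NA"
        if 0 < self.cq < 0.01:
            return "<0.01"
        return f"{self.cq:.2f}".rstrip("0").rstrip(".") if self.cq == int(self.cq) else f"{self.cq:.2f}"


def _reference_index(references: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in references.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


def count_hits_multi(
    reads: ReadSet, references: Mapping[str, str], params: HitParams = HitParams()
) -> dict[str, int]:
    """Count hitting reads for several candidate references in one pass.

    Each read is counted at most once per reference; references are scored
    independently (a read may hit more than one candidate).
    """
    params.validate()
    for name, ref in references.items():
        if not ref:
            raise InputError(f"empty reference {name!r}")
        if set(ref.upper()) - _DNA_OK:
            raise InputError(f"reference {name!r} is not DNA over ACGTN")
    if len(reads) == 0:
        log.warning("count_hits called with an empty read set")
        return {name: 0 for name in references}

    k = params.kmer_seed_length
    index = _reference_index({n: s.upper() for n, s in references.items()}, k)
    counts = {name: 0 for name in references}
    ref_seqs = {n: s.upper() for n, s in references.items()}

    for read in reads:
        seq = read.sequence.upper()
        rl = len(seq)
        min_overlap = params.min_read_coverage * rl
        hit_refs: set[str] = set()
        tried: set[tuple[str, str, int]] = set()
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for i in range(0, rl - k + 1):
                postings = index.get(oriented[i : i + k])
                if not postings:
                    continue
                for name, p in postings:
                    if name in hit_refs:
                        continue
                    offset = p - i
                    key = (name, strand, offset)
                    if key in tried or len(tried) > 16:
                        continue
                    tried.add(key)
                    if _offset_hit(oriented, ref_seqs[name], offset, min_overlap, params):
                        hit_refs.add(name)
                if len(hit_refs) == len(references):
                    break
            if len(hit_refs) == len(references):
                break
        for name in hit_refs:
            counts[name] += 1
    return counts


def _offset_hit(read: str, ref: str, offset: int, min_overlap: float, params: HitParams) -> bool:
    """Banded alignment of the read against the reference at a seed offset."""
    rl = len(read)
    ref_start = max(0, offset)
    ref_end = min(len(ref), offset + rl)
    aligned = ref_end - ref_start
    if aligned < min_overlap:
        return False
    read_seg = read[ref_start - offset : ref_end - offset]
    ref_seg = ref[ref_start:ref_end]
    max_dist = int(math.floor((1 - params.min_identity) * aligned))
    res = edlib.align(read_seg, ref_seg, mode="NW", task="distance", k=max_dist)
    return res["editDistance"] != -1


def count_hits(reads: ReadSet, reference: str, params: HitParams = HitParams()) -> int:
    """Number of reads with a qualifying alignment to ``reference``."""
    return count_hits_multi(reads, {"ref": reference}, params)["ref"]


def chromosome_quotient(
    female_hits: int,
    male_hits: int,
    normalizer: float = 1.0,
    seq_name: str = "",
    seq_length: int = 0,
) -> CQResult:
    """CQ = female_hits / male_hits (optionally scaled by a normalizer).

    ``male_hits == 0`` yields an undefined quotient flagged ``no_data``
    rather than an exception: absence of male hits is itself informative.
    """
    if female_hits < 0 or male_hits < 0:
        raise InputError("hit counts must be >= 0")
    if male_hits == 0:
        return CQResult(
            seq_name, seq_length, female_hits, male_hits, cq=None,
            normalized=normalizer != 1.0, classification=NO_DATA,
            flags=["no_male_hits"],
        )
    cq = female_hits / male_hits * normalizer
    return CQResult(
        seq_name, seq_length, female_hits, male_hits, cq=cq,
        normalized=normalizer != 1.0,
    )


def classify_linkage(result: CQResult, min_male_hits: int = 20) -> str:
    """Classify a CQ result: male_specific (CQ < 0.01 with enough male
    evidence), autosomal_like (0.5 <= CQ <= 1.5), no_data (too few male
    hits), else undetermined."""
    if result.cq is None:
        label = NO_DATA
    elif result.cq < 0.01 and result.male_hits >= min_male_hits:
        label = MALE_SPECIFIC
    elif 0.5 <= result.cq <= 1.5:
        label = AUTOSOMAL_LIKE
    elif result.male_hits < min_male_hits:
        label = NO_DATA
    else:
        label = UNDETERMINED
    result.classification = label
    return label


def cq_table(
    male_reads: ReadSet,
    female_reads: ReadSet,
    references: Mapping[str, str],
    params: HitParams = HitParams(),
    min_male_hits: int = 20,
    normalize: bool = False,
) -> pd.DataFrame:
    """CQ for every candidate, as a male-specificity table.

    With ``normalize`` the quotient is scaled by male/female total bases to
    compensate for unequal sequencing effort between the sex pools.
    """
    normalizer = 1.0
    if normalize:
        fb = female_reads.total_bases
        if fb == 0:
            raise InputError("cannot normalize with an empty female read set")
        normalizer = male_reads.total_bases / fb
    m_counts = count_hits_multi(male_reads, references, params)
    f_counts = count_hits_multi(female_reads, references, params)
    rows = []
    for name, seq in references.items():
        res = chromosome_quotient(
            f_counts[name], m_counts[name], normalizer, seq_name=name,
            seq_length=len(seq),
        )
        classify_linkage(res, min_male_hits)
        rows.append(
            {
                "seq_name": name,
                "seq_length": len(seq),
                "female_hits": res.female_hits,
                "male_hits": res.male_hits,
                "CQ": res.display_cq(),
                "classification": res.classification,
            }
        )
    return pd.DataFrame(rows)
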