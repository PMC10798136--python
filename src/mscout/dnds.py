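"""Nei-Gojobori (NG86) dN/dS with pathway averaging on codon alignments.

Synonymous and nonsynonymous sites are counted per codon as the fraction
of the three possible changes at each position that preserve the encoded
amino acid, with stop-creating changes excluded from the denominator, so
every codon contributes exactly three sites. Differences between a codon
pair are averaged over all substitution orderings (pathways), excluding
pathways that pass through a stop codon; if every pathway is blocked the
unrestricted average is used and flagged. Proportions are corrected for
multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).

omega = dN/dS << 1 indicates purifying selection; the inverse ratio dS/dN
is also reported for convenience.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple, Optional

import pandas as pd

from ._util import CODON_TO_AA, DNA
from .errors import InputError, InsufficientAlignmentError

GAP_CHARS = set("-.")


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a sense codon.

    For each position, the fraction of single-nucleotide changes that are
    synonymous among those not creating a stop; S + N == 3 always.
    """
    codon = codon.upper()
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        raise InputError(f"not an unambiguous codon: {codon!r}")
    if aa == "*":
        raise InputError(f"stop codon has no site counts: {codon!r}")
    s_total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in DNA:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = CODON_TO_AA[alt]
            if alt_aa == "*":
                continue
            non_stop += 1
            if alt_aa == aa:
                syn += 1
        if non_stop:
            s_total += syn / non_stop
    return s_total, 3.0 - s_total


class PathwayCounts(NamedTuple):
    sd: float
    nd: float
    all_paths_blocked: bool = False


def pathway_differences(codon_a: str, codon_b: str) -> PathwayCounts:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    For k differing positions the k! substitution orderings are averaged,
    excluding orderings that pass through a stop codon. When every
    ordering is blocked the unrestricted average is returned with
    ``all_paths_blocked`` set.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if CODON_TO_AA.get(c, "*") == "*":
            raise InputError(f"stop or ambiguous codon: {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return PathwayCounts(0.0, 0.0)
    totals = []  # (sd, nd) per unblocked pathway
    totals_all = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*":
                blocked = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        totals_all.append((sd, nd))
        if not blocked:
            totals.append((sd, nd))
    chosen = totals if totals else totals_all
    sd = sum(t[0] for t in chosen) / len(chosen)
    nd = sum(t[1] for t in chosen) / len(chosen)
    return PathwayCounts(sd, nd, all_paths_blocked=not totals)


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class NGCounts:
    """Per-pair NG86 site and difference counts with corrected rates."""

    seq_a: str
    seq_b: str
    n_codons: int
    S: float
    N: float
    sd: float
    nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    flags: list[str] = field(default_factory=list)

    @property
    def ds_dn(self) -> Optional[float]:
        if self.omega is None or self.omega == 0:
            return None
        return 1.0 / self.omega


def _rows_of(alignment) -> list[tuple[str, str]]:
    if isinstance(alignment, dict):
        rows = [(str(k), str(v).upper()) for k, v in alignment.items()]
    else:
        rows = []
        for item in alignment:
            if hasattr(item, "id") and hasattr(item, "seq"):
                rows.append((str(item.id), str(item.seq).upper()))
            else:
                rows.append((str(item[0]), str(item[1]).upper()))
    if len(rows) < 2:
        raise InputError("a codon alignment needs at least two rows")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise InputError("alignment rows have unequal lengths")
    if lengths.pop() % 3 != 0:
        raise InputError("alignment length is not a multiple of 3")
    return rows


def dnds(alignment, pair: tuple = (0, 1)) -> NGCounts:
    """NG86 dN/dS for one pair of rows of a codon alignment.

    Codon columns where either sequence has a gap or ambiguity are
    excluded pairwise. Fewer than 10 comparable codons raises
    InsufficientAlignmentError. omega is None (flagged) when dS == 0 or
    either proportion is saturated.
    """
    rows = _rows_of(alignment)
    names = {name: seq for name, seq in rows}

    def pick(key):
        if isinstance(key, int):
            return rows[key]
        if key in names:
            return key, names[key]
        raise InputError(f"no alignment row {key!r}")

    (name_a, a), (name_b, b) = pick(pair[0]), pick(pair[1])
    S = N = sd = nd = 0.0
    n_codons = 0
    flags: list[str] = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if GAP_CHARS & (set(ca) | set(cb)):
            continue
        if CODON_TO_AA.get(ca, "*") == "*" or CODON_TO_AA.get(cb, "*") == "*":
            continue
        n_codons += 1
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        pc = pathway_differences(ca, cb)
        sd += pc.sd
        nd += pc.nd
        if pc.all_paths_blocked and "stop_blocked_pathways" not in flags:
            flags.append("stop_blocked_pathways")
    if n_codons < 10:
        raise InsufficientAlignmentError(
            f"only {n_codons} comparable codons between {name_a} and {name_b}"
        )
    pS = sd / S if S else 0.0
    pN = nd / N if N else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if dS is None:
        flags.append("dS_saturated")
    if dN is None:
        flags.append("dN_saturated")
    omega = None
    if dS is not None and dN is not None:
        if dS == 0:
            flags.append("omega_undefined_dS_zero")
        else:
            omega = dN / dS
    return NGCounts(
        name_a, name_b, n_codons, S, N, sd, nd, pS, pN, dS, dN, omega, flags
    )


def dnds_matrix(alignment) -> pd.DataFrame:
    """All pairwise NG86 estimates of a codon alignment, one row per pair."""
    rows = _rows_of(alignment)
    out = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            r = dnds(rows, (i, j))
            out.append(
                {
                    "seq_a": r.seq_a,
                    "seq_b": r.seq_b,
                    "n_codons": r.n_codons,
                    "S": r.S,
                    "N": r.N,
                    "sd": r.sd,
                    "nd": r.nd,
                    "pS": r.pS,
                    "pN": r.pN,
                    "dS": r.dS,
                    "dN": r.dN,
                    "omega": r.omega,
                    "ds_dn": r.ds_dn,
                    "flags": ";".join(r.flags),
                }
            )
    return pd.DataFrame(out)
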