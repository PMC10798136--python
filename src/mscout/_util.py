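"""Shared sequence utilities: translation, reverse complement, scoring."""

from __future__ import annotations

import hashlib
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

DNA = "ACGT"
_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_b62 = substitution_matrices.load("BLOSUM62")
#: BLOSUM62 as a plain dict keyed by residue pairs; unknown pairs score -4.
BLOSUM62: dict[tuple[str, str], int] = {}
for _a in _b62.alphabet:
    for _b in _b62.alphabet:
        BLOSUM62[(_a, _b)] = int(_b62[_a, _b])


def blosum62(a: str, b: str) -> int:
    return BLOSUM62.get((a, b), -4)


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string; codons containing N/other letters yield X,
    trailing partial codons are dropped, stops are '*'."""
    n = len(seq) - len(seq) % 3
    out = []
    for i in range(0, n, 3):
        out.append(CODON_TO_AA.get(seq[i : i + 3], "X"))
    return "".join(out)


@lru_cache(maxsize=None)
def preferred_substitutions(aa: str) -> tuple[str, ...]:
    """Residues that exchange favourably with ``aa`` under BLOSUM62.

    Positive-score partners (excluding identity); if none exist (e.g. C,
    whose only positive score is with itself) the top-scoring non-identical
    residues are used instead.
    """
    scored = sorted(
        ((blosum62(aa, x), x) for x in AA20 if x != aa), reverse=True
    )
    positive = tuple(x for s, x in scored if s > 0)
    if positive:
        return positive
    best = scored[0][0]
    return tuple(x for s, x in scored if s == best)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=n))


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def derive_seed(base_seed: int, *tokens) -> int:
    """Derive a deterministic 31-bit child seed from a base seed and tokens."""
    material = repr((int(base_seed), tokens)).encode()
    return int.from_bytes(hashlib.sha256(material).digest()[:4], "big") % (2**31)
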