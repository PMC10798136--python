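"""Protein distances, BIONJ trees, bootstrap support, clade contrasts.

BIONJ is neighbour joining with a variance-weighted reduction of the
distance matrix: when nodes i and j are joined into u, the distances from
u are the convex combination lambda*d(i,k) + (1-lambda)*d(j,k) (after
subtracting the branch estimates), with lambda chosen to minimise the
variance of the reduced distances. Like NJ it is exact on additive
matrices — the tree it returns reproduces every pairwise distance as a
path length. Branch lengths are in substitutions per site when the
distances are.

Trees are Bio.Phylo objects, so Newick round-tripping, traversal and
rooting come from Biopython; support values are attached as internal-node
confidences in [0, 100].
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .errors import InputError

log = logging.getLogger(__name__)

GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with taxon labels."""

    labels: list[str]
    data: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")

    def validate(self) -> None:
        d = self.data
        if not np.allclose(d, d.T, atol=1e-12):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise InputError("distance matrix has negative entries")
        if not np.all(np.isfinite(d)):
            raise InputError(
                "distance matrix has non-finite entries (saturated pairs "
                "must be excluded, not clamped)"
            )

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.data):
                fh.write(lab + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")


def _msa_rows(msa) -> list[tuple[str, str]]:
    if isinstance(msa, Mapping):
        rows = [(str(k), str(v).upper()) for k, v in msa.items()]
    else:
        rows = []
        for item in msa:
            if hasattr(item, "id") and hasattr(item, "seq"):
                rows.append((str(item.id), str(item.seq).upper()))
            else:
                rows.append((str(item[0]), str(item[1]).upper()))
    if len(rows) < 3:
        raise InputError("need at least three alignment rows")
    if len({len(s) for _, s in rows}) != 1:
        raise InputError("alignment rows have unequal lengths")
    return rows


def pairwise_distance(msa, model: str = "poisson") -> DistanceMatrix:
    """p-distance or Poisson-corrected distance matrix from a protein MSA.

    Gap columns are deleted pairwise. Pairs with p >= 1 under the Poisson
    model are flagged saturated and set non-finite (the caller decides how
    to exclude them). A pair with zero comparable columns is an error.
    """
    if model not in ("p", "poisson"):
        raise InputError(f"unknown distance model {model!r}")
    rows = _msa_rows(msa)
    labels = [name for name, _ in rows]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate taxon labels")
    n = len(rows)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i][1], rows[j][1]
            comparable = mismatch = 0
            for x, y in zip(a, b):
                if x in GAP_CHARS or y in GAP_CHARS:
                    continue
                comparable += 1
                if x != y:
                    mismatch += 1
            if comparable == 0:
                raise InputError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = mismatch / comparable
            if model == "p":
                dist = p
            else:
                if p >= 1:
                    saturated.append((labels[i], labels[j]))
                    dist = np.inf
                else:
                    dist = -np.log(1 - p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d, saturated)


def bionj(dist: DistanceMatrix) -> Tree:
    """BIONJ agglomeration of a distance matrix into an unrooted tree.

    Joins minimise the neighbour-joining Q criterion with the BIONJ
    variance-weighted matrix reduction; equal Q values resolve to the
    smallest (label, label) pair. Negative branch-length estimates are set
    to zero with the deficit transferred to the sibling branch (logged).
    The returned tree has a trifurcating root, i.e. it is unrooted.
    """
    dist.validate()
    n = len(dist.labels)
    if n < 3:
        raise InputError("need at least three taxa")
    d = dist.data.astype(float).copy()
    v = d.copy()  # BIONJ initial variances equal the distances
    nodes: list[Clade] = [Clade(name=lab) for lab in dist.labels]
    names: list[str] = list(dist.labels)  # tie-break keys per active node
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                pair_key = tuple(sorted((names[active[ai]], names[active[aj]])))
                cand = (q, pair_key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        bi = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:
            log.debug("negative branch %.4g at %s transferred", bi, names[i])
            bj += bi
            bi = 0.0
        if bj < 0:
            log.debug("negative branch %.4g at %s transferred", bj, names[j])
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        vij = v[i, j]
        others = [a for a in active if a != i and a != j]
        if vij > 0:
            lam = 0.5 + sum(v[j, k] - v[i, k] for k in others) / (2 * (m - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        new_clade = Clade()
        ci, cj = nodes[i], nodes[j]
        ci.branch_length = float(bi)
        cj.branch_length = float(bj)
        new_clade.clades = [ci, cj]
        # reuse slot i for the merged node
        for k in others:
            dk = lam * (d[i, k] - bi) + (1 - lam) * (d[j, k] - bj)
            vk = lam * v[i, k] + (1 - lam) * v[j, k] - lam * (1 - lam) * vij
            d[i, k] = d[k, i] = max(dk, 0.0)
            v[i, k] = v[k, i] = vk
        nodes[i] = new_clade
        names[i] = min(names[i], names[j])
        active.remove(j)

    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    bi = (dij + dik - djk) / 2
    bj = (dij + djk - dik) / 2
    bk = (dik + djk - dij) / 2
    for node, b in ((nodes[i], bi), (nodes[j], bj), (nodes[k], bk)):
        node.branch_length = float(max(b, 0.0))
    order = sorted((i, j, k), key=lambda x: names[x])
    root = Clade(clades=[nodes[x] for x in order])
    return Tree(root=root, rooted=False)


def tree_to_newick(tree: Tree) -> str:
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick", format_branch_length="%.12g")
    return buf.getvalue().strip()


def newick_to_tree(newick: str) -> Tree:
    return Phylo.read(io.StringIO(newick), "newick")


def tip_names(clade: Clade) -> frozenset:
    return frozenset(t.name for t in clade.get_terminals())


def bipartitions(tree: Tree) -> dict[frozenset, Clade]:
    """Non-trivial bipartitions of an unrooted tree, keyed by the tip-name
    side not containing the reference (alphabetically first) taxon."""
    all_tips = tip_names(tree.root)
    ref = min(all_tips)
    out: dict[frozenset, Clade] = {}
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = tip_names(clade)
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        key = side if ref not in side else all_tips - side
        out[key] = clade
    return out


def bootstrap_support(
    msa, n_reps: int = 1000, seed: int = 0, model: str = "poisson"
) -> Tree:
    """BIONJ tree with column-resampling bootstrap supports (percent).

    The alignment columns are resampled with replacement n_reps times, a
    BIONJ tree is built per replicate, and each internal bipartition of
    the original tree receives the percentage of replicates containing it.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    rows = _msa_rows(msa)
    ncol = len(rows[0][1])
    tree = bionj(pairwise_distance(rows, model))
    parts = bipartitions(tree)
    counts = {key: 0 for key in parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = [(name, "".join(seq[c] for c in cols)) for name, seq in rows]
        try:
            rep_tree = bionj(pairwise_distance(resampled, model))
        except InputError:
            continue  # e.g. a replicate with a saturated pair
        rep_parts = set(bipartitions(rep_tree))
        for key in counts:
            if key in rep_parts:
                counts[key] += 1
    for key, clade in parts.items():
        clade.confidence = 100.0 * counts[key] / n_reps
    return tree


def _depths_from(clade: Clade) -> dict[str, float]:
    """Path length from ``clade`` (exclusive of its own branch) to each tip."""
    out: dict[str, float] = {}

    def walk(c: Clade, acc: float):
        if c.is_terminal():
            out[c.name] = acc
        for child in c.clades:
            walk(child, acc + (child.branch_length or 0.0))

    walk(clade, 0.0)
    return out


def clade_branch_contrast(
    tree: Tree, clade_a: Sequence[str], clade_b: Sequence[str]
) -> tuple[float, float, float]:
    """Mean tip path length of two sister clades and their ratio.

    The tree is conceptually rooted at the edge separating the two taxon
    sets; each clade's mean is measured from its own attachment node, so
    the separating branch contributes to neither side. Returns
    (mean_a, mean_b, mean_a / mean_b).
    """
    set_a, set_b = set(clade_a), set(clade_b)
    all_tips = set(tip_names(tree.root))
    if set_a & set_b:
        raise InputError(f"clades overlap: {sorted(set_a & set_b)}")
    missing = (set_a | set_b) - all_tips
    if missing:
        raise InputError(f"taxa not in tree: {sorted(missing)}")
    if set_a | set_b != all_tips:
        raise InputError(
            f"clades must partition the tips; missing {sorted(all_tips - set_a - set_b)}"
        )

    target = None
    for clade in tree.find_clades():
        if clade is tree.root:
            continue
        side = set(tip_names(clade)) if not clade.is_terminal() else {clade.name}
        if side == set_a or side == set_b:
            target = clade
            target_side = side
            break
    if target is None:
        raise InputError(
            f"no edge separates {sorted(set_a)} from {sorted(set_b)}: "
            "the sets do not form connected subtrees"
        )
    # the separating branch (above `target`) contributes to neither mean:
    # each clade is measured from its own endpoint of that edge
    path = tree.get_path(target)
    parent = tree.root if len(path) < 2 else path[-2]
    inside = _depths_from(target)
    mean_inside = sum(inside.values()) / len(inside)
    if parent is tree.root and len(tree.root.clades) == 2 and target in tree.root.clades:
        # rooted input: the separating edge is split across the root, so
        # the outside clade is measured from its own root-child node
        sibling = next(c for c in tree.root.clades if c is not target)
        out = _depths_from(sibling)
        mean_outside = sum(out.values()) / len(out)
    else:
        outside_tips = [
            t for t in tree.get_terminals() if t.name not in target_side
        ]
        mean_outside = sum(
            tree.distance(parent, t) for t in outside_tips
        ) / len(outside_tips)
    if target_side == set_a:
        ma, mb = mean_inside, mean_outside
    else:
        ma, mb = mean_outside, mean_inside
    return ma, mb, (ma / mb if mb else float("inf"))
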