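"""Test utilities: random additive trees and brute-force least-squares
topology search, independent of the package's own tree code."""

from __future__ import annotations

import heapq
import itertools

import numpy as np


def random_additive_tree(n: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths.

    Returns (labels, distance_matrix, bipartitions) where bipartitions is
    the set of non-trivial splits as frozensets of the side not containing
    the first label.
    """
    adj: dict[str, list[tuple[str, float]]] = {}

    def add_edge(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def del_edge(a, b):
        adj[a] = [(x, w) for x, w in adj[a] if x != b]
        adj[b] = [(x, w) for x, w in adj[b] if x != a]

    leaves = ["T1", "T2", "T3"]
    for leaf in leaves:
        add_edge(leaf, "x0", float(rng.uniform(0.05, 1.0)))
    internal = 1
    for i in range(4, n + 1):
        edges = sorted(
            {tuple(sorted((u, v))) for u in adj for v, _ in adj[u]}
        )
        a, b = edges[int(rng.integers(0, len(edges)))]
        w = next(w for x, w in adj[a] if x == b)
        del_edge(a, b)
        mid = f"x{internal}"
        internal += 1
        w1 = w * float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w1)
        add_edge(mid, b, w - w1)
        leaf = f"T{i}"
        add_edge(leaf, mid, float(rng.uniform(0.05, 1.0)))
        leaves.append(leaf)

    D = np.zeros((n, n))
    for i, s in enumerate(leaves):
        dist = {s: 0.0}
        pq = [(0.0, s)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist.get(u, np.inf):
                continue
            for v, w in adj[u]:
                nd = d + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(pq, (nd, v))
        for j, t in enumerate(leaves):
            D[i, j] = dist[t]

    ref = leaves[0]
    splits = set()
    for u in adj:
        for v, _ in adj[u]:
            if u.startswith("x") and v.startswith("x") and u < v:
                side = _component_tips(adj, v, u)
                if ref in side:
                    side = frozenset(leaves) - side
                if 2 <= len(side) <= n - 2:
                    splits.add(frozenset(side))
    return leaves, D, splits


def _component_tips(adj, start, blocked):
    seen = {blocked, start}
    stack = [start]
    tips = set()
    while stack:
        u = stack.pop()
        if not u.startswith("x"):
            tips.add(u)
        for v, _ in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return frozenset(tips)


def enumerate_topologies(labels):
    """All unrooted binary leaf-labelled topologies as edge structures.

    Each topology is a dict: node -> neighbours; internal nodes are ints,
    leaves are their labels. Built by sequential edge insertion.
    """
    first = {
        "edges": [(labels[0], "i0"), (labels[1], "i0"), (labels[2], "i0")],
        "next_internal": 1,
    }
    topologies = [first]
    for leaf in labels[3:]:
        new_list = []
        for topo in topologies:
            for k, (a, b) in enumerate(topo["edges"]):
                mid = f"i{topo['next_internal']}"
                edges = list(topo["edges"])
                edges.pop(k)
                edges += [(a, mid), (mid, b), (leaf, mid)]
                new_list.append(
                    {"edges": edges, "next_internal": topo["next_internal"] + 1}
                )
        topologies = new_list
    return topologies


def topology_splits(topo, labels):
    ref = labels[0]
    adj: dict[str, list[str]] = {}
    for a, b in topo["edges"]:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    splits = set()
    for a, b in topo["edges"]:
        if a.startswith("i") and b.startswith("i"):
            seen = {a, b}
            stack = [b]
            tips = set()
            while stack:
                u = stack.pop()
                if not u.startswith("i"):
                    tips.add(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            side = frozenset(tips)
            if ref in side:
                side = frozenset(labels) - side
            if 2 <= len(side) <= len(labels) - 2:
                splits.add(side)
    return splits


def least_squares_fit(topo, labels, D):
    """Ordinary least-squares branch lengths for a fixed topology; returns
    the residual sum of squares."""
    adj: dict[str, list[tuple[str, int]]] = {}
    for idx, (a, b) in enumerate(topo["edges"]):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(topo["edges"])))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        path = _edge_path(adj, labels[i], labels[j])
        A[row, path] = 1.0
        y[row] = D[i, j]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ coef - y
    return float(resid @ resid)


def _edge_path(adj, start, goal):
    prev = {start: (None, None)}
    stack = [start]
    while stack:
        u = stack.pop()
        if u == goal:
            break
        for v, idx in adj[u]:
            if v not in prev:
                prev[v] = (u, idx)
                stack.append(v)
    path = []
    u = goal
    while prev[u][0] is not None:
        path.append(prev[u][1])
        u = prev[u][0]
    return path


def best_ls_topology_splits(labels, D):
    """Splits of the minimum-RSS topology over the full enumeration."""
    best_rss, best_splits = None, None
    for topo in enumerate_topologies(labels):
        rss = least_squares_fit(topo, labels, D)
        if best_rss is None or rss < best_rss - 1e-12:
            best_rss, best_splits = rss, topology_splits(topo, labels)
    return best_splits, best_rss
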