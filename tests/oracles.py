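"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by the most direct method available
(exhaustive enumeration, naive scanning, dense grids, closed forms) without
touching the library code paths it is used to check.
"""

from __future__ import annotations

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def glx_region_bruteforce(protein: str, min_len: int, min_density: float):
    """O(n^2) scan over all substrings: longest with Q+E density >= t,
    ties broken toward the smaller start."""
    n = len(protein)
    is_glx = np.fromiter((1.0 if aa in "QE" else 0.0 for aa in protein), float, n)
    prefix = np.concatenate([[0.0], np.cumsum(is_glx)])
    best = None  # (length, start0)
    for i in range(n):
        for j in range(i + 1, n + 1):
            length = j - i
            if (prefix[j] - prefix[i]) / length >= min_density:
                if best is None or length > best[0]:
                    best = (length, i)
    if best is None or best[0] < min_len:
        return None
    length, i = best
    density = float(prefix[i + length] - prefix[i]) / length
    return (i + 1, i + length, density)


def count_exact_naive(window: str, reads) -> int:
    """Naive O(n*m) substring scan on both strands, one count per read."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = window.translate(comp)[::-1]

    def contains(hay: str, needle: str) -> bool:
        return any(hay[i : i + len(needle)] == needle
                   for i in range(len(hay) - len(needle) + 1))

    n = 0
    for r in reads:
        seq = r.seq if hasattr(r, "seq") else r
        if contains(seq, window) or contains(seq, rc):
            n += 1
    return n


def pi_grid(protein: str, pka: dict, step: float = 1e-4) -> float:
    """Dense-grid zero crossing of the Henderson-Hasselbalch charge curve."""
    ph = np.arange(0.0, 14.0 + step, step)
    pos = 10 ** pka["Nterm"] / (10 ** pka["Nterm"] + 10**ph)
    for aa in ("H", "K", "R"):
        pos = pos + protein.count(aa) * 10 ** pka[aa] / (10 ** pka[aa] + 10**ph)
    neg = 10**ph / (10 ** pka["Cterm"] + 10**ph)
    for aa in ("D", "E", "C", "Y"):
        neg = neg + protein.count(aa) * 10**ph / (10 ** pka[aa] + 10**ph)
    q = pos - neg
    idx = int(np.argmin(np.abs(q)))
    return float(ph[idx])


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary topology with positive branch lengths.

    Returns (splits, distance_matrix, labels): splits is the set of
    non-trivial bipartitions (frozensets of the canonical side), distances
    are exact path sums (additive by construction).
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    # start from a 3-leaf star, attach remaining leaves to random edges
    nodes = {0: None}
    import itertools

    # represent the tree as an adjacency dict with branch lengths
    adj: dict = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def del_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    counter = itertools.count(n_leaves)  # internal node ids
    root = next(counter)
    for leaf in (0, 1, 2):
        add_edge(root, leaf, float(rng.uniform(0.05, 0.5)))
    for leaf in range(3, n_leaves):
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        mid = next(counter)
        del_edge(a, b)
        split = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, w * split)
        add_edge(mid, b, w * (1 - split))
        add_edge(mid, leaf, float(rng.uniform(0.05, 0.5)))

    # pairwise path distances by BFS
    def dist_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        di = dist_from(i)
        for j in range(i + 1, n_leaves):
            D[i, j] = D[j, i] = di[j]  # mirrored: exactly symmetric

    # bipartitions: removing each internal edge
    all_leaves = frozenset(labels)

    def leaves_beyond(u, banned):
        out = set()
        stack = [u]
        seen = {banned, u}
        while stack:
            x = stack.pop()
            if x < n_leaves:
                out.add(labels[x])
            for v in adj[x]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(out)

    splits = set()
    for a in adj:
        for b in adj[a]:
            if a < b and a >= n_leaves and b >= n_leaves:
                side = leaves_beyond(a, b)
                if 1 < len(side) < n_leaves - 1:
                    splits.add(min(side, all_leaves - side,
                                   key=lambda s: (len(s), tuple(sorted(s)))))
    return splits, D, labels


def tree_splits(tree, labels) -> set:
    """Non-trivial bipartitions of a skbio TreeNode, canonical side."""
    all_leaves = frozenset(labels)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(min(side, all_leaves - side,
                           key=lambda s: (len(s), tuple(sorted(s)))))
    return splits


def random_protein(rng: np.random.Generator, n: int, weights=None) -> str:
    p = weights if weights is not None else None
    return "".join(rng.choice(list(AA20), size=n, p=p))
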