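"""Independent reference implementations used only to check the package.

These deliberately share no code with genefam: a plain full-matrix
Smith–Waterman scorer, and an exhaustive unrooted-topology enumerator for
additive-matrix tests.
"""

from __future__ import annotations

import itertools

import numpy as np


def sw_score_oracle(a: str, b: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Best local alignment score by brute-force Gotoh recursion over the
    full matrix (gap of length k costs open + k*extend)."""
    la, lb = len(a), len(b)
    NEG = float("-inf")
    h = np.zeros((la + 1, lb + 1))
    e = np.full((la + 1, lb + 1), NEG)
    f = np.full((la + 1, lb + 1), NEG)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            e[i][j] = max(h[i - 1][j] - gap_open - gap_extend,
                          e[i - 1][j] - gap_extend)
            f[i][j] = max(h[i][j - 1] - gap_open - gap_extend,
                          f[i][j - 1] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


# ---------------------------------------------------------------------------
# unrooted topology enumeration
# ---------------------------------------------------------------------------

class _Tree:
    """Unrooted tree as an adjacency map over integer node ids; leaves carry
    labels."""

    def __init__(self) -> None:
        self.adj: dict[int, set[int]] = {}
        self.label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = set()
        if label is not None:
            self.label[nid] = label
        return nid

    def connect(self, u: int, v: int) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)

    def disconnect(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def copy(self) -> "_Tree":
        t = _Tree()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.label = dict(self.label)
        t._next = self._next
        return t


def enumerate_topologies(labels: list[str]) -> list[_Tree]:
    """All distinct unrooted binary topologies over the labels
    (1, 3, 15, 105 ... for 3, 4, 5, 6 leaves)."""
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    base = _Tree()
    center = base.new_node()
    for lbl in labels[:3]:
        leaf = base.new_node(lbl)
        base.connect(center, leaf)
    trees = [base]
    for lbl in labels[3:]:
        grown: list[_Tree] = []
        for t in trees:
            for u, v in t.edges():
                t2 = t.copy()
                t2.disconnect(u, v)
                mid = t2.new_node()
                leaf = t2.new_node(lbl)
                t2.connect(u, mid)
                t2.connect(mid, v)
                t2.connect(mid, leaf)
                grown.append(t2)
        trees = grown
    return trees


def tree_distance_matrix(
    tree: _Tree, labels: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Additive leaf-distance matrix from random positive edge lengths."""
    lengths = {e: rng.uniform(0.5, 2.0) for e in tree.edges()}

    def elen(u: int, v: int) -> float:
        return lengths[(u, v) if u < v else (v, u)]

    leaf_of = {lbl: nid for nid, lbl in tree.label.items()}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        # BFS path length
        start, goal = leaf_of[labels[i]], leaf_of[labels[j]]
        stack = [(start, -1, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node == goal:
                d[i, j] = d[j, i] = dist
                break
            for nxt in tree.adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, dist + elen(node, nxt)))
    return d


def tree_bipartitions(tree: _Tree, labels: list[str]) -> set[frozenset[str]]:
    """Non-trivial splits, canonicalized as the side without min(labels)."""
    all_set = set(labels)
    ref = min(all_set)
    out: set[frozenset[str]] = set()
    for u, v in tree.edges():
        # leaves on v's side when edge (u, v) is cut
        side: set[str] = set()
        stack = [(v, u)]
        while stack:
            node, prev = stack.pop()
            if node in tree.label:
                side.add(tree.label[node])
            for nxt in tree.adj[node]:
                if nxt != prev:
                    stack.append((nxt, node))
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(all_set) - 1:
            out.add(frozenset(side))
    return out
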