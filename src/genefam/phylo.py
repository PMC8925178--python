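"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap
supports, and anchor-based subfamily assignment.

The family tree is built with Saitou–Nei neighbor joining on pairwise
protein distances (Poisson-corrected by default, plain p-distance
selectable).  Supports come from column-resampling bootstrap; subfamily
labels propagate from reference anchors (e.g. the named VQ subfamilies
VQI–VQVII of Arabidopsis and rice) to unlabeled leaves through the smallest
anchored clade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .core_io import Alignment, SequenceSet

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "p_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "assign_subfamilies",
    "progressive_align",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix asymmetric beyond tolerance")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    """An (arbitrarily rooted) tree with branch lengths and optional
    bootstrap supports on internal edges."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def newick(self, support_scale: float | None = None) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                s = node.support
                if support_scale is not None:
                    s = round(s * support_scale)
                label = str(s)
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized as the side *not*
        containing the lexicographically smallest leaf."""
        all_leaves = set(self.leaf_names)
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = {leaf.name for leaf in node.leaves()}
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(frozenset(side))
        return out

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (sums of branch lengths)."""
        names = sorted(self.leaf_names)
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def below(node: TreeNode) -> dict[str, float]:
            # distances from node to each leaf beneath it
            if node.is_leaf:
                return {node.name: 0.0}
            dists: dict[str, float] = {}
            groups: list[dict[str, float]] = []
            for c in node.children:
                sub = {k: v + c.length for k, v in below(c).items()}
                groups.append(sub)
                dists.update(sub)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a, da in groups[i].items():
                        for b, db in groups[j].items():
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
            return dists

        below(self.root)
        return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def p_distance(
    row_a: str, row_b: str, correction: Literal[None, "poisson"] = None
) -> float:
    """Fraction of differing sites over gap-free columns, optionally with
    the Poisson multiple-hit correction ``-ln(1 - p)``."""
    if len(row_a) != len(row_b):
        raise ValueError("rows have unequal length")
    compared = diffs = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a == "-" or b == "-":
            continue
        compared += 1
        if a != b:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable (gap-free) columns")
    p = diffs / compared
    if correction == "poisson":
        # saturated rows would be infinite; clamp just inside the domain
        return -math.log(max(1.0 - p, 1e-6))
    return p


def distance_matrix(
    aln: Alignment, model: Literal["p", "poisson"] = "poisson"
) -> DistanceMatrix:
    labels = [rid for rid, _ in aln.rows]
    n = len(labels)
    d = np.zeros((n, n))
    corr = "poisson" if model == "poisson" else None
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(aln.rows[i][1], aln.rows[j][1], corr)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    At each step the pair minimizing the Q-criterion is joined (ties broken
    by the lowest (row, column) index pair); branch lengths come from the
    standard closed forms, with negative estimates clamped to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    d = dm.d.copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minima for determinism
        best = np.inf
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best - 1e-12:
                    best, bi, bj = q[i, j], i, j
        li = d[bi, bj] / 2 + (r[bi] - r[bj]) / (2 * (m - 2))
        lj = d[bi, bj] - li
        parent = TreeNode(children=[nodes[bi], nodes[bj]])
        nodes[bi].length = max(0.0, li)
        nodes[bj].length = max(0.0, lj)
        new_row = 0.5 * (d[bi, :] + d[bj, :] - d[bi, bj])
        keep = [k for k in range(m) if k not in (bi, bj)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    a, b = nodes
    # attach the remaining edge wholly to the non-internal side so that
    # path lengths reproduce the input on additive matrices
    if a.is_leaf and not b.is_leaf:
        a, b = b, a
    b.length = max(0.0, d[0, 1])
    a.children.append(b)
    a.length = 0.0
    return PhyloTree(root=a)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    model: Literal["p", "poisson"] = "poisson",
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; each internal
    edge's support is the number of replicates recovering its bipartition
    (range 0..replicates; rescale on output if percentages are wanted).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if aln.n_rows < 3:
        raise ValueError("need at least 3 rows")
    # canonical row order makes tie-breaking, and hence supports,
    # independent of input row order
    aln = Alignment(sorted(aln.rows), aln.alphabet)
    tree = neighbor_joining(distance_matrix(aln, model))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    rows = [list(seq) for _, seq in aln.rows]
    ids = [rid for rid, _ in aln.rows]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = [(rid, "".join(row[c] for c in cols))
                    for rid, row in zip(ids, rows)]
        try:
            rep_tree = neighbor_joining(
                distance_matrix(Alignment(rep_rows, aln.alphabet), model)
            )
        except ValueError:
            continue  # e.g. a replicate with no comparable columns
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = set(tree.leaf_names)
    ref = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = {leaf.name for leaf in node.leaves()}
        if ref in side:
            side = all_leaves - side
        key = frozenset(side)
        if key in counts:
            node.support = counts[key]
    return tree


# ---------------------------------------------------------------------------
# subfamily assignment
# ---------------------------------------------------------------------------

def assign_subfamilies(
    tree: PhyloTree, anchors: dict[str, str]
) -> dict[str, str]:
    """Propagate subfamily labels from anchor leaves to the rest.

    Each unlabeled leaf takes the subfamily of the smallest clade containing
    it and at least one anchor, provided all anchors inside that clade
    agree; disagreement yields ``UNASSIGNED``.
    """
    if not anchors:
        raise ValueError("no anchors supplied")
    leaf_names = set(tree.leaf_names)
    missing = set(anchors) - leaf_names
    if missing:
        raise ValueError(f"anchor ids not in tree: {sorted(missing)}")

    parent: dict[int, TreeNode] = {}
    for node in tree.root.walk():
        for c in node.children:
            parent[id(c)] = node

    out: dict[str, str] = {}
    for leaf in tree.root.leaves():
        if leaf.name in anchors:
            out[leaf.name] = anchors[leaf.name]
            continue
        node = leaf
        label = "UNASSIGNED"
        while True:
            clade_anchors = {
                anchors[l.name] for l in node.leaves() if l.name in anchors
            }
            if clade_anchors:
                label = (
                    clade_anchors.pop() if len(clade_anchors) == 1
                    else "UNASSIGNED"
                )
                break
            if id(node) not in parent:
                break
            node = parent[id(node)]
        out[leaf.name] = label
    return out


# ---------------------------------------------------------------------------
# fallback progressive aligner
# ---------------------------------------------------------------------------
# A small guide-tree progressive aligner (pairwise Needleman-Wunsch on
# BLOSUM62, affine gaps, UPGMA guide, profile-profile merging) so the
# pipeline can run end-to-end when no external alignment is supplied.
# It is not a replacement for a production MSA tool.

def _blosum62() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def _profile_align(
    prof_a: list[tuple[str, str]],
    prof_b: list[tuple[str, str]],
    sub: dict[tuple[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> list[tuple[str, str]]:
    """Gotoh alignment of two gapped profiles with sum-of-pairs scoring."""
    cols_a = list(zip(*[s for _, s in prof_a]))
    cols_b = list(zip(*[s for _, s in prof_b]))
    la, lb = len(cols_a), len(cols_b)

    def col_score(ca, cb) -> float:
        tot = npairs = 0
        for x in ca:
            for y in cb:
                if x == "-" or y == "-":
                    continue
                tot += sub.get((x, y), sub.get((y, x), 0.0))
                npairs += 1
        return tot / npairs if npairs else 0.0

    NEG = -1e9
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - gap_extend * i
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - gap_extend * j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = col_score(cols_a[i - 1], cols_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open - gap_extend,
                          X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open - gap_extend,
                          Y[i, j - 1] - gap_extend)
    # traceback (prefer M, then X, then Y)
    i, j = la, lb
    state = max((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y"),
                key=lambda t: t[0])[1]
    path: list[str] = []
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            s = col_score(cols_a[i - 1], cols_b[j - 1])
            prev = M[i, j] - s
            path.append("M")
            i, j = i - 1, j - 1
            for cand, lbl in ((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y")):
                if abs(cand - prev) < 1e-6:
                    state = lbl
                    break
        elif state == "X" or (j == 0 and i > 0):
            path.append("X")
            if i > 0 and abs(X[i, j] - (M[i - 1, j] - gap_open - gap_extend)) < 1e-6:
                state = "M"
            i -= 1
        else:
            path.append("Y")
            if j > 0 and abs(Y[i, j] - (M[i, j - 1] - gap_open - gap_extend)) < 1e-6:
                state = "M"
            j -= 1
    path.reverse()
    out_a = {rid: [] for rid, _ in prof_a}
    out_b = {rid: [] for rid, _ in prof_b}
    ai = bi = 0
    for step in path:
        if step in ("M", "X"):
            for rid, s in prof_a:
                out_a[rid].append(s[ai])
            ai += 1
        else:
            for rid, _ in prof_a:
                out_a[rid].append("-")
        if step in ("M", "Y"):
            for rid, s in prof_b:
                out_b[rid].append(s[bi])
            bi += 1
        else:
            for rid, _ in prof_b:
                out_b[rid].append("-")
    merged = [(rid, "".join(out_a[rid])) for rid, _ in prof_a]
    merged += [(rid, "".join(out_b[rid])) for rid, _ in prof_b]
    return merged


def progressive_align(
    seqs: SequenceSet, gap_open: float = 10.0, gap_extend: float = 0.5
) -> Alignment:
    """Progressive multiple alignment (UPGMA guide + profile merging)."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    names = list(seqs.records)
    if len(names) == 1:
        return Alignment([(names[0], seqs[names[0]])], "protein")
    sub = _blosum62()
    n = len(names)
    d = np.zeros((n, n))
    profiles: dict[int, list[tuple[str, str]]] = {
        i: [(names[i], seqs[names[i]])] for i in range(n)
    }
    for i in range(n):
        for j in range(i + 1, n):
            pair = _profile_align(profiles[i], profiles[j], sub,
                                  gap_open, gap_extend)
            d[i, j] = d[j, i] = p_distance(pair[0][1], pair[1][1])
    link = linkage(squareform(d, checks=False), method="average")
    for k, (a, b, _, _) in enumerate(link):
        merged = _profile_align(profiles.pop(int(a)), profiles.pop(int(b)),
                                sub, gap_open, gap_extend)
        profiles[n + k] = merged
    (final,) = profiles.values()
    order = {name: i for i, name in enumerate(names)}
    final.sort(key=lambda row: order[row[0]])
    return Alignment(final, "protein")
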