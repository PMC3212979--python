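"""Distance-based phylogeny of repeat copies: pairwise-deletion distances
(p, Kimura 2-parameter, or a Tamura-Nei-form composite-likelihood surrogate),
neighbor joining, column-resampling bootstrap, clade collapse, and
sub-cluster extraction.

Trees are stored as undirected weighted graphs with per-internal-edge
bootstrap supports, so collapsing and (mid-point) re-rooting are cheap and
rooting-invariant. Sub-clusters are the maximal supported clades of the
collapsed midpoint-rooted tree; copies outside every sub-cluster are
reported as unclustered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _align_kernels as _ak
from ._util import encode

_MODELS = {"p": 0, "k2p": 1, "mcl": 2}


class UndefinedDistanceError(ValueError):
    pass


class SaturationError(ValueError):
    def __init__(self, msg, p_distance):
        super().__init__(msg)
        self.p_distance = p_distance  # flagged fallback value


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        assert m.shape == (len(self.labels), len(self.labels))


def _row_codes(row):
    return encode(row) if isinstance(row, str) else np.asarray(row)


def pairwise_distance(a, b, model: str = "p") -> float:
    """Distance between two equal-length gapped rows, pairwise deletion.

    Columns gapped (or N) in either row are excluded. Models: ``p`` mismatch
    fraction; ``k2p`` Kimura 2-parameter; ``mcl`` Tamura-Nei-form distance
    with empirical base frequencies pooled over the two rows (the composite-
    likelihood surrogate). Saturated pairs raise SaturationError carrying the
    p-distance fallback.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    ca, cb = _row_codes(a), _row_codes(b)
    if ca.shape[0] != cb.shape[0]:
        raise ValueError("rows must come from one alignment (equal length)")
    ok = (ca <= 3) & (cb <= 3)
    if not ok.any():
        raise UndefinedDistanceError("no shared ungapped columns")
    x, y = ca[ok].astype(int), cb[ok].astype(int)
    valid = x.shape[0]
    diff = int((x != y).sum())
    p = diff / valid
    if model == "p":
        return p
    ts = int((((x == 0) & (y == 2)) | ((x == 2) & (y == 0))
              | ((x == 1) & (y == 3)) | ((x == 3) & (y == 1))).sum())
    tv = diff - ts
    P, Q = ts / valid, tv / valid
    if model == "k2p":
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        if w1 <= 0 or w2 <= 0:
            raise SaturationError("K2P distance saturated", p)
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    freq = np.bincount(np.concatenate([x, y]), minlength=4) / (2 * valid)
    gR, gY = freq[0] + freq[2], freq[1] + freq[3]
    k1 = 2 * freq[0] * freq[2] / gR if gR > 0 else 0.0
    k2 = 2 * freq[1] * freq[3] / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY - freq[0] * freq[2] * gY / gR
              - freq[1] * freq[3] * gR / gY) if gR > 0 and gY > 0 else 0.0
    P1 = int((((x == 0) & (y == 2)) | ((x == 2) & (y == 0))).sum()) / valid
    P2 = int((((x == 1) & (y == 3)) | ((x == 3) & (y == 1))).sum()) / valid
    if k1 <= 0 or k2 <= 0 or k3 <= 0:
        raise SaturationError("degenerate base composition", p)
    w1 = 1 - P1 / k1 - 0.5 * Q / gR
    w2 = 1 - P2 / k2 - 0.5 * Q / gY
    w3 = 1 - 0.5 * Q / (gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("TN distance saturated", p)
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def distance_matrix(msa, model: str = "mcl") -> DistanceMatrix:
    """All-pairs distances from an MSA (pairwise deletion; pooled empirical
    base frequencies for the mcl model). Saturated pairs fall back to the
    p-distance."""
    cols = np.arange(msa.n_cols, dtype=np.int64)
    D = _ak.distance_matrix_kernel(msa.codes, cols, _MODELS[model])
    if np.isnan(D).any():
        raise UndefinedDistanceError("some pair shares no ungapped columns")
    return DistanceMatrix(tuple(msa.ids), D)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class Tree:
    """Unrooted tree: adjacency with branch lengths + edge supports (%)."""

    def __init__(self, n_leaves, labels):
        self.n_leaves = n_leaves
        self.labels = tuple(labels)
        self.adj = {}       # node -> {neighbor: length}
        self.support = {}   # frozenset({u, v}) -> float | None

    def add_edge(self, u, v, length, support=None):
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length
        if support is not None:
            self.support[frozenset((u, v))] = support

    def copy(self):
        t = Tree(self.n_leaves, self.labels)
        for u, nb in self.adj.items():
            t.adj[u] = dict(nb)
        t.support = dict(self.support)
        return t

    def is_leaf(self, u):
        return u < self.n_leaves

    # -- topology helpers ---------------------------------------------------

    def _side_leafset(self, u, v):
        """Leaves on the v side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        out = set()
        while stack:
            x = stack.pop()
            if self.is_leaf(x):
                out.add(x)
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self):
        """{canonical leafset: (edge, support)} over internal edges."""
        out = {}
        all_leaves = frozenset(range(self.n_leaves))
        for e in {frozenset((u, v)) for u in self.adj for v in self.adj[u]}:
            u, v = tuple(e)
            if self.is_leaf(u) or self.is_leaf(v):
                continue
            side = self._side_leafset(u, v)
            canon = _canon_split(side, all_leaves)
            out[canon] = (e, self.support.get(e))
        return out

    def leaf_distances(self):
        """Dict leaf -> dict node -> path length (for midpoint search)."""
        dists = {}
        for leaf in range(self.n_leaves):
            d = {leaf: 0.0}
            stack = [leaf]
            while stack:
                x = stack.pop()
                for y, ln in self.adj[x].items():
                    if y not in d:
                        d[y] = d[x] + ln
                        stack.append(y)
            dists[leaf] = d
        return dists

    def newick(self) -> str:
        """Newick with bootstrap supports as internal node labels."""
        # root at the highest-degree internal node for output
        root = max(self.adj, key=lambda u: (len(self.adj[u]), u))

        def rec(u, parent):
            children = [v for v in self.adj[u] if v != parent]
            if not children:
                return self.labels[u]
            inner = ",".join(
                f"{rec(v, u)}:{self.adj[u][v]:.6f}" for v in children
            )
            sup = ""
            if parent is not None:
                s = self.support.get(frozenset((u, parent)))
                if s is not None:
                    sup = f"{s:.0f}"
            return f"({inner}){sup}"

        return rec(root, None) + ";"


def _canon_split(side, all_leaves):
    other = all_leaves - side
    a = (len(side), tuple(sorted(side)))
    b = (len(other), tuple(sorted(other)))
    return side if a <= b else other


def nj(matrix: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining (ties to the smallest label pair;
    negative branch lengths truncated to 0, deficit moved to the sister)."""
    D = np.asarray(matrix.matrix, dtype=np.float64)
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite entries")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need >= 3 taxa")
    left, right, lb, rb = _ak.nj_kernel(D)
    tree = Tree(n, matrix.labels)
    for k in range(n, left.shape[0]):
        if left[k] < 0:
            continue
        tree.add_edge(k, int(left[k]), float(lb[k]))
        tree.add_edge(k, int(right[k]), float(rb[k]))
    # contract the zero-length artificial root edge into a trifurcation
    root = left.shape[0] - 1
    if root in tree.adj and len(tree.adj[root]) == 2:
        (a, la), (b, lbn) = tree.adj[root].items()
        if la == 0.0 or lbn == 0.0:
            del tree.adj[root]
            tree.adj[a].pop(root)
            tree.adj[b].pop(root)
            tree.add_edge(a, b, la + lbn)
    return tree


def bootstrap_support(msa, model: str = "mcl", n_reps: int = 1000,
                      seed: int = 0) -> Tree:
    """NJ tree from the full alignment with bootstrap supports mapped onto
    its internal edges (percent of column-resampled replicates containing
    each bipartition). Deterministic given ``seed``."""
    if n_reps < 2:
        raise ValueError("need >= 2 bootstrap replicates")
    base = nj(distance_matrix(msa, model))
    target = base.bipartitions()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    ncols = msa.n_cols
    mcode = _MODELS[model]
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols).astype(np.int64)
        D = _ak.distance_matrix_kernel(msa.codes, cols, mcode)
        if np.isnan(D).any():
            continue
        left, right, lb, rb = _ak.nj_kernel(D)
        rep = Tree(msa.n_rows, msa.ids)
        for k in range(msa.n_rows, left.shape[0]):
            if left[k] < 0:
                continue
            rep.add_edge(k, int(left[k]), float(lb[k]))
            rep.add_edge(k, int(right[k]), float(rb[k]))
        for split in rep.bipartitions():
            if split in counts:
                counts[split] += 1
    out = base.copy()
    for split, (edge, _s) in target.items():
        out.support[edge] = 100.0 * counts[split] / n_reps
    return out


def collapse(tree: Tree, min_support: float = 50.0) -> Tree:
    """Contract internal edges with support below ``min_support``."""
    t = tree.copy()
    again = True
    while again:
        again = False
        for e in list(t.support):
            if e not in t.support:
                continue
            u, v = tuple(e)
            if u not in t.adj or v not in t.adj[u]:
                continue
            s = t.support[e]
            if s is not None and s < min_support:
                _contract_edge(t, u, v)
                again = True
    return t


def _contract_edge(t: Tree, u, v):
    """Merge v into u (v must be internal)."""
    if t.is_leaf(v):
        u, v = v, u
    if t.is_leaf(v):
        return
    for w, ln in list(t.adj[v].items()):
        if w == u:
            continue
        sup = t.support.pop(frozenset((v, w)), None)
        t.adj[u][w] = ln
        t.adj[w][u] = ln
        t.adj[w].pop(v, None)
        if sup is not None:
            t.support[frozenset((u, w))] = sup
    t.adj[u].pop(v, None)
    t.support.pop(frozenset((u, v)), None)
    del t.adj[v]


def midpoint_edge(tree: Tree):
    """(u, v, offset_from_u) of the midpoint of the longest leaf-leaf path."""
    dists = tree.leaf_distances()
    best = (-1.0, None, None)
    for a in range(tree.n_leaves):
        for b in range(a + 1, tree.n_leaves):
            d = dists[a][b]
            if d > best[0]:
                best = (d, a, b)
    total, a, b = best
    # walk from a to b accumulating length until half the path
    half = total / 2.0
    path = _path(tree, a, b)
    acc = 0.0
    for u, v in zip(path, path[1:]):
        ln = tree.adj[u][v]
        if acc + ln >= half:
            return u, v, half - acc
        acc += ln
    u, v = path[-2], path[-1]
    return u, v, tree.adj[u][v]


def _path(tree: Tree, a, b):
    prev = {a: None}
    stack = [a]
    while stack:
        x = stack.pop()
        if x == b:
            break
        for y in tree.adj[x]:
            if y not in prev:
                prev[y] = x
                stack.append(y)
    path = [b]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path[::-1]


def subclusters(tree: Tree, min_support: float = 50.0,
                min_size: int = 10):
    """Maximal supported clades of the midpoint-rooted (collapsed) tree.

    Returns (clusters, unclustered): clusters is a list of leaf-label sets
    (mutually disjoint, each of size >= min_size with bipartition support
    >= min_support); unclustered collects all remaining leaves.
    """
    if tree.n_leaves <= min_size or len(tree.adj) < 2:
        return [], [set(tree.labels[i] for i in range(tree.n_leaves))]
    u, v, _off = midpoint_edge(tree)
    clusters = []

    def clade_ok(child, parent):
        leaves = tree._side_leafset(parent, child)
        # a sub-cluster is a cohesive minority group: its complement must
        # itself be large, otherwise the "clade" merely reflects a couple
        # of outliers on the other side of the root
        if len(leaves) < min_size or tree.n_leaves - len(leaves) < min_size:
            return None
        if tree.is_leaf(child) or tree.is_leaf(parent):
            return None
        s = tree.support.get(frozenset((child, parent)))
        if s is None or s < min_support:
            return None
        return leaves

    taken = set()

    def descend(node, parent):
        leaves = clade_ok(node, parent) if parent is not None else None
        if leaves is not None:
            clusters.append(leaves)
            taken.update(leaves)
            return
        for nb in tree.adj[node]:
            if nb != parent:
                descend(nb, node)

    # root on the midpoint edge: explore both directions
    descend(u, v)
    descend(v, u)
    unclustered = [i for i in range(tree.n_leaves) if i not in taken]
    return ([set(tree.labels[i] for i in c) for c in clusters],
            [set(tree.labels[i] for i in unclustered)])


def write_phylip(path, dm: DistanceMatrix):
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for i, lab in enumerate(dm.labels):
            row = " ".join(f"{x:.6f}" for x in dm.matrix[i])
            fh.write(f"{str(lab)[:10]:<10} {row}\n")
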