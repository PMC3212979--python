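"""Independent brute-force oracles used by the test suite.

These re-derive expected values by exhaustive enumeration / textbook dynamic
programming, sharing no code paths with the package implementation beyond the
published energy-model constants.
"""

from __future__ import annotations

import math
from functools import lru_cache

# --- RNA folding oracle ----------------------------------------------------

_PAIRS = {("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")}
_W = {("C", "G"): 2.0, ("G", "C"): 2.0, ("G", "U"): 0.8, ("U", "G"): 0.8,
      ("A", "U"): 1.3, ("U", "A"): 1.3}
MINLOOP = 3
MAXINTER = 30
ML_A, ML_B = 3.4, 0.4


def _rna(seq):
    return seq.upper().replace("T", "U")


def enumerate_structures(seq):
    """All pseudoknot-free pair sets with min loop 3 over allowed pairs."""
    s = _rna(seq)
    n = len(s)

    @lru_cache(maxsize=None)
    def structs(i, j):
        # all structures on s[i..j] inclusive, as frozensets of pairs
        if j - i < MINLOOP + 1:
            return [frozenset()]
        out = list(structs(i + 1, j))  # i unpaired
        for k in range(i + MINLOOP + 1, j + 1):
            if (s[i], s[k]) in _PAIRS:
                for left in structs(i + 1, k - 1):
                    for right in structs(k + 1, j):
                        out.append(left | right | {(i, k)})
        return out

    return structs(0, n - 1) if n else [frozenset()]


def structure_energy(seq, pairs):
    """Loop-decomposition energy; math.inf if an interior loop exceeds the cap."""
    s = _rna(seq)
    pairs = sorted(pairs)
    total = 0.0
    for (i, j) in pairs:
        nested = [(k, l) for (k, l) in pairs if i < k and l < j]
        direct = [
            c for c in nested
            if not any(d[0] < c[0] and c[1] < d[1] for d in nested if d != c)
        ]
        if not direct:
            total += 4.8 + 1.08 * math.log((j - i - 1) / 3.0)
        elif len(direct) == 1:
            (k, l) = direct[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 + l2 == 0:
                total += -0.9 - 0.5 * (_W[(s[i], s[j])] + _W[(s[k], s[l])])
            elif l1 + l2 <= MAXINTER:
                total += 1.6 + 0.45 * (l1 + l2) + 0.65 * abs(l1 - l2)
            else:
                return math.inf
        else:
            total += ML_A + ML_B * (len(direct) + 1)
    return total


def brute_force_partition(seq, temperature=310.15):
    """(logZ, pair probability dict, unpaired probability list, min energy)."""
    RT = 0.0019872 * temperature
    structures = enumerate_structures(seq)
    weights = []
    emin = 0.0
    for st in structures:
        e = structure_energy(seq, st)
        w = 0.0 if e == math.inf else math.exp(-e / RT)
        weights.append(w)
        if e < emin:
            emin = e
    Z = sum(weights)
    n = len(seq)
    pp = {}
    unpaired = [0.0] * n
    for st, w in zip(structures, weights):
        paired = set()
        for (i, j) in st:
            pp[(i, j)] = pp.get((i, j), 0.0) + w
            paired.add(i)
            paired.add(j)
        for i in range(n):
            if i not in paired:
                unpaired[i] += w
    pp = {k: v / Z for k, v in pp.items()}
    unpaired = [u / Z for u in unpaired]
    return math.log(Z), pp, unpaired, emin


# --- Smith-Waterman oracle ---------------------------------------------------


def sw_best_score(q, t, match, mismatch, gap_open, gap_ext):
    """Affine-gap local alignment score by straightforward O(mn) DP.

    Gap of length k costs gap_open + k * gap_ext.
    """
    m, n = len(q), len(t)
    NEG = -1e18
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_ext, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_ext, F[i - 1][j] - gap_ext)
            sub = match if q[i - 1] == t[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# --- distance / tree oracles -------------------------------------------------


def k2p_distance(P, Q):
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


def random_additive_matrix(rng, n_taxa):
    """A random binary tree and its additive leaf-to-leaf distance matrix."""
    import numpy as np

    nodes = list(range(n_taxa))
    children = {}
    lengths = {}
    nxt = n_taxa
    while len(nodes) > 1:
        idx = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(idx[0])], nodes[int(idx[1])]
        la = float(rng.uniform(0.05, 1.0))
        lb = float(rng.uniform(0.05, 1.0))
        children[nxt] = (a, b)
        lengths[(nxt, a)] = la
        lengths[(nxt, b)] = lb
        nodes = [x for x in nodes if x not in (a, b)] + [nxt]
        nxt += 1
    root = nodes[0]

    # leaf paths to root
    def path(leaf):
        out = {}
        def rec(node, dist):
            if node == leaf:
                out["d"] = dist
                return True
            if node in children:
                for c in children[node]:
                    if rec(c, dist + lengths[(node, c)]):
                        return True
            return False
        rec(root, 0.0)
        return out["d"]

    # pairwise distance via common structure: easier to do LCA walk
    import itertools

    parent = {}
    for p, (a, b) in children.items():
        parent[a] = p
        parent[b] = p

    def anc(x):
        chain = [x]
        while x in parent:
            x = parent[x]
            chain.append(x)
        return chain

    D = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        ai = anc(i)
        aj = set(anc(j))
        lca = next(x for x in ai if x in aj)
        d = 0.0
        x = i
        while x != lca:
            d += lengths[(parent[x], x)]
            x = parent[x]
        x = j
        while x != lca:
            d += lengths[(parent[x], x)]
            x = parent[x]
        D[i, j] = D[j, i] = d
    # splits (bipartitions) of the tree, as frozensets of the smaller side
    def leafset(node):
        if node < n_taxa:
            return {node}
        a, b = children[node]
        return leafset(a) | leafset(b)

    all_leaves = frozenset(range(n_taxa))
    splits = set()
    for node in children:
        if node == root:
            continue
        ls = frozenset(leafset(node))
        if 1 < len(ls) < n_taxa - 1:
            canon = ls if (len(ls), sorted(ls)) <= (len(all_leaves - ls), sorted(all_leaves - ls)) else all_leaves - ls
            splits.add(canon)
    return D, splits
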