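"""Independent oracles and utilities shared by the test suite.

Everything here is deliberately written in a different style from the
package (dict-based, brute-force) so it can serve as an independent
cross-check of the implementation rather than a mirror of it.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
from dendropy.calculate import treecompare


# --- textbook neighbor joining (dict-of-dicts, straight from the book) -----

def textbook_nj(labels, matrix):
    """Plain O(n^3) NJ over a dict-of-dicts; returns a Newick string.

    Joins the Q-minimising pair at each step, breaking ties on the
    lexicographically smallest pair of current node names (node names
    start as the input labels, so index order and name order agree).
    """
    d = {a: {b: float(matrix[i][j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    sub = {lb: f"{lb}" for lb in labels}
    order = {lb: i for i, lb in enumerate(labels)}
    next_id = [len(labels)]

    def join_once():
        names = sorted(d, key=lambda x: order[x])
        m = len(names)
        r = {a: sum(d[a][b] for b in names if b != a) for a in names}
        best = None
        for a, b in itertools.combinations(names, 2):
            q = (m - 2) * d[a][b] - r[a] - r[b]
            if best is None or q < best[0] - 1e-15:
                best = (q, a, b)
        _, a, b = best
        la = d[a][b] / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb_ = d[a][b] - la
        la, lb_ = max(la, 0.0), max(lb_, 0.0)
        new = f"N{next_id[0]}"
        next_id[0] += 1
        order[new] = max(order.values()) + 1
        d[new] = {}
        for c in names:
            if c in (a, b):
                continue
            dist = (d[a][c] + d[b][c] - d[a][b]) / 2
            d[new][c] = d[c][new] = dist
        d[new][new] = 0.0
        for c in (a, b):
            del d[c]
            for row in d.values():
                row.pop(c, None)
        sub[new] = f"({sub[a]}:{la:.12g},{sub[b]}:{lb_:.12g})"

    if len(labels) == 2:
        half = matrix[0][1] / 2
        return f"({labels[0]}:{half:.12g},{labels[1]}:{half:.12g});"
    while len(d) > 3:
        join_once()
    a, b, c = sorted(d, key=lambda x: order[x])
    la = (d[a][b] + d[a][c] - d[b][c]) / 2
    lb_ = d[a][b] - la
    lc = d[a][c] - la
    la, lb_, lc = (max(x, 0.0) for x in (la, lb_, lc))
    return f"({sub[a]}:{la:.12g},{sub[b]}:{lb_:.12g},{sub[c]}:{lc:.12g});"


# --- random additive trees ------------------------------------------------

def random_additive_matrix(n_leaves, rng, min_edge=0.02, max_edge=0.2):
    """A random additive distance matrix plus the generating tree.

    Grown by splitting a random edge for each new leaf.  Distances are
    rescaled to stay below 0.95 so they remain valid p-distances.
    Returns (labels, matrix, newick_of_generating_tree).
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    # edges: dict frozenset({u,v}) -> length; nodes are ints, leaves 0..n-1
    edges = {}
    nid = [n_leaves]

    def new_node():
        nid[0] += 1
        return nid[0] - 1

    center = new_node()
    for leaf in (0, 1, 2):
        edges[frozenset((leaf, center))] = rng.uniform(min_edge, max_edge)
    for leaf in range(3, n_leaves):
        key = list(edges)[int(rng.integers(len(edges)))]
        length = edges.pop(key)
        a, b = tuple(key)
        mid = new_node()
        split = rng.uniform(0.25, 0.75)
        edges[frozenset((a, mid))] = length * split
        edges[frozenset((b, mid))] = length * (1 - split)
        edges[frozenset((leaf, mid))] = rng.uniform(min_edge, max_edge)

    adj = {}
    for key, length in edges.items():
        a, b = tuple(key)
        adj.setdefault(a, []).append((b, length))
        adj.setdefault(b, []).append((a, length))

    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, ln in adj[node]:
                if nb not in out:
                    out[nb] = out[node] + ln
                    stack.append(nb)
        return out

    mat = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        di = dist_from(i)
        for j in range(n_leaves):
            mat[i, j] = di[j]
    mat = (mat + mat.T) / 2  # kill float-order asymmetry in the path sums
    top = mat.max()
    if top > 0.95:
        scale = 0.95 / top
        mat *= scale
        for key in edges:
            edges[key] *= scale
        adj = {k: [(nb, ln * scale) for nb, ln in v] for k, v in adj.items()}

    def render(node, parent, length):
        kids = [(nb, ln) for nb, ln in adj[node] if nb != parent]
        if not kids:
            return f"L{node}:{length:.12g}"
        inner = ",".join(render(nb, node, ln) for nb, ln in kids)
        return f"({inner}):{length:.12g}"

    root = center
    inner = ",".join(render(nb, root, ln) for nb, ln in adj[root])
    return labels, mat, f"({inner});"


# --- tree comparison ------------------------------------------------------

def rf_distance(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


def path_distance_matrix(newick, labels):
    """Leaf-to-leaf path lengths of a Newick tree, ordered by ``labels``."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return out


def similarity_tree_newick_ids(tree):
    """Serialise a package SimilarityTree using hit ids as leaf labels."""

    def render(node):
        if node.is_leaf:
            label = node.annotations.get("hit_id", node.label)
            return f"{label}:{node.length:.9g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.9g}"

    inner = ",".join(render(c) for c in tree.root.children)
    return f"({inner});"


# --- brute-force metric oracles -------------------------------------------

def brute_force_coverage(hit_intervals, query_len):
    """Per-position marking oracle for query coverage."""
    marked = [False] * query_len
    for lo, hi in hit_intervals:
        for i in range(max(lo, 0), min(hi, query_len)):
            marked[i] = True
    return sum(marked) / query_len


def brute_force_gap_free(rows):
    """Column-scan oracle: columns with no gap in any row."""
    if not rows:
        return 0
    width = len(rows[0])
    return sum(all(r[c] != "-" for r in rows) for c in range(width))
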