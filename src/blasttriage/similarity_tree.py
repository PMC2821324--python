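"""p-distance matrices and neighbor-joining similarity trees.

The similarity tree gives an approximate picture of the phylogenetic
relationships between the query and its BLAST hits.  It is built from
uncorrected p-distances over the stacked pseudo-alignment and the
neighbor-joining algorithm — deliberately fast rather than optimised for
phylogenetic accuracy (no multiple-hit correction, no bootstrap), because
its job is interactive triage of hits, not publication-grade phylogeny.

Two site modes are offered.  ``all_sites`` compares each pair over every
column where both sequences carry a residue (pairwise deletion);
``gap_free`` restricts all pairs to columns with no gap in any selected
row.  The initial/default tree uses all sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .blast_io import BlastResult
from .errors import IntegrityError, SelectionError
from .pseudo_msa import GAP, PseudoMsa, stack

DEFAULT_TOP_N = 100
DEFAULT_RANK = "phylum"

#: Deterministic palette cycled over taxonomy groups in first-appearance order.
PALETTE_SIZE = 12


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances in [0, 1]."""

    labels: list[str]
    values: np.ndarray
    site_mode: str = "all_sites"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise IntegrityError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise IntegrityError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise IntegrityError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise IntegrityError("distance matrix diagonal must be zero")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise IntegrityError("p-distances must lie in [0, 1]")


class TreeNode:
    """Node of an (unrooted) similarity tree.

    ``length`` is the branch length to the parent in p-distance units;
    leaf nodes carry a label and an annotation dict.
    """

    __slots__ = ("label", "length", "children", "annotations")

    def __init__(
        self,
        label: Optional[str] = None,
        length: float = 0.0,
        children: Optional[list["TreeNode"]] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.children: list[TreeNode] = children or []
        self.annotations: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class SimilarityTree:
    """NJ tree over the query and selected hits, Newick-serialisable."""

    root: TreeNode
    site_mode: str = "all_sites"
    query_label: str = "QUERY"

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def __len__(self) -> int:
        return len(self.leaves())


def p_distance_matrix(
    msa: PseudoMsa,
    labels: Sequence[str],
    site_mode: str = "all_sites",
) -> DistanceMatrix:
    """Pairwise p-distances between the selected rows of the alignment.

    ``all_sites``: each pair is compared over columns where both rows have
    residues (pairwise deletion).  ``gap_free``: only columns with no gap
    in *any* selected row are used, identically for every pair.  A pair
    with zero comparable columns is assigned distance 1 with a warning.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise SelectionError("need at least 2 sequences to compute distances")
    if site_mode not in ("all_sites", "gap_free"):
        raise SelectionError(f"unknown site mode {site_mode!r}")
    rows = np.array(
        [np.frombuffer(msa.row(lb).encode("ascii"), dtype="S1") for lb in labels]
    )
    residue = rows != GAP.encode("ascii")
    if site_mode == "gap_free":
        usable = residue.all(axis=0)
        if not usable.any():
            raise SelectionError(
                "no gap-free columns in the selected alignment; "
                "use site_mode='all_sites' instead"
            )
        rows = rows[:, usable]
        residue = residue[:, usable]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = residue[i] & residue[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                warnings.warn(
                    f"no comparable columns between {labels[i]!r} and "
                    f"{labels[j]!r}; distance set to 1.0",
                    stacklevel=2,
                )
                d[i, j] = d[j, i] = 1.0
            else:
                mism = int((rows[i][both] != rows[j][both]).sum())
                d[i, j] = d[j, i] = mism / n_comp
    return DistanceMatrix(labels=labels, values=d, site_mode=site_mode)


def neighbor_joining(dm: DistanceMatrix) -> SimilarityTree:
    """Build the unrooted NJ tree from a distance matrix.

    Standard agglomerative neighbor joining: at each step the pair
    minimising the Q-criterion is joined; ties break on the smallest
    (i, j) index pair, so runs are deterministic.  Negative branch
    lengths (possible on non-additive input) are clamped to zero.  The
    returned tree is unrooted, represented with a trifurcating root for
    n >= 3 (a bifurcating one for n == 2).
    """
    d = np.array(dm.values, dtype=float)
    n = len(dm.labels)
    if n < 2:
        raise SelectionError("neighbor joining needs at least 2 taxa")
    nodes = [TreeNode(label=lb) for lb in dm.labels]
    if n == 2:
        half = d[0, 1] / 2.0
        nodes[0].length = nodes[1].length = half
        return SimilarityTree(root=TreeNode(children=nodes))

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) on ties: lexicographic scan over the upper triangle
        best = (np.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0] - 1e-15:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        knew = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            d[knew, c] = d[c, knew] = (d[i, c] + d[j, c] - dij) / 2.0
        nodes.append(parent)
        active = [c for c in active if c not in (i, j)] + [knew]

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = d[a, b] - la
    lc = d[a, c] - la
    for node_idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[node_idx].length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return SimilarityTree(root=root, site_mode=dm.site_mode)


def sanitize_label(label: str) -> str:
    """Make a label safe for unquoted Newick: spaces to underscores,
    structural characters stripped."""
    out = label.replace(" ", "_")
    for ch in "():;,[]'\"":
        out = out.replace(ch, "")
    return out


def _newick_node(node: TreeNode, with_lengths: bool) -> str:
    if node.is_leaf:
        body = sanitize_label(node.label or "")
    else:
        body = "(" + ",".join(
            _newick_node(ch, with_lengths) for ch in node.children
        ) + ")"
    if with_lengths:
        return f"{body}:{node.length:.12g}"
    return body


def to_newick(tree: SimilarityTree, with_lengths: bool = True) -> str:
    """Serialise the tree to a Newick string (labels sanitised)."""
    inner = ",".join(
        _newick_node(ch, with_lengths) for ch in tree.root.children
    )
    return f"({inner});"


def annotate_and_name(
    tree: SimilarityTree,
    result: BlastResult,
    rank: str = DEFAULT_RANK,
    external_labels: Optional[set[str]] = None,
) -> SimilarityTree:
    """Rename hit leaves by species and attach taxonomy/coverage metadata.

    Leaf labels become the species name; when several hits share a species
    the accession is appended to keep labels unique.  Each leaf gets a
    taxonomy group — the lineage name at ``rank`` (default phylum), or
    ``"unknown"`` — and a stable colour index assigned per group in order
    of first appearance.  The query leaf keeps its label and gets the
    dedicated group ``"query"``; leaves named in ``external_labels``
    (user-supplied sequences folded into the alignment) keep theirs and
    get group ``"external"``.
    """
    from .selection import coverage_of_hit

    external_labels = external_labels or set()
    leaves = tree.leaves()
    hit_of_leaf: dict[int, object] = {}
    species_count: dict[str, int] = {}
    for idx, leaf in enumerate(leaves):
        if leaf.label == tree.query_label or leaf.label in external_labels:
            continue
        try:
            hit = result.hit_by_id(leaf.label)
        except KeyError:
            base = leaf.label.rsplit(".", 1)[0]  # duplicate-id suffix
            try:
                hit = result.hit_by_id(base)
            except KeyError:
                raise SelectionError(
                    f"tree leaf {leaf.label!r} matches no hit in the result"
                ) from None
        hit_of_leaf[idx] = hit
        sp = hit.species or "unknown"
        species_count[sp] = species_count.get(sp, 0) + 1

    groups: dict[str, int] = {}
    for idx, leaf in enumerate(leaves):
        if leaf.label == tree.query_label:
            group = "query"
        elif leaf.label in external_labels:
            group = "external"
        else:
            hit = hit_of_leaf[idx]
            sp = hit.species or "unknown"
            name = sp.replace(" ", "_")
            if species_count[sp] > 1 or sp == "unknown":
                name = f"{name}_{hit.accession}"
            group = "unknown"
            if hit.lineage:
                for rk, nm in hit.lineage:
                    if rk == rank:
                        group = nm
                        break
            leaf.annotations.update(
                hit_id=hit.hit_id,
                species=sp,
                taxid=hit.taxid,
                description=hit.description,
                coverage=coverage_of_hit(hit, result.column_count),
            )
            leaf.label = sanitize_label(name)
        if group not in groups:
            groups[group] = len(groups)
        leaf.annotations["group"] = group
        leaf.annotations["color"] = groups[group] % PALETTE_SIZE
    return tree


def rebuild_tree(
    result: BlastResult,
    msa: Optional[PseudoMsa] = None,
    selection: Optional[Iterable[str]] = None,
    site_mode: str = "all_sites",
    top_n: int = DEFAULT_TOP_N,
    rank: str = DEFAULT_RANK,
    external_labels: Optional[set[str]] = None,
) -> SimilarityTree:
    """Compose distances → NJ → annotation for the current selection.

    With no explicit ``selection`` the default scope is the ``top_n``
    (100) best-scoring hits; the query is always included.  The default
    build uses all sites.
    """
    if msa is None:
        msa = stack(result)
    if selection is None:
        from .selection import top_n as _top_n

        selection = _top_n(result, n=top_n)
    sel = [lb for lb in msa.labels if lb in set(selection)]
    extra = [lb for lb in selection if lb not in set(msa.labels)]
    if extra:
        raise SelectionError(f"selection labels not in alignment: {extra[:5]}")
    if not sel:
        raise SelectionError("selection is empty")
    labels = [msa.query_label] + sel
    dm = p_distance_matrix(msa, labels, site_mode=site_mode)
    tree = neighbor_joining(dm)
    tree.query_label = msa.query_label
    return annotate_and_name(
        tree, result, rank=rank, external_labels=external_labels
    )


def write_annotations(tree: SimilarityTree, path: str | Path) -> None:
    """Annotation sidecar TSV: leaf, species, taxid, group, color, coverage."""
    with open(path, "w") as fh:
        fh.write("leaf\tspecies\ttaxid\tgroup\tcolor\tcoverage\tdescription\n")
        for leaf in tree.leaves():
            ann = leaf.annotations
            cov = ann.get("coverage")
            fh.write(
                "\t".join(
                    [
                        leaf.label or "",
                        str(ann.get("species", "")),
                        str(ann.get("taxid", "")),
                        str(ann.get("group", "")),
                        str(ann.get("color", "")),
                        f"{cov:.4f}" if cov is not None else "",
                        str(ann.get("description", "")),
                    ]
                )
                + "\n"
            )


def plot_tree(tree: SimilarityTree, path: str | Path) -> None:
    """Static rectangular cladogram with taxonomy-coloured leaf labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    leaves = tree.leaves()
    ys: dict[int, float] = {}
    for i, leaf in enumerate(leaves):
        ys[id(leaf)] = float(i)

    cmap = plt.get_cmap("tab20")

    def layout(node: TreeNode, x0: float, ax) -> float:
        x = x0 + node.length
        if node.is_leaf:
            y = ys[id(node)]
            color = cmap(node.annotations.get("color", 0) % 20)
            ax.plot([x0, x], [y, y], color="black", lw=0.8)
            ax.text(x, y, " " + (node.label or ""), va="center", fontsize=6,
                    color=color)
            return y
        child_ys = [layout(ch, x, ax) for ch in node.children]
        y = sum(child_ys) / len(child_ys)
        ax.plot([x0, x], [y, y], color="black", lw=0.8)
        ax.plot([x, x], [min(child_ys), max(child_ys)], color="black", lw=0.8)
        return y

    fig, ax = plt.subplots(figsize=(8, max(2, 0.18 * len(leaves))))
    layout(tree.root, 0.0, ax)
    ax.set_yticks([])
    ax.set_xlabel("p-distance")
    for side in ("top", "right", "left"):
        ax.spines[side].set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
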