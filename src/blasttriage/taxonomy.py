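"""Local NCBI-taxonomy tables: lineage lookup and taxonomic hit selection.

Works from flat files in the NCBI taxdump column layout (pipe-delimited
``nodes.dmp`` / ``names.dmp``); only "scientific name" entries are indexed
so the name → taxid map stays unambiguous.  A small packaged fixture
taxonomy ships with the package so nothing needs downloading.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .blast_io import BlastResult, Hit
from .errors import TaxonomyError

ROOT_TAXID = 1
UNKNOWN = "unknown"


@dataclass
class TaxonomyTable:
    """taxid → (parent, rank, scientific name), with a name index."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    name_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name_index:
            self.name_index = {n.lower(): t for t, n in self.name.items()}
        self._validate()

    def _validate(self) -> None:
        for taxid, parent in self.parent.items():
            if parent != taxid and parent not in self.parent:
                raise TaxonomyError(
                    f"node {taxid} references missing parent {parent}"
                )
        # every walk must reach a self-parent root without revisiting a node
        for taxid in self.parent:
            seen = set()
            node = taxid
            while self.parent[node] != node:
                if node in seen:
                    raise TaxonomyError(f"cycle in taxonomy at taxid {node}")
                seen.add(node)
                node = self.parent[node]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def resolve(self, taxon: Union[int, str]) -> int:
        """Resolve a taxid or scientific name to a taxid."""
        if isinstance(taxon, int):
            if taxon not in self.parent:
                raise TaxonomyError(f"unknown taxid {taxon}")
            return taxon
        key = taxon.lower()
        if key in self.name_index:
            return self.name_index[key]
        close = difflib.get_close_matches(key, self.name_index, n=3)
        hint = f"; did you mean {close}?" if close else ""
        raise TaxonomyError(f"unknown taxon name {taxon!r}{hint}")


def load_taxdump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTable:
    """Load a taxonomy from NCBI-taxdump-style ``nodes.dmp``/``names.dmp``.

    Integrity (orphan parents, cycles) is checked on load and reported
    with the offending taxid.
    """
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    for line in Path(nodes_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("|")]
        taxid, par = int(fields[0]), int(fields[1])
        parent[taxid] = par
        rank[taxid] = fields[2] if len(fields) > 2 else "no rank"
    name: dict[int, str] = {}
    for line in Path(names_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("|")]
        taxid, nm = int(fields[0]), fields[1]
        name_class = fields[3] if len(fields) > 3 else "scientific name"
        if name_class == "scientific name":
            name[taxid] = nm
    return TaxonomyTable(parent=parent, rank=rank, name=name)


def fixture_taxonomy() -> TaxonomyTable:
    """The packaged ~50-taxon taxonomy used by the simulator and examples."""
    data = resources.files("blasttriage") / "data"
    return load_taxdump(str(data / "nodes.dmp"), str(data / "names.dmp"))


def lineage(table: TaxonomyTable, taxid: int) -> list[tuple[str, str]]:
    """Ordered (rank, name) path from the root down to ``taxid``."""
    if taxid not in table:
        raise TaxonomyError(f"unknown taxid {taxid}")
    path = []
    node = taxid
    while True:
        path.append((table.rank.get(node, "no rank"), table.name.get(node, str(node))))
        parent = table.parent[node]
        if parent == node:
            break
        node = parent
    return path[::-1]


def _lineage_taxids(table: TaxonomyTable, taxid: int) -> list[int]:
    path = []
    node = taxid
    while True:
        path.append(node)
        parent = table.parent[node]
        if parent == node:
            break
        node = parent
    return path[::-1]


def species_of_hit(hit: Hit, table: TaxonomyTable) -> tuple[str, Optional[int]]:
    """Best-effort species resolution for one hit.

    A taxid already on the hit wins; otherwise the last bracketed
    ``[...]`` span of the description (the NR convention for organism
    names) is matched against the scientific-name index.  Anything
    unresolvable degrades to ``("unknown", None)``.
    """
    if hit.taxid is not None and hit.taxid in table:
        return table.name.get(hit.taxid, UNKNOWN), hit.taxid
    desc = hit.description or ""
    last: Optional[str] = None
    depth = 0
    start = -1
    for i, ch in enumerate(desc):
        if ch == "[":
            depth += 1
            if depth == 1:
                start = i + 1
        elif ch == "]" and depth > 0:
            depth -= 1
            if depth == 0:
                last = desc[start:i]
    if last:
        key = last.strip().lower()
        if key in table.name_index:
            taxid = table.name_index[key]
            return table.name[taxid], taxid
        return last.strip(), None
    return UNKNOWN, None


def annotate_hits(result: BlastResult, table: TaxonomyTable) -> BlastResult:
    """Fill species/taxid/lineage on every hit, in place; returns the result."""
    for hit in result.hits:
        species, taxid = species_of_hit(hit, table)
        hit.species = species if species != UNKNOWN else None
        hit.taxid = taxid
        hit.lineage = lineage(table, taxid) if taxid is not None else None
    return result


@dataclass
class TaxonNode:
    """One node of the hierarchical hit-count summary."""

    name: str
    taxid: Optional[int]
    count: int = 0
    children: list["TaxonNode"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "taxid": self.taxid,
            "count": self.count,
            "children": [c.to_dict() for c in self.children],
        }

    def render(self, indent: int = 0) -> str:
        lines = [f"{'  ' * indent}{self.name} ({self.count})"]
        for child in self.children:
            lines.append(child.render(indent + 1))
        return "\n".join(lines)


def taxonomy_summary(
    hits: Iterable[Hit],
    table: TaxonomyTable,
    max_depth: Optional[int] = None,
) -> TaxonNode:
    """Hierarchical graph of hit counts per taxon.

    Lineages are truncated at ``max_depth`` levels below the root (None =
    full depth); hits whose lineage ends at a truncated node are counted
    there.  Hits with no resolvable taxonomy are grouped under a dedicated
    "unknown" child of the root.  Every node's count equals the sum over
    its subtree, so the root conserves the total hit count.
    """
    root = TaxonNode(name=table.name.get(ROOT_TAXID, "root"), taxid=ROOT_TAXID)
    index: dict[tuple[int, ...], TaxonNode] = {(): root}
    unknown_node: Optional[TaxonNode] = None
    for hit in hits:
        if hit.taxid is None or hit.taxid not in table:
            if unknown_node is None:
                unknown_node = TaxonNode(name=UNKNOWN, taxid=None)
                root.children.append(unknown_node)
            unknown_node.count += 1
            root.count += 1
            continue
        path = _lineage_taxids(table, hit.taxid)[1:]  # below root
        if max_depth is not None:
            path = path[:max_depth]
        root.count += 1
        key: tuple[int, ...] = ()
        for taxid in path:
            key = key + (taxid,)
            node = index.get(key)
            if node is None:
                node = TaxonNode(name=table.name.get(taxid, str(taxid)), taxid=taxid)
                index[key[:-1]].children.append(node)
                index[key] = node
            node.count += 1
    return root


def select_by_taxon(
    hits: Iterable[Hit],
    table: TaxonomyTable,
    taxon: Union[int, str],
    include: bool = True,
) -> set[str]:
    """Hit ids whose lineage contains (or does not contain) a taxon.

    ``include=False`` returns the complement among *annotated* hits only:
    hits with no taxonomy never match either way.
    """
    target = table.resolve(taxon)
    selected: set[str] = set()
    for hit in hits:
        if hit.taxid is None or hit.taxid not in table:
            continue
        member = target in _lineage_taxids(table, hit.taxid)
        if member == include:
            selected.add(hit.hit_id)
    return selected
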