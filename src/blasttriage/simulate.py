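"""Synthetic BLAST datasets with known ground truth.

The simulator stands in for a live BLAST search: it evolves hit sequences
from a query along a known tree, wraps them in HSPs the way BLAST would
report them (partial coverage, multi-HSP splits, tandem-duplicated
domains, indels), and emits a well-formed single-query NCBI BLAST XML
report.  Because the generating tree, sequences and HSPs are all
recorded, every downstream operation — parsing, stacking, distances, NJ,
filtering, taxonomy — can be checked against exact truth.

Substitution model: i.i.d. per site, replacement uniform over the other
alphabet letters, with a per-branch substitution probability.  For a path
of branches with probabilities p_e over an alphabet of k letters, the
expected p-distance has the closed form

    E[d] = 1 - 1/k - (1 - 1/k) * prod_e (1 - p_e * k / (k - 1)).

Synthetic scores decrease monotonically with edit distance
(raw = 2*matches - mismatches - 2*gap columns) and E-values are the
deterministic transform 10^(-bit_score / 10): only their ordering matters
to the tools under test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional
from xml.sax.saxutils import escape

import numpy as np

from .blast_io import Hsp
from .errors import SelectionError
from .similarity_tree import TreeNode
from .taxonomy import TaxonomyTable, fixture_taxonomy

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDE_ALPHABET = "ACGT"

QUERY_ID = "QUERY"


@dataclass
class TruthRecord:
    """Ground truth for one synthetic hit."""

    hit_id: str
    accession: str
    species: str
    taxid: int
    description: str
    seq: str            # full hit sequence as deposited in the fake database
    hsps: list[Hsp]     # exactly what the XML will report
    kind: str           # "single" | "split" | "dup"


@dataclass
class SyntheticTruth:
    """A complete simulated dataset: tree, sequences, HSPs, taxonomy."""

    program: str
    query_id: str
    query_seq: str
    records: list[TruthRecord]
    tree: TreeNode      # generating tree; leaf labels are QUERY and hit ids
    seed: int
    alphabet: str = "protein"

    @property
    def query_len(self) -> int:
        return len(self.query_seq)

    def record_by_id(self, hit_id: str) -> TruthRecord:
        for rec in self.records:
            if rec.hit_id == hit_id:
                return rec
        raise KeyError(hit_id)


def expected_p_distance(path_probs: list[float], k: int) -> float:
    """Closed-form expected p-distance along a path of branches."""
    prod = 1.0
    for p in path_probs:
        prod *= 1.0 - p * k / (k - 1)
    return 1.0 - (1.0 / k + (1.0 - 1.0 / k) * prod)


def _random_topology(labels: list[str], rng: np.random.Generator) -> TreeNode:
    """Random binary tree by repeated joining of uniformly chosen pairs."""
    nodes = [TreeNode(label=lb) for lb in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [n for n_idx, n in enumerate(nodes) if n_idx not in (i, j)]
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def _balanced_topology(labels: list[str]) -> TreeNode:
    nodes = [TreeNode(label=lb) for lb in labels]
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            nxt.append(TreeNode(children=[nodes[i], nodes[i + 1]]))
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return nodes[0]


def _mutate(seq: str, p: float, alphabet: str, rng: np.random.Generator) -> str:
    """Substitute each site with probability p, uniformly to another letter."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    for i in hits:
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _diverge_copy(
    seq: str, ref: str, n: int, alphabet: str, rng: np.random.Generator
) -> str:
    """Second repeat unit: mutate n positions that currently match ``ref``.

    Turning matches into mismatches (never the reverse) guarantees the
    duplicated copy aligns strictly worse than the first one.
    """
    out = list(seq)
    match_pos = [i for i in range(len(seq)) if seq[i] == ref[i]]
    n = min(n, len(match_pos))
    for i in rng.choice(len(match_pos), size=n, replace=False):
        pos = match_pos[i]
        choices = [c for c in alphabet if c != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _species_pool(table: TaxonomyTable) -> list[tuple[int, str]]:
    pool = [
        (taxid, table.name[taxid])
        for taxid, rk in sorted(table.rank.items())
        if rk == "species"
    ]
    return pool


def _apply_indels(
    aligned_query: str,
    aligned_hit: str,
    indel_rate: float,
    alphabet: str,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Interleave geometric-length indel events into an aligned pair.

    A deletion turns hit residues into gaps; an insertion adds hit
    residues opposite query gaps.  Event starts are i.i.d. per column.
    """
    if indel_rate <= 0:
        return aligned_query, aligned_hit
    qa_out: list[str] = []
    ha_out: list[str] = []
    i = 0
    n = len(aligned_query)
    while i < n:
        if rng.random() < indel_rate:
            length = min(int(rng.geometric(0.5)), 5)
            if rng.random() < 0.5:  # deletion in hit
                for _ in range(length):
                    if i >= n:
                        break
                    qa_out.append(aligned_query[i])
                    ha_out.append("-")
                    i += 1
                continue
            # insertion in hit (columns the query does not have)
            for _ in range(length):
                qa_out.append("-")
                ha_out.append(alphabet[rng.integers(len(alphabet))])
            # fall through to also copy the current column
        qa_out.append(aligned_query[i])
        ha_out.append(aligned_hit[i])
        i += 1
    return "".join(qa_out), "".join(ha_out)


def _score_hsp(
    q_span: tuple[int, int],
    h_span: tuple[int, int],
    aligned_query: str,
    aligned_hit: str,
    protein: bool,
) -> Hsp:
    matches = sum(
        1 for a, b in zip(aligned_query, aligned_hit) if a == b and a != "-"
    )
    gaps = aligned_query.count("-") + aligned_hit.count("-")
    mismatches = len(aligned_query) - matches - gaps
    raw = 2 * matches - mismatches - 2 * gaps
    # strictly monotone in raw and always positive (raw >= -2*align_len)
    bit = 0.25 * (raw + 2 * len(aligned_query)) + 1.0
    e_value = 10.0 ** (-min(bit, 1500.0) / 10.0)
    positives = matches + (mismatches // 2 if protein else 0)
    return Hsp(
        query_start=q_span[0],
        query_end=q_span[1],
        hit_start=h_span[0],
        hit_end=h_span[1],
        aligned_query=aligned_query,
        aligned_hit=aligned_hit,
        bit_score=bit,
        raw_score=float(raw),
        e_value=e_value,
        identities=matches,
        positives=positives,
        align_len=len(aligned_query),
    )


def simulate_dataset(
    n_hits: int = 50,
    query_len: int = 300,
    tree_shape: str = "random",
    sub_rate: float = 0.1,
    indel_rate: float = 0.0,
    dup_fraction: float = 0.0,
    split_fraction: float = 0.0,
    coverage_range: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    alphabet: str = "protein",
    taxonomy: Optional[TaxonomyTable] = None,
) -> SyntheticTruth:
    """Simulate a BLAST search result with full ground truth.

    Sequences evolve from a common ancestor along a tree whose leaves are
    the query and the ``n_hits`` hits; each branch carries a substitution
    probability drawn around ``sub_rate`` (exactly ``sub_rate`` on every
    hit branch of a star tree, where the query sits at the centre).  A
    ``dup_fraction`` of hits get a tandem-duplicated domain — two HSPs
    over the same query span with distinct scores; a ``split_fraction``
    get their alignment broken into two disjoint HSPs; the rest are
    single-HSP.  ``coverage_range`` bounds the fraction of the query each
    hit aligns to.  Same seed, same arguments → identical truth.
    """
    for name, rate in (
        ("sub_rate", sub_rate),
        ("indel_rate", indel_rate),
        ("dup_fraction", dup_fraction),
        ("split_fraction", split_fraction),
    ):
        if not 0.0 <= rate <= 1.0:
            raise SelectionError(f"{name} must be in [0, 1], got {rate}")
    if n_hits < 1:
        raise SelectionError(f"n_hits must be >= 1, got {n_hits}")
    if dup_fraction + split_fraction > 1.0:
        raise SelectionError("dup_fraction + split_fraction must be <= 1")
    if tree_shape not in ("star", "random", "balanced"):
        raise SelectionError(f"unknown tree_shape {tree_shape!r}")

    rng = np.random.default_rng(seed)
    letters = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    table = taxonomy if taxonomy is not None else fixture_taxonomy()
    pool = _species_pool(table)

    hit_ids = [f"hit{i:04d}" for i in range(n_hits)]
    labels = [QUERY_ID] + hit_ids
    if tree_shape == "star":
        tree = TreeNode(children=[TreeNode(label=lb) for lb in labels])
    elif tree_shape == "balanced":
        tree = _balanced_topology(labels)
    else:
        tree = _random_topology(labels, rng)

    # branch substitution probabilities; the query branch of a star tree is
    # zero so hits evolve directly from the query sequence
    def assign_lengths(node: TreeNode) -> None:
        for child in node.children:
            if tree_shape == "star":
                child.length = 0.0 if child.label == QUERY_ID else sub_rate
            else:
                child.length = sub_rate * rng.uniform(0.5, 1.5)
            assign_lengths(child)

    assign_lengths(tree)

    root_seq = "".join(letters[i] for i in rng.integers(len(letters), size=query_len))
    leaf_seq: dict[str, str] = {}

    def evolve(node: TreeNode, seq: str) -> None:
        if node.is_leaf:
            leaf_seq[node.label] = seq
            return
        for child in node.children:
            evolve(child, _mutate(seq, child.length, letters, rng))

    evolve(tree, root_seq)
    query_seq = leaf_seq[QUERY_ID]

    records: list[TruthRecord] = []
    protein = alphabet == "protein"
    for i, hit_id in enumerate(hit_ids):
        full = leaf_seq[hit_id]
        lo, hi = coverage_range
        cov = rng.uniform(lo, hi)
        span = max(min(query_len, 20), int(round(cov * query_len)))
        a = int(rng.integers(0, query_len - span + 1))
        b = a + span

        r = rng.random()
        kind = "dup" if r < dup_fraction else (
            "split" if r < dup_fraction + split_fraction else "single"
        )
        if kind == "split" and span < 50:
            kind = "single"

        hsps: list[Hsp] = []
        if kind == "split":
            # two disjoint HSPs separated by an unaligned middle region
            third = span // 3
            cut1 = a + third
            cut2 = b - third
            segs = [(a, cut1), (cut2, b)]
        else:
            segs = [(a, b)]

        hit_segments: list[str] = []
        offset = 0
        for qs, qe in segs:
            qa, ha = query_seq[qs:qe], full[qs:qe]
            if kind != "dup":  # dup hits stay gapless so copy ranks are exact
                qa, ha = _apply_indels(qa, ha, indel_rate, letters, rng)
            seg_res = ha.replace("-", "")
            hsps.append(
                _score_hsp((qs, qe), (offset, offset + len(seg_res)), qa, ha, protein)
            )
            hit_segments.append(seg_res)
            offset += len(seg_res)

        if kind == "dup":
            # tandem duplication: a second, more-diverged copy of the same
            # domain, producing a second HSP over the same query span
            qa = query_seq[a:b]
            copy2 = _diverge_copy(full[a:b], qa, max(1, span // 8), letters, rng)
            seg_res = copy2
            hsps.append(
                _score_hsp((a, b), (offset, offset + len(seg_res)), qa, copy2, protein)
            )
            hit_segments.append(seg_res)
            offset += len(seg_res)

        taxid, species = pool[rng.integers(len(pool))]
        accession = f"SYN{i:04d}"
        records.append(
            TruthRecord(
                hit_id=hit_id,
                accession=accession,
                species=species,
                taxid=taxid,
                description=f"synthetic protein {accession} [{species}]",
                seq="".join(hit_segments),
                hsps=hsps,
                kind=kind,
            )
        )

    for rec in records:
        for hsp in rec.hsps:
            hsp.validate()

    return SyntheticTruth(
        program="blastp" if protein else "blastn",
        query_id=QUERY_ID,
        query_seq=query_seq,
        records=records,
        tree=tree,
        seed=seed,
        alphabet=alphabet,
    )


def truth_newick(truth: SyntheticTruth) -> str:
    """Generating tree as Newick with QUERY/hit-id leaf labels."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.label}:{node.length:.6g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.6g}"

    if truth.tree.is_leaf:
        return f"({render(truth.tree)});"
    inner = ",".join(render(c) for c in truth.tree.children)
    return f"({inner});"


# --- BLAST XML emission ----------------------------------------------------

_XML_HEADER = """<?xml version="1.0"?>
<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">
"""


def _hsp_xml(num: int, hsp: Hsp) -> str:
    gaps = hsp.aligned_query.count("-") + hsp.aligned_hit.count("-")
    return f"""      <Hsp>
        <Hsp_num>{num}</Hsp_num>
        <Hsp_bit-score>{hsp.bit_score:g}</Hsp_bit-score>
        <Hsp_score>{hsp.raw_score:g}</Hsp_score>
        <Hsp_evalue>{hsp.e_value:.12g}</Hsp_evalue>
        <Hsp_query-from>{hsp.query_start + 1}</Hsp_query-from>
        <Hsp_query-to>{hsp.query_end}</Hsp_query-to>
        <Hsp_hit-from>{hsp.hit_start + 1}</Hsp_hit-from>
        <Hsp_hit-to>{hsp.hit_end}</Hsp_hit-to>
        <Hsp_query-frame>0</Hsp_query-frame>
        <Hsp_hit-frame>0</Hsp_hit-frame>
        <Hsp_identity>{hsp.identities}</Hsp_identity>
        <Hsp_positive>{hsp.positives}</Hsp_positive>
        <Hsp_gaps>{gaps}</Hsp_gaps>
        <Hsp_align-len>{hsp.align_len}</Hsp_align-len>
        <Hsp_qseq>{hsp.aligned_query}</Hsp_qseq>
        <Hsp_hseq>{hsp.aligned_hit}</Hsp_hseq>
        <Hsp_midline>{' ' * hsp.align_len}</Hsp_midline>
      </Hsp>
"""


def emit_blast_xml(truth: SyntheticTruth, path: str | Path) -> Path:
    """Write the truth as a single-query NCBI BLAST XML report."""
    path = Path(path)
    parts = [_XML_HEADER]
    program = truth.program
    parts.append(f"""<BlastOutput>
  <BlastOutput_program>{program}</BlastOutput_program>
  <BlastOutput_version>{program.upper()} 2.12.0+ (synthetic)</BlastOutput_version>
  <BlastOutput_reference>synthetic fixture</BlastOutput_reference>
  <BlastOutput_db>synthetic_db</BlastOutput_db>
  <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>
  <BlastOutput_query-def>{escape(truth.query_id)}</BlastOutput_query-def>
  <BlastOutput_query-len>{truth.query_len}</BlastOutput_query-len>
  <BlastOutput_param>
    <Parameters>
      <Parameters_expect>10</Parameters_expect>
    </Parameters>
  </BlastOutput_param>
  <BlastOutput_iterations>
    <Iteration>
      <Iteration_iter-num>1</Iteration_iter-num>
      <Iteration_query-ID>Query_1</Iteration_query-ID>
      <Iteration_query-def>{escape(truth.query_id)}</Iteration_query-def>
      <Iteration_query-len>{truth.query_len}</Iteration_query-len>
      <Iteration_hits>
""")
    for num, rec in enumerate(truth.records, start=1):
        parts.append(f"""        <Hit>
          <Hit_num>{num}</Hit_num>
          <Hit_id>{escape(rec.hit_id)}</Hit_id>
          <Hit_def>{escape(rec.description)}</Hit_def>
          <Hit_accession>{escape(rec.accession)}</Hit_accession>
          <Hit_len>{len(rec.seq)}</Hit_len>
          <Hit_hsps>
""")
        for hnum, hsp in enumerate(rec.hsps, start=1):
            parts.append(_hsp_xml(hnum, hsp))
        parts.append("          </Hit_hsps>\n        </Hit>\n")
    parts.append("""      </Iteration_hits>
      <Iteration_stat>
        <Statistics>
          <Statistics_db-num>1</Statistics_db-num>
          <Statistics_db-len>1000000</Statistics_db-len>
          <Statistics_hsp-len>0</Statistics_hsp-len>
          <Statistics_eff-space>1000000</Statistics_eff-space>
          <Statistics_kappa>0.041</Statistics_kappa>
          <Statistics_lambda>0.267</Statistics_lambda>
          <Statistics_entropy>0.14</Statistics_entropy>
        </Statistics>
      </Iteration_stat>
    </Iteration>
  </BlastOutput_iterations>
</BlastOutput>
""")
    path.write_text("".join(parts))
    return path


def write_query_fasta(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(f">{truth.query_id}\n{truth.query_seq}\n")
    return path


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> Path:
    """Truth table: one row per hit with species, kind and HSP spans."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("hit_id\taccession\tspecies\ttaxid\tkind\tn_hsps\tquery_spans\n")
        for rec in truth.records:
            spans = ";".join(f"{h.query_start}-{h.query_end}" for h in rec.hsps)
            fh.write(
                f"{rec.hit_id}\t{rec.accession}\t{rec.species}\t{rec.taxid}\t"
                f"{rec.kind}\t{len(rec.hsps)}\t{spans}\n"
            )
    return path


def write_taxdump(outdir: str | Path) -> tuple[Path, Path]:
    """Copy the packaged fixture taxonomy into ``outdir``."""
    from importlib import resources

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = resources.files("blasttriage") / "data"
    nodes = outdir / "nodes.dmp"
    names = outdir / "names.dmp"
    nodes.write_text((data / "nodes.dmp").read_text())
    names.write_text((data / "names.dmp").read_text())
    return nodes, names
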