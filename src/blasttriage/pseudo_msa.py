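"""Query-anchored pseudo multiple alignment built by HSP stacking.

Each hit's BLAST-aligned residues are projected onto the columns of the
query: a hit residue aligned to query position *i* lands in column *i*.
Alignment columns where the query carries a gap — insertions in the hit —
have no query column and are dropped (the stacking is deliberately lossy).
Regions of the hit not aligned to the query become gap characters.

When a hit has several HSPs, non-overlapping ones (on the query) are
concatenated into the same row.  HSPs that overlap on the query — the
signature of duplicated domains, where each repeat unit aligns to the same
query region — are resolved greedily by score: only the repeat unit in the
highest-scoring pair enters the alignment.

This trades alignment accuracy for speed: no joint multiple alignment is
computed, which is what makes thousand-hit datasets interactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .blast_io import BlastResult, Hit, Hsp
from .errors import IntegrityError, SelectionError

GAP = "-"

#: Most external sequences that may be folded into one selection.
MAX_EXTERNAL_SEQUENCES = 5

QUERY_LABEL = "QUERY"


@dataclass
class PseudoMsa:
    """Query-anchored alignment matrix; every row has ``column_count`` columns.

    ``rows`` maps row labels (hit ids, external-sequence names) to gapped
    strings.  The query row itself is gap-free by construction.
    """

    column_count: int
    query_row: str
    rows: dict[str, str] = field(default_factory=dict)
    alphabet: str = "protein"
    query_label: str = QUERY_LABEL

    def __post_init__(self) -> None:
        if len(self.query_row) != self.column_count:
            raise IntegrityError(
                f"query row has {len(self.query_row)} columns, "
                f"expected {self.column_count}"
            )
        if GAP in self.query_row:
            raise IntegrityError("query row must not contain gaps")

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    def row(self, label: str) -> str:
        if label == self.query_label:
            return self.query_row
        try:
            return self.rows[label]
        except KeyError:
            raise SelectionError(f"unknown row label {label!r}") from None

    def coverage_mask(self, label: str) -> list[bool]:
        return [c != GAP for c in self.row(label)]

    def coverage_intervals(self, label: str) -> list[tuple[int, int]]:
        """Covered stretches of a row as 0-based half-open intervals."""
        mask = self.coverage_mask(label)
        out: list[tuple[int, int]] = []
        start: Optional[int] = None
        for i, covered in enumerate(mask):
            if covered and start is None:
                start = i
            elif not covered and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, self.column_count))
        return out

    def to_fasta(self, path: str | Path, labels: Optional[Iterable[str]] = None) -> None:
        """Write the (selected) alignment as aligned FASTA, query first."""
        labels = list(labels) if labels is not None else self.labels
        with open(path, "w") as fh:
            fh.write(f">{self.query_label}\n{self.query_row}\n")
            for label in labels:
                if label == self.query_label:
                    continue
                fh.write(f">{label}\n{self.row(label)}\n")


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    # half-open intervals: adjacency is not overlap
    return a[0] < b[1] and b[0] < a[1]


def resolve_hsps(hit: Hit) -> list[Hsp]:
    """Pick the HSPs of a hit that enter the stacked alignment.

    Greedy by descending bit score (ties: lower query start, then input
    order); an HSP overlapping any already-kept HSP on the query is
    discarded entirely.  For a duplicated domain this keeps exactly the
    highest-scoring repeat unit.
    """
    order = sorted(
        range(len(hit.hsps)),
        key=lambda i: (-hit.hsps[i].bit_score, hit.hsps[i].query_start, i),
    )
    kept: list[Hsp] = []
    for i in order:
        hsp = hit.hsps[i]
        if not any(_overlaps(hsp.query_span, k.query_span) for k in kept):
            kept.append(hsp)
    kept.sort(key=lambda h: h.query_start)
    return kept


def _project_row(row: list[str], hsp: Hsp, column_count: int, hit_id: str) -> None:
    """Write one HSP's hit residues into their query columns."""
    pos = hsp.query_start
    for qc, hc in zip(hsp.aligned_query, hsp.aligned_hit):
        if qc == GAP:
            continue  # insertion in the hit: no query column, dropped
        if not 0 <= pos < column_count:
            raise IntegrityError(
                f"hit {hit_id}: HSP column {pos} outside query "
                f"[0,{column_count})"
            )
        row[pos] = hc
        pos += 1
    if pos != hsp.query_end:
        raise IntegrityError(
            f"hit {hit_id}: HSP consumed {pos - hsp.query_start} query "
            f"residues but spans [{hsp.query_start},{hsp.query_end})"
        )


def stack(result: BlastResult) -> PseudoMsa:
    """Build the pseudo-MSA of the query and all hits in ``result``."""
    width = result.column_count
    alphabet = "nucleotide" if result.program == "blastn" else "protein"
    msa = PseudoMsa(
        column_count=width,
        query_row=result.query_seq[:width].upper(),
        alphabet=alphabet,
    )
    seen: dict[str, int] = {}
    for hit in result.hits:
        label = hit.hit_id
        if label in seen:  # duplicate ids get a disambiguating suffix
            seen[label] += 1
            label = f"{label}.{seen[hit.hit_id]}"
        else:
            seen[label] = 0
        row = [GAP] * width
        for hsp in resolve_hsps(hit):
            _project_row(row, hsp, width, hit.hit_id)
        msa.rows[label] = "".join(row)
    return msa


def gap_free_site_count(msa: PseudoMsa, selected_labels: Iterable[str] = ()) -> int:
    """Number of columns with a residue in the query and every selected row.

    With an empty selection this is the full column count (the query row is
    gap-free).  Intended to be recomputed whenever the selection changes —
    it is the quick proxy for how much phylogenetic signal the selected
    alignment retains.
    """
    rows = [msa.row(label) for label in selected_labels if label != msa.query_label]
    return sum(
        all(row[i] != GAP for row in rows) for i in range(msa.column_count)
    )


def _default_aligner(alphabet: str):
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
    else:
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    return aligner


def insert_external_sequences(
    msa: PseudoMsa,
    seqs: Sequence[tuple[str, str]],
    alphabet: Optional[str] = None,
    aligner=None,
) -> PseudoMsa:
    """Fold up to five user-supplied sequences into the alignment.

    Each sequence is globally aligned to the ungapped query (affine gaps;
    BLOSUM62 for protein, +2/−3 with open 5 / extend 2 for nucleotide —
    pass ``aligner`` to override) and then projected into query columns
    exactly like an HSP: residues opposite query gaps are dropped.  The
    caller is expected to rebuild the similarity tree afterwards.

    ``seqs`` is a sequence of ``(name, residues)`` pairs, e.g. parsed
    FASTA records.
    """
    if not 1 <= len(seqs) <= MAX_EXTERNAL_SEQUENCES:
        raise SelectionError(
            f"between 1 and {MAX_EXTERNAL_SEQUENCES} external sequences "
            f"may be added, got {len(seqs)}"
        )
    alphabet = alphabet or msa.alphabet
    if alphabet != msa.alphabet:
        raise SelectionError(
            f"alphabet mismatch: alignment is {msa.alphabet}, "
            f"sequences declared {alphabet}"
        )
    nucleotide_chars = set("ACGTUN-")
    if aligner is None:
        aligner = _default_aligner(alphabet)
    new_rows = dict(msa.rows)
    for name, seq in seqs:
        seq = seq.upper()
        if alphabet == "nucleotide" and not set(seq) <= nucleotide_chars:
            raise SelectionError(
                f"sequence {name!r} contains non-nucleotide characters"
            )
        if alphabet == "protein" and set(seq) <= nucleotide_chars and msa.alphabet == "nucleotide":
            pass  # unreachable; kept for clarity of the mismatch rule
        aln = aligner.align(msa.query_row, seq)[0]
        qa, sa = str(aln[0]), str(aln[1])
        row = [GAP] * msa.column_count
        pos = 0
        for qc, sc in zip(qa, sa):
            if qc == GAP:
                continue
            row[pos] = sc
            pos += 1
        label = name
        suffix = 1
        while label in new_rows or label == msa.query_label:
            suffix += 1
            label = f"{name}.{suffix}"
        new_rows[label] = "".join(row)
    return PseudoMsa(
        column_count=msa.column_count,
        query_row=msa.query_row,
        rows=new_rows,
        alphabet=msa.alphabet,
        query_label=msa.query_label,
    )
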