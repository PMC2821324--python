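"""Reading NCBI BLAST XML reports into the package's data model.

Only the XML dialect (``-outfmt 5``) is accepted: it is the one BLAST output
format that carries the gapped alignment strings required for HSP stacking.
Coordinates are converted to 0-based half-open on ingest; the 1-based
inclusive convention of the XML survives only at the I/O boundary.

Supported programs are blastn, blastp, blastx and tblastn.  tblastx is
rejected: its alignments live in overlapping reading frames on both
sequences and cannot be projected onto a single query coordinate system.
For blastx the analysis happens at the protein level — nucleotide query
coordinates are mapped onto codon (protein) columns and, within each hit,
only HSPs sharing the frame of the best-scoring HSP are retained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Blast import NCBIXML

from .errors import (
    IntegrityError,
    MultiQueryError,
    ParseError,
    SelectionError,
    UnsupportedProgramError,
)

#: Hard cap on the number of hits retained from a single report.
MAX_HITS = 5000

SUPPORTED_PROGRAMS = frozenset({"blastn", "blastp", "blastx", "tblastn"})

#: Programs whose alignments (after ingest) are amino-acid strings.
PROTEIN_LEVEL_PROGRAMS = frozenset({"blastp", "blastx", "tblastn"})


@dataclass
class Hsp:
    """One high-scoring pair: a local gapped alignment of query vs subject.

    ``query_start``/``query_end`` and ``hit_start``/``hit_end`` are 0-based
    half-open, in the *column space* of the analysis (protein positions for
    blastx, residue positions otherwise).  ``strand`` records minus-strand
    subject alignments (blastn), whose subject coordinates are normalised
    to start < end at parse time while the alignment strings stay
    query-forward as BLAST reports them.
    """

    query_start: int
    query_end: int
    hit_start: int
    hit_end: int
    aligned_query: str
    aligned_hit: str
    bit_score: float
    raw_score: float
    e_value: float
    identities: int
    positives: int
    align_len: int
    strand: str = "+"
    query_frame: int = 0
    hit_frame: int = 0

    def validate(self) -> None:
        if len(self.aligned_query) != len(self.aligned_hit):
            raise IntegrityError(
                f"aligned strings differ in length: {len(self.aligned_query)} "
                f"vs {len(self.aligned_hit)}"
            )
        if len(self.aligned_query) != self.align_len:
            raise IntegrityError(
                f"align_len {self.align_len} does not match alignment strings "
                f"({len(self.aligned_query)} columns)"
            )
        n_query_res = len(self.aligned_query) - self.aligned_query.count("-")
        if n_query_res != self.query_end - self.query_start:
            raise IntegrityError(
                f"query span [{self.query_start},{self.query_end}) holds "
                f"{self.query_end - self.query_start} residues but the aligned "
                f"query string has {n_query_res}"
            )
        if self.e_value < 0:
            raise IntegrityError(f"negative e-value {self.e_value}")
        if not (0 <= self.identities <= self.positives <= self.align_len):
            raise IntegrityError(
                f"identities ({self.identities}) <= positives ({self.positives}) "
                f"<= align_len ({self.align_len}) violated"
            )

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)


@dataclass
class Hit:
    """One database match with its local alignments (HSPs).

    The hit-level score and E-value are those of its best (highest
    bit-score) HSP.
    """

    hit_id: str
    accession: str
    description: str
    hit_len: int
    hsps: list[Hsp]
    species: Optional[str] = None
    taxid: Optional[int] = None
    lineage: Optional[list[tuple[str, str]]] = None

    def __post_init__(self) -> None:
        if not self.hsps:
            raise IntegrityError(f"hit {self.hit_id} has no HSPs")

    @property
    def best_hsp(self) -> Hsp:
        return max(self.hsps, key=lambda h: h.bit_score)

    @property
    def bit_score(self) -> float:
        return self.best_hsp.bit_score

    @property
    def e_value(self) -> float:
        return min(h.e_value for h in self.hsps)


@dataclass
class BlastResult:
    """A parsed single-query BLAST report, hits sorted by descending score."""

    program: str
    query_id: str
    query_seq: str
    query_len: int
    db_name: str
    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.program not in SUPPORTED_PROGRAMS:
            raise UnsupportedProgramError(
                f"program {self.program!r} is not supported "
                f"(expected one of {sorted(SUPPORTED_PROGRAMS)})"
            )

    @property
    def column_count(self) -> int:
        """Width of the query-anchored column space.

        Equals the query length, except for blastx where the nucleotide
        query is analysed at the protein level (codon columns).
        """
        if self.program == "blastx":
            return self.query_len // 3
        return self.query_len

    def hit_by_id(self, hit_id: str) -> Hit:
        for h in self.hits:
            if h.hit_id == hit_id:
                return h
        raise KeyError(hit_id)


def _blastx_columns(qs: int, qe: int, frame: int, query_len: int, n_res: int) -> tuple[int, int]:
    """Map a blastx nucleotide query span to protein columns of its frame."""
    if frame > 0:
        start = (qs - 1) // 3
    else:
        start = (query_len - qe) // 3
    return start, start + n_res


def parse_blast_xml(
    path: str | Path,
    query_fasta: Optional[str | Path] = None,
    max_hits: int = MAX_HITS,
) -> BlastResult:
    """Parse a single-query NCBI BLAST XML report.

    Hits come back sorted by descending best bit score and capped at
    ``max_hits`` (5,000 by default).  ``query_fasta`` supplies the full
    query sequence; without it, the query is reconstructed from the HSP
    alignment strings, with ``X`` (protein) / ``N`` (nucleotide) at
    positions no HSP covers.

    Raises :class:`ParseError` on malformed XML, :class:`MultiQueryError`
    on multi-query reports and :class:`UnsupportedProgramError` for
    tblastx.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            records = list(NCBIXML.parse(fh))
    except MultiQueryError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface the parser's complaint
        raise ParseError(f"cannot parse BLAST XML {path}: {exc}") from exc
    if len(records) != 1:
        raise MultiQueryError(
            f"{path} contains {len(records)} query iterations; "
            "run one query per report"
        )
    rec = records[0]
    program = rec.application.lower()
    if program == "tblastx":
        raise UnsupportedProgramError(
            "tblastx reports are not supported: overlapping reading frames "
            "on both sequences prevent query-anchored stacking"
        )
    if program not in SUPPORTED_PROGRAMS:
        raise UnsupportedProgramError(f"program {program!r} is not supported")

    query_len = int(rec.query_letters)
    hits: list[Hit] = []
    for aln in rec.alignments:
        hsps: list[Hsp] = []
        for raw in aln.hsps:
            qs, qe = int(raw.query_start), int(raw.query_end)
            ss, se = int(raw.sbjct_start), int(raw.sbjct_end)
            strand = "+"
            if ss > se:  # blastn minus strand
                ss, se = se, ss
                strand = "-"
            qframe, hframe = (raw.frame + (0, 0))[:2]
            qframe = int(qframe or 0)
            hframe = int(hframe or 0)
            aligned_query = raw.query.upper()
            aligned_hit = raw.sbjct.upper()
            n_res = len(aligned_query) - aligned_query.count("-")
            if program == "blastx":
                q0, q1 = _blastx_columns(qs, qe, qframe, query_len, n_res)
            else:
                q0, q1 = qs - 1, qe
            hsp = Hsp(
                query_start=q0,
                query_end=q1,
                hit_start=ss - 1,
                hit_end=se,
                aligned_query=aligned_query,
                aligned_hit=aligned_hit,
                bit_score=float(raw.bits),
                raw_score=float(raw.score),
                e_value=float(raw.expect),
                identities=int(raw.identities or 0),
                positives=int(raw.positives or raw.identities or 0),
                align_len=int(raw.align_length),
                strand=strand,
                query_frame=qframe,
                hit_frame=hframe,
            )
            try:
                hsp.validate()
            except IntegrityError as exc:
                raise ParseError(
                    f"inconsistent HSP in hit {aln.hit_id!r}: {exc}"
                ) from exc
            hsps.append(hsp)
        if program == "blastx":
            # analyses are carried out at the protein level; a single hit
            # must live in one reading frame, so keep the best HSP's frame
            best_frame = max(hsps, key=lambda h: h.bit_score).query_frame
            hsps = [h for h in hsps if h.query_frame == best_frame]
        hits.append(
            Hit(
                hit_id=aln.hit_id,
                accession=aln.accession,
                description=aln.hit_def,
                hit_len=int(aln.length),
                hsps=hsps,
            )
        )

    hits.sort(key=lambda h: -h.bit_score)

    column_count = query_len // 3 if program == "blastx" else query_len
    query_seq = None
    if query_fasta is not None and program != "blastx":
        seq = str(next(SeqIO.parse(str(query_fasta), "fasta")).seq).upper()
        if len(seq) != query_len:
            raise ParseError(
                f"query FASTA length {len(seq)} does not match report "
                f"query length {query_len}"
            )
        query_seq = seq
    if query_seq is None:
        query_seq = _reconstruct_query(hits, column_count, program)

    result = BlastResult(
        program=program,
        query_id=rec.query or rec.query_id,
        query_seq=query_seq,
        query_len=query_len,
        db_name=rec.database,
        hits=hits,
    )
    return cap_hits(result, max_hits)


def _reconstruct_query(hits: list[Hit], column_count: int, program: str) -> str:
    """Rebuild the (column-space) query from HSP query strings."""
    fill = "N" if program == "blastn" else "X"
    cols = [fill] * column_count
    for hit in hits:
        for hsp in hit.hsps:
            pos = hsp.query_start
            for ch in hsp.aligned_query:
                if ch != "-":
                    if 0 <= pos < column_count:
                        cols[pos] = ch
                    pos += 1
    return "".join(cols)


def cap_hits(result: BlastResult, max_hits: int = MAX_HITS) -> BlastResult:
    """Return a copy of ``result`` keeping only the first ``max_hits`` hits."""
    if max_hits < 1:
        raise SelectionError(f"max_hits must be >= 1, got {max_hits}")
    if len(result.hits) <= max_hits:
        return result
    return replace(result, hits=result.hits[:max_hits])


def hit_feature_table(result: BlastResult):
    """Per-hit feature summary as a DataFrame.

    Columns: hit_id, species, e_value, bit_score, percent_similarity,
    coverage.  Missing taxonomy is rendered as the explicit marker
    ``"unknown"``.
    """
    import pandas as pd

    from .selection import coverage_of_hit, percent_similarity_of_hit

    rows = []
    for hit in result.hits:
        rows.append(
            {
                "hit_id": hit.hit_id,
                "species": hit.species if hit.species else "unknown",
                "e_value": hit.e_value,
                "bit_score": hit.bit_score,
                "percent_similarity": percent_similarity_of_hit(
                    hit, program=result.program
                ),
                "coverage": coverage_of_hit(hit, result.column_count),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hit_id",
            "species",
            "e_value",
            "bit_score",
            "percent_similarity",
            "coverage",
        ],
    )
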