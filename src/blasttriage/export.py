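"""FASTA export and the end-to-end pipeline runner.

BLAST XML only carries the locally aligned HSP segments of each subject,
never the full database record.  Exported sequences are therefore the
ungapped concatenation of a hit's kept HSP segments, flagged ``partial``
in the header — unless a subject FASTA with the full sequences is
supplied (e.g. the simulator's truth, or a local copy of the database).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from . import blast_io, pseudo_msa, selection, similarity_tree, taxonomy
from .blast_io import BlastResult
from .errors import SelectionError

logger = logging.getLogger("blasttriage")


def hit_sequence(hit, subject_seqs: Optional[dict[str, str]] = None) -> tuple[str, bool]:
    """Best available sequence for a hit and whether it is partial."""
    if subject_seqs:
        for key in (hit.hit_id, hit.accession):
            if key in subject_seqs:
                return subject_seqs[key], False
    kept = sorted(pseudo_msa.resolve_hsps(hit), key=lambda h: h.hit_start)
    seq = "".join(h.aligned_hit.replace("-", "") for h in kept)
    return seq, True


def export_fasta(
    result: BlastResult,
    selected_labels: Iterable[str],
    out_path: str | Path,
    subject_fasta: Optional[str | Path] = None,
) -> Path:
    """Write the selected hits as FASTA, in result (score) order."""
    labels = set(selected_labels)
    if not labels:
        raise SelectionError("cannot export an empty selection")
    subject_seqs: Optional[dict[str, str]] = None
    if subject_fasta is not None:
        subject_seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(subject_fasta), "fasta")
        }
    out_path = Path(out_path)
    n = 0
    with open(out_path, "w") as fh:
        for hit in result.hits:
            if hit.hit_id not in labels:
                continue
            seq, partial = hit_sequence(hit, subject_seqs)
            species = hit.species or "unknown"
            flag = " partial" if partial else ""
            fh.write(f">{hit.accession} {species} {hit.description}{flag}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
            n += 1
    missing = labels - {h.hit_id for h in result.hits}
    if missing:
        raise SelectionError(f"selection labels not in result: {sorted(missing)[:5]}")
    logger.info("exported %d sequences to %s", n, out_path)
    return out_path


@dataclass
class RunConfig:
    """Flat, file-round-trippable configuration of one pipeline run."""

    xml: str
    outdir: str
    query_fasta: Optional[str] = None
    nodes: Optional[str] = None
    names: Optional[str] = None
    subject_fasta: Optional[str] = None
    site_mode: str = "all_sites"
    top_n: int = selection.DEFAULT_TOP_N
    rank: str = similarity_tree.DEFAULT_RANK
    e_value_threshold: Optional[float] = None
    intervals: list[tuple[str, float, float]] = field(default_factory=list)
    taxa: list[tuple[str, bool]] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for label, path in (
            ("xml", self.xml),
            ("query_fasta", self.query_fasta),
            ("nodes", self.nodes),
            ("names", self.names),
            ("subject_fasta", self.subject_fasta),
        ):
            if path is not None and not Path(path).exists():
                raise SelectionError(f"{label} path does not exist: {path}")
        if (self.nodes is None) != (self.names is None):
            raise SelectionError("nodes and names must be given together")

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"xml={self.xml}",
            f"outdir={self.outdir}",
            f"site_mode={self.site_mode}",
            f"top_n={self.top_n}",
            f"rank={self.rank}",
            f"seed={self.seed}",
            f"log_level={self.log_level}",
        ]
        for key in ("query_fasta", "nodes", "names", "subject_fasta"):
            value = getattr(self, key)
            if value is not None:
                lines.append(f"{key}={value}")
        if self.e_value_threshold is not None:
            lines.append(f"evalue={self.e_value_threshold:g}")
        for metric, low, high in self.intervals:
            lines.append(f"interval={metric}:{low:g}:{high:g}")
        for taxon, include in self.taxa:
            lines.append(f"taxon={'+' if include else '-'}{taxon}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict = {"intervals": [], "taxa": []}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("xml", "outdir", "site_mode", "rank", "log_level",
                       "query_fasta", "nodes", "names", "subject_fasta"):
                values[key] = value
            elif key == "top_n":
                values["top_n"] = int(value)
            elif key == "seed":
                values["seed"] = int(value)
            elif key == "evalue":
                values["e_value_threshold"] = float(value)
            elif key == "interval":
                metric, low, high = value.split(":")
                values["intervals"].append((metric, float(low), float(high)))
            elif key == "taxon":
                include = not value.startswith("-")
                name = value[1:] if value[:1] in "+-" else value
                values["taxa"].append((name, include))
            else:
                raise SelectionError(f"unknown config key {key!r}")
        return cls(**values)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Parse → annotate → filter → stack → tree → export, deterministically.

    Returns the output bundle: Newick tree, annotation TSV, per-hit
    feature table, selected-hit FASTA and the run log.  Every filter
    step logs hit counts before and after.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        result = blast_io.parse_blast_xml(config.xml, query_fasta=config.query_fasta)
        logger.info("parsed %s: %d hits, query length %d (%s)",
                    config.xml, len(result.hits), result.query_len, result.program)

        table = None
        if config.nodes:
            table = taxonomy.load_taxdump(config.nodes, config.names)
            taxonomy.annotate_hits(result, table)
            n_annot = sum(1 for h in result.hits if h.taxid is not None)
            logger.info("taxonomy: %d/%d hits annotated", n_annot, len(result.hits))

        state = selection.SelectionState(
            e_value_threshold=config.e_value_threshold,
            top=config.top_n,
            intervals=list(config.intervals),
            taxa=[(int(t) if str(t).isdigit() else t, inc) for t, inc in config.taxa],
        )
        selected = {h.hit_id for h in result.hits}
        if state.e_value_threshold is not None:
            before = len(selected)
            selected &= selection.apply_evalue_threshold(result, state.e_value_threshold)
            logger.info("evalue<=%g: %d -> %d hits",
                        state.e_value_threshold, before, len(selected))
        for metric, low, high in state.intervals:
            before = len(selected)
            selected &= selection.select_interval(result, metric, low, high)
            logger.info("%s in [%g,%g]: %d -> %d hits",
                        metric, low, high, before, len(selected))
        for taxon, include in state.taxa:
            before = len(selected)
            selected &= taxonomy.select_by_taxon(result.hits, table, taxon, include)
            logger.info("taxon %s%s: %d -> %d hits",
                        "+" if include else "-", taxon, before, len(selected))
        scope = selection.top_n(result, n=config.top_n, within=selected)
        logger.info("tree scope: top-%d of %d selected hits -> %d leaves + query",
                    config.top_n, len(selected), len(scope))
        if not scope:
            raise SelectionError("no hits pass the configured filters")

        msa = pseudo_msa.stack(result)
        tree = similarity_tree.rebuild_tree(
            result, msa=msa, selection=scope,
            site_mode=config.site_mode, rank=config.rank,
        )

        outputs = {
            "newick": outdir / "tree.nwk",
            "annotations": outdir / "annotations.tsv",
            "features": outdir / "features.tsv",
            "fasta": outdir / "selected.fasta",
            "log": log_path,
        }
        outputs["newick"].write_text(similarity_tree.to_newick(tree) + "\n")
        similarity_tree.write_annotations(tree, outputs["annotations"])
        blast_io.hit_feature_table(result).to_csv(
            outputs["features"], sep="\t", index=False
        )
        export_fasta(result, scope, outputs["fasta"],
                     subject_fasta=config.subject_fasta)
        logger.info("wrote %d output files to %s", len(outputs), outdir)
        return outputs
    finally:
        logger.removeHandler(handler)
        handler.close()
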