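"""Hit-selection model: metrics, thresholds, histograms, top-N.

Small-scale selection works on the top-N (default 100) best-scoring hits;
large-scale selection samples the entire capped hit list through an
E-value threshold, interval selections on three alignment statistics
(bit score, percent similarity, alignment coverage) and taxonomic
selection.  All filters are pure set operations over hit ids and compose
by intersection, so applying them in any order gives the same result.

Metric conventions (fixed here because interactive UI semantics are
inherently under-specified): E-value and interval bounds are inclusive;
a score-threshold "click" at t is the interval [t, +inf); coverage and
percent similarity are computed over the *kept* (post-resolve) HSPs, the
ones that actually enter the stacked alignment — coverage as the query
fraction covered by their union, similarity pooled (length-weighted)
across them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .blast_io import BlastResult, Hit
from .errors import SelectionError
from .pseudo_msa import resolve_hsps

METRICS = ("bit_score", "percent_similarity", "coverage")

DEFAULT_TOP_N = 100


def coverage_of_hit(hit: Hit, query_len: int) -> float:
    """Fraction of the query covered by the union of kept HSP intervals."""
    kept = resolve_hsps(hit)
    covered = 0
    for hsp in kept:  # kept HSPs are disjoint on the query
        lo = max(0, hsp.query_start)
        hi = min(query_len, hsp.query_end)
        covered += max(0, hi - lo)
    return covered / query_len if query_len else 0.0


def percent_similarity_of_hit(hit: Hit, program: str = "blastp") -> float:
    """Pooled percent similarity over kept HSPs.

    100 * sum(positives) / sum(align_len); for blastn, where BLAST
    reports no conservative substitutions, identities stand in for
    positives.
    """
    kept = resolve_hsps(hit)
    total = sum(h.align_len for h in kept)
    if total == 0:
        return 0.0
    if program == "blastn":
        num = sum(h.identities for h in kept)
    else:
        num = sum(h.positives for h in kept)
    return 100.0 * num / total


def metric_value(hit: Hit, metric: str, result: BlastResult) -> float:
    if metric == "bit_score":
        return hit.bit_score
    if metric == "percent_similarity":
        return percent_similarity_of_hit(hit, program=result.program)
    if metric == "coverage":
        return coverage_of_hit(hit, result.column_count)
    raise SelectionError(
        f"unknown metric {metric!r}; expected one of {METRICS}"
    )


def apply_evalue_threshold(result: BlastResult, threshold: float) -> set[str]:
    """Ids of hits whose best E-value is <= threshold (inclusive)."""
    if threshold < 0:
        raise SelectionError(f"E-value threshold must be >= 0, got {threshold}")
    return {h.hit_id for h in result.hits if h.e_value <= threshold}


@dataclass
class MetricHistogram:
    """Ranked values and an equal-width binning of one alignment metric."""

    metric: str
    ranked_values: list[float]      # decreasing, one per hit in scope
    bin_edges: list[float]          # strictly increasing, len = n_bins + 1
    counts: list[int]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_low\tbin_high\tcount\n")
            for lo, hi, c in zip(self.bin_edges, self.bin_edges[1:], self.counts):
                fh.write(f"{lo:g}\t{hi:g}\t{c}\n")


def metric_histogram(
    result: BlastResult, metric: str, n_bins: int = 20
) -> MetricHistogram:
    """Distribution of one metric over all hits in scope.

    Values come back ranked in decreasing order (the score-histogram
    view) plus equal-width bins over [min, max] (the distribution view).
    Zero hits give an empty histogram rather than an error.
    """
    values = sorted(
        (metric_value(h, metric, result) for h in result.hits), reverse=True
    )
    if not values:
        return MetricHistogram(metric=metric, ranked_values=[], bin_edges=[], counts=[])
    lo, hi = min(values), max(values)
    if lo == hi:  # degenerate range: a single bin holding everything
        edges = [lo, lo + 1.0]
        counts = [len(values)]
    else:
        counts_arr, edges_arr = np.histogram(values, bins=n_bins, range=(lo, hi))
        edges = edges_arr.tolist()
        counts = counts_arr.tolist()
    return MetricHistogram(
        metric=metric, ranked_values=values, bin_edges=edges, counts=counts
    )


def select_interval(
    result: BlastResult, metric: str, low: float, high: float
) -> set[str]:
    """Ids of hits with low <= metric <= high (closed interval)."""
    if low > high:
        raise SelectionError(f"interval low {low} exceeds high {high}")
    return {
        h.hit_id
        for h in result.hits
        if low <= metric_value(h, metric, result) <= high
    }


def top_n(
    result: BlastResult,
    n: int = DEFAULT_TOP_N,
    within: Optional[Iterable[str]] = None,
) -> list[str]:
    """The n best-scoring hit ids, optionally restricted to ``within``.

    Returns hit ids in descending-score order; fewer than n hits just
    returns them all (the remaining hits stay available to the
    large-scale tools).
    """
    if n < 1:
        raise SelectionError(f"top_n needs n >= 1, got {n}")
    scope = result.hits
    if within is not None:
        allowed = set(within)
        scope = [h for h in scope if h.hit_id in allowed]
    ranked = sorted(scope, key=lambda h: -h.bit_score)
    return [h.hit_id for h in ranked[:n]]


@dataclass
class SelectionState:
    """Reproducible record of the active filters.

    ``intervals`` is a list of (metric, low, high) triples;
    ``taxa`` a list of (taxon, include) pairs resolved against a
    taxonomy table at application time.  Filters intersect.
    """

    e_value_threshold: Optional[float] = None
    top: int = DEFAULT_TOP_N
    intervals: list[tuple[str, float, float]] = field(default_factory=list)
    taxa: list[tuple[Union[int, str], bool]] = field(default_factory=list)

    def apply(self, result: BlastResult, taxonomy=None) -> set[str]:
        """Intersection of all active filters over the capped hit list."""
        selected = {h.hit_id for h in result.hits}
        if self.e_value_threshold is not None:
            selected &= apply_evalue_threshold(result, self.e_value_threshold)
        for metric, low, high in self.intervals:
            selected &= select_interval(result, metric, low, high)
        if self.taxa:
            from .taxonomy import select_by_taxon

            if taxonomy is None:
                raise SelectionError(
                    "taxonomy filters require a taxonomy table"
                )
            for taxon, include in self.taxa:
                selected &= select_by_taxon(result.hits, taxonomy, taxon, include)
        return selected

    def small_scale_scope(self, result: BlastResult, taxonomy=None) -> list[str]:
        """Top-N ids among the hits passing the active filters."""
        return top_n(result, n=self.top, within=self.apply(result, taxonomy))

    # -- flat key=value (de)serialisation ----------------------------------

    def to_config(self) -> str:
        lines = [f"top_n={self.top}"]
        if self.e_value_threshold is not None:
            lines.append(f"evalue={self.e_value_threshold:g}")
        for metric, low, high in self.intervals:
            lines.append(f"interval={metric}:{low:g}:{high:g}")
        for taxon, include in self.taxa:
            lines.append(f"taxon={'+' if include else '-'}{taxon}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SelectionState":
        state = cls()
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "top_n":
                state.top = int(value)
            elif key == "evalue":
                state.e_value_threshold = float(value)
            elif key == "interval":
                metric, low, high = value.split(":")
                state.intervals.append((metric, float(low), float(high)))
            elif key == "taxon":
                include = not value.startswith("-")
                name = value[1:] if value[:1] in "+-" else value
                taxon: Union[int, str] = int(name) if name.isdigit() else name
                state.taxa.append((taxon, include))
            else:
                raise SelectionError(f"unknown selection config key {key!r}")
        return state


SCORE_INFINITY = math.inf


def score_threshold(result: BlastResult, threshold: float) -> set[str]:
    """The score-histogram "click": hits scoring at least ``threshold``."""
    return select_interval(result, "bit_score", threshold, SCORE_INFINITY)
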