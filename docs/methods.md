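# Methods

This note documents the models, conventions and design choices behind
`blasttriage`, in the spirit of a methods appendix: what each component
computes, which parameters matter, and what the synthetic data used in
testing does and does not establish about real BLAST output.

## Input model

Only NCBI BLAST XML (`-outfmt 5`) is accepted: it is the one standard
report format that carries the gapped alignment strings HSP stacking
requires; tabular formats do not.  Supported programs are blastn,
blastp, blastx and tblastn.  tblastx is rejected because its alignments
live in overlapping reading frames on both sequences and cannot be
projected onto a single query coordinate system.  Reports are
single-query; multi-query files are refused with instructions rather
than silently truncated.

Coordinates are converted to 0-based half-open on ingest; the XML's
1-based inclusive convention survives only at I/O boundaries.  Minus-
strand blastn HSPs are normalised (subject coordinates swapped, strand
flag retained, alignment strings kept query-forward as reported).  At
most 5,000 hits are retained per report, the best-scoring first; a hit's
reported score and E-value are those of its best (highest bit-score)
HSP, with the E-value reported as the minimum over its HSPs — for
single-domain hits the two coincide, and for multi-domain hits the best
HSP dominates both.

BLAST XML does not carry the full query sequence.  When a query FASTA is
supplied it is used verbatim (after a length check); otherwise the query
is reconstructed from the HSP query strings, with `X` (protein) or `N`
(nucleotide) at positions no HSP covers.  Reconstruction is exact
wherever at least one HSP aligns, which in practice is every position
that matters to the alignment.

For blastx the analysis happens at the protein level: nucleotide query
coordinates map to codon columns (`(pos-1)//3` forward,
`(len-pos)//3` reverse), the column space is `query_len // 3`, and
within each hit only HSPs sharing the reading frame of its best HSP are
kept — concatenating frame-shifted HSPs of one hit would interleave
incompatible translations.

## HSP stacking

The pseudo multiple alignment has exactly one column per query residue.
Each hit residue aligned to query position *i* is written into column
*i*; alignment columns where the query carries a gap (insertions in the
hit) have no column and are **dropped** — the stacking is deliberately
lossy in exchange for speed and a fixed coordinate system.  Hit regions
not aligned to the query become gap characters.

Within a hit, HSPs are resolved greedily by descending bit score (ties:
lower query start, then input order); an HSP whose query interval
intersects an already-kept one is discarded entirely.  Overlap means a
non-empty intersection of half-open intervals, so adjacent HSPs do not
overlap and are concatenated.  Partial overlaps are treated like full
overlaps — the lower-scoring HSP is dropped whole rather than trimmed,
because trimming would manufacture alignment content no aligner
produced.  For a tandem-duplicated domain, where each repeat unit yields
an HSP over the same query region, this keeps exactly the repeat unit of
the highest-scoring pair.

External sequences (at most five per selection) are globally aligned to
the ungapped query — affine gaps; BLOSUM62 with open 10/extend 0.5 for
protein, +2/−3 with open 5/extend 2 for nucleotide; the aligner object
can be replaced by the caller — and then projected into query columns
exactly as HSPs are, insertions dropped.

## Distances and the similarity tree

p-distance = mismatches / compared columns, uncorrected for multiple
substitutions, as appropriate for a triage tree rather than a
publication phylogeny.  Two site modes:

- **all_sites** (default, used for the initial tree): each pair is
  compared over the columns where both rows carry residues (pairwise
  deletion);
- **gap_free**: only columns with no gap in *any* selected row enter,
  identically for every pair; requesting it when no such column exists
  is an error that advises all_sites.

A pair with zero comparable columns is assigned distance 1.0 with a
warning instead of failing, so one non-overlapping hit cannot abort a
whole tree build.  The gap-free site counter reports, for any selection,
the number of columns residue-complete across the query and all selected
rows — the quick proxy for usable phylogenetic signal, recomputed on
every selection change.

Neighbor joining is the standard agglomerative algorithm on the
Q-criterion.  Determinism and degeneracy handling: ties in Q break on
the lexicographically smallest index pair; negative branch lengths
(possible on non-additive input) are clamped to zero; the output is
unrooted, represented with a trifurcating root (bifurcating for the
two-leaf case, which splits the single distance in half).  On additive
input the algorithm is exact, which the tests exploit: random additive
matrices must be recovered with Robinson-Foulds distance 0 and path
lengths reproduced to 1e-6, and small cases must agree with an
independently coded textbook NJ and with scikit-bio's implementation.

Leaves are renamed by species, with the accession appended whenever a
species name is shared or unknown.  Each leaf gets a taxonomy group —
its lineage name at a configurable rank, defaulting to phylum, which
gives informative coarse groups for typical mixed-kingdom hit lists —
and a color index cycled deterministically over a 12-slot palette in
group-first-appearance order.  Newick labels are sanitised (spaces to
underscores; parentheses, commas, colons, semicolons, quotes and
brackets stripped) and branch lengths written at 12 significant digits.

## Taxonomy

Taxonomies load from flat files in the NCBI taxdump column layout
(pipe-delimited `nodes.dmp` / `names.dmp`); only "scientific name"
entries are indexed so the name→taxid map stays unambiguous.  Orphan
parents and cycles are integrity errors at load time.  A ~60-node
fixture taxonomy (three bacterial phyla, one archaeal, four eukaryote
phyla, sixteen species) ships with the package so examples and tests
need no download; it uses real NCBI taxids so results transfer.

Species resolution per hit: an explicit taxid wins; otherwise the last
bracketed `[...]` span of the description — the NR convention for
organism names — is matched against the name index; anything else
degrades to unknown rather than erroring.  Taxonomic selection is
lineage membership (include) or its complement among annotated hits
(exclude); hits without taxonomy never match either direction, so
include/exclude partitions exactly the annotated hits.  The hierarchical
summary conserves the total hit count at every depth, with unknowns in a
dedicated bucket under the root.

## Selection semantics

Interactive UI semantics are inherently under-specified, so they are
fixed here for determinism: E-value threshold and metric intervals are
closed (inclusive at both ends); the score-histogram "click" at *t*
means `score >= t`; all filters are pure set operations over hit ids and
compose as intersections, hence order-independent.  Coverage is the
query fraction covered by the union of the *kept* HSP intervals, and
percent similarity pools positives over kept HSPs length-weighted
(identities stand in for positives under blastn) — both consistent with
the stacked alignment rather than the raw HSP list.  The small-scale
scope is the top-N (default 100) best-scoring hits among those passing
the active filters; remaining hits stay in memory for the large-scale
tools.

## The simulator

`simulate_dataset` emulates what a BLAST search of evolving homologs
would report.  Sequences evolve from a common ancestor along a tree
(star, balanced or random topology) whose leaves are the query and the
hits, under i.i.d. per-site substitution with uniform replacement over
the other alphabet letters.  For a path of branches with substitution
probabilities p_e over a k-letter alphabet the expected p-distance has
the closed form

    E[d] = 1 - 1/k - (1 - 1/k) * prod_e (1 - p_e * k/(k-1)),

which the tests verify both against a tiny Monte-Carlo chain and against
star-tree simulations (observed mean within three standard errors).

Alignment features are then layered per hit: a contiguous coverage
window (fraction drawn from `coverage_range`); optionally a split into
two disjoint HSPs with an unaligned middle (multi-domain hits);
optionally a tandem duplication — a second, strictly more diverged copy
of the covered segment producing a second HSP over the same query span.
The duplicated copy mutates only positions that match the query, so its
score is strictly lower by construction and the repeat-unit rule has an
unambiguous truth.  Duplicated hits carry no indels so the two copies'
score ranking is exact.  Indels elsewhere are i.i.d. per column with
geometric lengths (capped at 5), deletions and insertions equally
likely.

Synthetic scores are a fixed monotone transform of alignment quality:
`raw = 2*matches - mismatches - 2*gapcolumns`,
`bit = 0.25*(raw + 2*align_len) + 1` (strictly monotone in raw, always
positive), `E = 10^(-bit/10)`.  Only the ordering matters to the tools
under test; no Karlin-Altschul statistics are attempted.  Everything is
driven by one integer seed; the same seed yields byte-identical XML.

Defaults are chosen as a realistic protein use case: 300-residue query,
full-coverage hits, per-branch substitution probability around 0.1
(random trees jitter each branch uniformly in [0.5, 1.5] x the rate).
The end-to-end recovery experiment uses substitution-only, full-coverage
simulation at rate 0.05 over 12 leaves, since what it isolates is
topology recovery from p-distance estimates, not robustness to partial
coverage.

What the simulator does **not** emulate — and hence what passing tests
do not establish about real data: BLAST's score statistics and E-value
calibration, compositional bias, low-complexity regions, genuinely
missing HSPs for diverged homologs, alignment errors near gap ends, and
rate heterogeneity across sites.  The tests establish that the machinery
is correct under its stated model, not that p-distance NJ on stacked
HSPs is an accurate phylogeny — by design it is a fast approximation for
triage.

## Problem sizes and numerics

The shipped test and acceptance runs use datasets of 12-6,000 hits with
queries of 40-400 residues — large enough to exercise every code path
(cap, top-100 scope, duplications, splits, partial coverage) while the
full suite completes in seconds.  NJ is O(n^3) in pure Python/NumPy and
comfortable at the 101-leaf default scope.  Distance matrices are
validated on construction (symmetry to 1e-12, zero diagonal, [0, 1]
bounds); NJ tie-breaks use a 1e-15 strict-improvement margin so float
noise cannot reorder joins across platforms.

## Known limitations

- Full subject sequences are not in BLAST XML; FASTA export emits the
  concatenated kept-HSP segments flagged `partial` unless a subject
  FASTA is supplied.
- blastx support is limited to single-frame stacking per hit; the
  reverse-frame column mapping is approximate at codon boundaries.
- No correction for multiple substitutions is offered (p-distance only),
  and no bootstrap or likelihood methods — out of scope for a triage
  tree.
- merged/deleted taxids (merged.dmp) are not handled; taxonomies are
  assumed internally consistent.
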