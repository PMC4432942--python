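# Methods

## Data model

A dataset is a typed contig table plus optional sequences and gene
annotations, cross-referenced by contig id. Column kinds are inferred
from the delimited file: a column is *numeric* iff every non-missing
cell is a plain real number (scientific notation accepted; thousands
separators, `inf` and `nan` tokens deliberately rejected so inference
is deterministic), otherwise *ordinal*. Missing cells are empty
strings on disk, NaN/None in memory, and are excluded from filters,
binning, gradients, and gate matching (a contig with a missing value
can never satisfy a range condition — conservative exclusion).

Roles follow the upload-wizard convention: exactly one `id` column;
at most one each of `x`, `y`, `size`, `color`; every numeric column
not claimed by a plot property automatically becomes a `filter`;
everything else is `info`. FASTA ids must be a subset of the table's
contigs (a foreign FASTA is an error); GFF3 features on unknown
contigs are dropped with a logged count, since partial annotation
files are common.

GC content is (#G + #C) / (#A + #C + #G + #T), case-insensitive, with
N and IUPAC ambiguity codes excluded from the denominator (undefined
when no unambiguous base exists). Including ambiguous bases would bias
gappy contigs toward arbitrary values; excluding them leaves GC a
property of the observed bases only.

## Lineage collapse

Lineages are positional strings (`;`-separated, trimmed, empty
segments dropped); no rank-name validation is attempted against any
reference taxonomy. The contig-count-weighted prefix tree is collapsed
by greedy frontier refinement (see README for the loop): always expand
the heaviest expandable frontier node that still fits the bound, ties
by name. Two design points deserve note:

* **Terminator retention.** A contig whose lineage ends at an internal
  node would lose its deepest selected ancestor when that node is
  expanded. Such nodes are retained in the frontier alongside their
  children (counted against the bound, marked non-expandable). This
  keeps the partition a full cover without inventing pseudo-taxa.
* **Weighting.** Nodes are prioritised by contig count. Length- or
  leaf-weighted variants would be easy, but count-weighting matches
  the goal of giving legend colors to the groups with the most points.

The result is maximal — no single frontier node can be refined within
the bound — which the tests verify against exhaustive enumeration of
every downward-closed expansion set on trees with ≤ 12 internal nodes.
One property that does *not* hold: the contig-weighted mean assignment
depth is not monotone in the bound k. A larger budget can admit an
early wide expansion that redirects later refinements (tests carry a
40-contig counterexample where the mean depth drops from 1.258 at
k = 9 to 1.194 at k = 10). The mean depth is, however, always
bracketed by the k = 1 and fully-refined partitions, and that is what
the property test asserts.

Unclassified contigs form a reserved `Unclassified` group rather than
being dropped: they must remain plottable and hideable like any other
group.

## Search, filters, gates

Search is case-insensitive substring over the canonical text rendering
of every metadata field (so `3051` finds a coverage of `3051.0`) plus
every annotation feature's type and attribute values; a contig's hit
count is (#matching fields) + (#matching features). Regular
expressions sit behind an explicit flag. Range filters conjoin with
inclusive bounds. Genome-bin gates are user-chosen axis-aligned
rectangles in the (GC, coverage) plane, first match wins; no automatic
clustering is attempted — the package deliberately stops at manual
gating, leaving algorithmic binning to dedicated tools.

## Color and size

"Statistical binning" of a quantitative column is equal-frequency by
default: the j-th edge is the ⌈j·n/k⌉-th order statistic, deduplicated,
and edges equal to the maximum are dropped so the top bin is never
empty; bins are left-open right-closed except the first. Quantile bins
were chosen over equal-width as the default because metagenome
coverage is heavy-tailed; equal-width is available as an option.
Gradients interpolate each RGB channel linearly over the observed
range, endpoints mapping exactly, constant columns to the low color.
The qualitative palette is a fixed 20-color list; group i receives
color i mod 20.

Mark *area* is proportional to the size column (radius
= r_min + (r_max − r_min)·√(v/v_max), clamped to [2, 40] display
units); area-proportionality is the perceptually standard choice for
bubble plots. Coverage axes default to log10 (values span orders of
magnitude), GC to linear; non-positive values on a log axis are
dropped and counted, never offset, so positions are not silently
distorted. The plot spec records every exclusion, and
marks + filtered + hidden + dropped always equals the contig total.

The HTML renderer embeds the canonical JSON payload (sorted keys,
compact separators — byte-stable across renders) and draws it with a
small inline SVG script offering pan, zoom and hover. The tested
contract is the payload, not pixels.

## The synthetic community

`santa_barbara_toy(seed)` emulates the *structure* of an oil-seep
metagenome at desk scale (453 contigs, ~1.1 Mbp):

* six archaeal genomes, 50 contigs each, GC means 0.30–0.70 in steps
  of 0.08 (between-contig SD 0.015), coverage medians 60–520× with
  log-scale SD 0.12, contig lengths log-normal around 3 kb;
* ~136 background contigs from >100 distinct bacterial species
  lineages across six phyla, short (~800 bp) and at 3–9× coverage;
* one 44 kb contig at exactly 3051× coverage (a putative mobile
  element) — by construction the only contig above 10× the global
  median coverage;
* eight unclassified contigs;
* seven planted Pfam-shaped token families (`PF00801`–`PF00807`) on
  known carrier contigs; one genome carries two families planted on
  28 + 28 of its 50 contigs, so some carriers hold two tokens by
  pigeonhole regardless of seed. Decoy domain tokens on other genes
  come from the disjoint `PF9xxxx` range.

Sequences are i.i.d. bases with a per-contig GC probability drawn from
a truncated normal; gene models of 300–1500 bp are tiled along each
contig on alternating strands. All randomness flows through one
`numpy.random.default_rng(seed)` (PCG64), so output is byte-identical
across platforms. The taxonomy tree and hence the collapse result are
independent of the seed (lineages and contig counts are fixed by the
model list).

The coverage ladder (60, 95, 150, 230, 350, 520×) and GC spacing were
chosen so that ±3 SD rectangular gates around the planted centroids
are essentially disjoint: the expected per-contig misassignment rate
is ~1–2% (GC noise is the per-contig draw plus binomial sequence
noise), comfortably inside the ≥95% recovery the tests require, and
so that the mobile element is the unique 10×-median coverage outlier.

What the generator does **not** emulate: sequence homology or codon
structure, read-level errors, chimeric contigs, strain variation,
correlated GC along a contig, or realistic assembly-size distributions
(a real assembly has 10³–10⁶× more contigs). Passing tests therefore
demonstrate the correctness of the bookkeeping and algorithms, not
robustness to biological messiness in real annotations.

## Problem sizes and tolerances

Tests run the toy community (453 contigs), random trees of ≤ 40
contigs for collapse properties, and ≤ 12-internal-node trees for the
exhaustive oracle sweep; the whole suite completes in seconds. GC
recovery is asserted to 0.03 at n = 50 contigs per genome (SE ≈ 0.002,
so the tolerance is ~10 SE); bin recovery at ≥ 95% against a ~98%
expectation; quantile-bin occupancies exactly, since 5 divides 100.
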