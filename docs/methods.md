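# Methods

## Coordinate and breakend conventions

All internal coordinates are 0-based half-open; conversions from 1-based
formats (VCF) happen only at read time. A breakend is a chromosome,
position and orientation: `head` means the derivative chromosome retains
the sequence to the left of the position (BEDPE strand `+`), `tail` the
sequence to the right (strand `-`). VCF breakend ALT bracket notation maps
onto this vocabulary as: the local breakend is `head` when the ALT starts
with the reference base, `tail` when it starts with a bracket; the mate is
`tail` for `[` and `head` for `]`. Junctions are stored in canonical order
(breakends sorted by chromosome then position) so the same physical
rearrangement read from BEDPE or VCF compares equal. Chromosome names are
taken verbatim — mixed-reference inputs fail loudly rather than being
silently aliased. Unpaired VCF breakend records, which real caller output
contains, are dropped with a warning rather than treated as fatal.

## Complex-event classification

Chained rearrangements are found on a per-sample junction graph: two
junctions are linked when they each have a breakend on the same chromosome
within `w_chain` (default 1 Mb), and connected components with at least
`min_junctions` (default 3) junctions become candidate events. Both
thresholds are exposed; the defaults make recovery on the synthetic
cohorts unambiguous while remaining in the range used for chained-event
calling in cancer genomes.

**Bridges.** For each pair of chained breakends from *different* junctions
on one chromosome (within `w_chain` of each other), the intervening
interval is a bridge. Its copy-number delta is the length-weighted modal
total copy number inside the bridge minus the modal copy number of the two
flanking regions (1 Mb each side, clipped at chromosome ends); modal
rather than mean copy number makes the delta robust to focal noise, and
ties break to the lower copy number for determinism. A negative delta is a
deletion bridge, positive a gain bridge.

**Chromothripsis detection.** Per chromosome, breakends are clustered
(adjacent breakends ≤ `ct_window`, default 50 Mb, apart). A cluster is
called when it has ≥ `min_breakends` (default 10) breakends, the copy-
number segments spanning it make ≥ `min_oscillations` (default 7)
transitions that alternate between the two most frequent copy-number
states (a transition touching any other state does not count), and —
unless `require_loh` is disabled — the span contains a segment with minor
copy number 0 and total ≥ 1. The oscillation-between-two-dominant-states
rule separates genuine shattering profiles from staircase-like gains; the
LOH switch exists because near-tetraploid genomes can oscillate without
reaching minor copy number zero.

**Labels and precedence.** A candidate whose junctions lie ≥ 50% inside a
chromothripsis region call is labelled chromothripsis; chromothriptic
regions generate incidental bridges, so this outranks the bridge rules and
prevents double-labelling. Otherwise a candidate with more deletion than
gain bridges (and ≥ 2 of them) is chromoplexy; the mirror-image condition
gives templated insertion, flagged `simple_chain` when only two
chromosomes are involved (the "complex" flavour of templated insertion
requires more than two). Everything else is reported as unclassified
complex. Classification is invariant to junction input order, and each
junction belongs to at most one event (components partition the graph).

## Burden, elbow and hotspots

Per-sample burden counts split junctions into intra- and
inter-chromosomal; subgroup comparisons use the Kruskal–Wallis test (for
two groups this is the rank test whose statistic is conventionally
reported as a chi-square). The high/low burden split sorts counts
descending, normalizes both axes to [0, 1], and takes the elbow as the
index with maximum perpendicular distance to the chord joining the curve's
endpoints; samples strictly above the elbow count are high, ties go low,
and a constant vector yields an empty high set. Normalizing the axes makes
the split invariant to rescaling the counts; on overlapping mixtures the
geometric elbow sits slightly into the low-group tail, so recovered
high-burden fractions run a point or two above the planted fraction.

Translocation hotspots bin both breakends of every translocation into
fixed-width bins (default 1 Mb, matching locus-level resolution) and count
*distinct* samples per bin — a sample with many breakends in one bin
counts once (the per-incidence count is also reported). The null is a
uniform genome-wide rate: each sample hits any bin with probability
(total sample-bin incidences)/(bins × cohort size); the per-bin p-value is
the binomial upper tail, with p = 1 for bins at or below the expected
count (no evidence of enrichment), BH-corrected across bins.

## TAD-disruption expression screen

Breakends are assigned to TADs by binary search under half-open
containment; positions in inter-TAD gaps get a boundary sentinel and
chromosomes without TADs a no-TAD sentinel. A TAD–TAD rearrangement joins
two distinct real TADs (boundary-touching junctions are kept but flagged
and excluded from the carrier definition). Neo-TADs follow breakend
orientation: a head breakend retains [tad start, position), a tail
breakend [position, tad end); genes overlapping either retained interval
are the fused domain's gene set.

Samples are grouped per single TAD — carrier if any TAD–TAD junction
touches it, control otherwise; carriers are compared against *all*
non-carriers. Each gene in a touched TAD gets a one-way ANOVA on log2
expression (with two groups the F statistic equals the squared pooled
t statistic); BH correction runs across all (TAD, gene) tests of the run —
the widest, most conservative family. A gene passes when it has
≥ `min_cases` (default 5) carriers, a median log2 expression >
`min_median` (default 2, interpreted on the same normalized log2 scale as
the input matrix) in at least one group, and q < `alpha` (default 0.05).
Under-powered genes are still reported, marked failed. The boundary
contrast splits samples into inside-TAD / within-`flank` (default 2 Mb)
outside / unaffected, with inside taking precedence for mixed samples, and
tests the gene's expression across groups with Kruskal–Wallis.

Degenerate inputs are handled deterministically: identical carrier and
control values give p = 1 and zero fold change; constant inputs skip the
ANOVA rather than emitting NaN.

## Synthetic cohorts

The generator emulates the structure of a newly diagnosed myeloma WGS
cohort on a toy genome of 5 × 50 Mb chromosomes tiled with 1 Mb TADs
separated by 100 kb boundary gaps, 3 genes per TAD. Per sample:

- simple SV counts are negative binomial — mean 31 with size 10 for
  baseline samples, mean 102 with size 10 for the 10% high-burden
  subpopulation (the means follow the reported cohort and high-burden
  medians; the baseline size parameter was calibrated so the maximum count
  over a ~700-sample cohort lands near the reported low-group maximum of
  ~76); translocations make up 6/31 of simple SVs, matching the reported
  intra/inter split;
- one planted complex event class per sample by default (a `mixed` flag
  allows co-occurrence), at prevalences 0.23 / 0.10 / 0.37 for
  chromothripsis / chromoplexy / templated insertion. Chromothripsis
  plants 16 clustered breakends whose inter-breakend segments alternate
  copy number 2 ↔ 1 with LOH on the CN-1 segments; chains plant a cyclic
  three-chromosome cycle with one short (≤ 0.7 Mb) bridge per chromosome
  at copy number 1 (deletion, chromoplexy) or 3 (gain, templated
  insertion);
- eight recurrent "super-enhancer-hijack" TADs each receive a TAD–TAD
  translocation in 20 samples (~10% of the cohort, the order of recurrent
  myeloma translocation loci), and the resident genes gain
  `effect_log2fc` (default +2) on top of Normal(5, 1) log2 expression in
  carriers.

Copy-number profiles start from a diploid heterozygous baseline per
chromosome and planted event intervals are overlaid, so segments tile each
chromosome exactly and cover every breakend. Expression is simulated
directly on the log2 scale, since the pipeline consumes normalized values.

**What the generator does not emulate.** Simple SVs are copy-neutral:
every deletion bridge, gain bridge, oscillation and LOH run in a synthetic
profile traces back to a planted complex event. Real deletions and
duplications change copy number, real chromothripsis regions are messier
than a strict two-state alternation, and real cohorts mix event classes
within samples far more than the disjoint default. Passing recovery tests
therefore demonstrates that the classifier implements its stated rules
correctly and is well-calibrated against copy-neutral chance chaining —
not that its defaults are optimal on real tumour genomes. There is also no
sequence level: junction positions are exact up to caller-style jitter
only in the timepoint-matching tests.

## Problem sizes and determinism

The test suite and the acceptance script run on 200-sample cohorts
(~8,000 junctions, ~675 genes), the scale at which every planted class has
tens of carriers while a full run stays in seconds. All randomness flows
from a single integer seed through one `numpy.random.Generator`; geometry
is integer-valued, so cohorts are reproducible across platforms, with
floats confined to the expression matrix.

## Known limitations

- The chaining rule (shared-chromosome proximity within `w_chain`) is a
  deliberate simplification of published chained-event callers; on small
  genomes it produces frequent chance components, which the classifier
  leaves unclassified rather than suppressing.
- Hotspot calling uses a uniform genome-wide null; real genomes have
  strongly non-uniform breakage rates, so on real data the test is
  anti-conservative and the descriptive per-bin counts should be read
  alongside it.
- The screen assumes one expression matrix on a shared assembly with the
  SV calls; no liftover is attempted.
- The boundary contrast and neo-TAD enumeration treat TADs as hard
  intervals; sub-TAD structure and loop-level contacts are out of scope.
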