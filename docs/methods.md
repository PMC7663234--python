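# Methods

## Segmental model of the pre-miRNA hairpin

Every analysis in this package is anchored on the hairpin precursor
(pre-miRNA) as the reference frame. A hairpin of length *L* (typically
60–110 nt) is expanded into a *window*, the hairpin plus an
`extension_flank` (default 50 nt) on each side, and the window is
partitioned into disjoint labelled intervals:

* `mature_5p`, `mature_3p` — the annotated mature products (~22 nt each);
* `undefined_complement` — when only one arm carries an annotated mature,
  the star-like interval on the opposite arm;
* `extension` — every other window position.

All coordinates are handled internally as 0-based half-open; GFF3 input is
converted from 1-based inclusive, BED is taken as is. Segment coordinates
are window-local and strand-aware (position 0 is the 5' end of the window),
so the geometry below is strand-independent.

**Undefined-complement placement.** Annotation databases record only the
arms with experimental support, so the opposite-arm interval must be
constructed. With hairpin-local mature [s, e) the complement is placed at
[L − e + overhang, L − s + overhang), `overhang` = 2 nt — the reflection of
the mature across the hairpin centre shifted 3'-ward by the Dicer 2-nt 3'
overhang. This reproduces standard star-sequence placement without RNA
folding, which we deliberately avoid: predicted secondary structure would
make the segment maps non-deterministic across folding engines, and the
mirror rule is exact and involutive (mirroring twice recovers the mature to
within ±2 · overhang, a tested property). The interval is clipped to the
hairpin and truncated, with a warning, if it would overlap the mature on a
very short hairpin.

**Extension includes the loop.** The tails "extending" a hairpin could be
read as external flanks only; we label *all* window positions not covered
by a mature/complement as `extension`, including the loop between the two
arms. For real hairpins, whose matures abut the termini, the two readings
are operationally equivalent, and the inclusive definition yields a clean
partition invariant — every window position carries exactly one label —
which the classifier and its tests rely on. The choice is recorded on the
`SegmentMap` (`includes_loop_in_extension`).

**Arm calling.** A mature is 5p when its midpoint lies in the 5' half of
the hairpin (exact midpoint ties go to 5p). Midpoints are compared as
doubled integers, so the rule is exact and annotation-free.

## Read filtering and classification

Reads arrive as aligned genomic intervals; alignment, adapter trimming and
quality filtering happen upstream. Three thresholds are applied jointly
(the predicate is a pure conjunction, so ordering cannot matter): length
≥ 17 nt, ≤ 2 mismatches, identity ≥ 90%. When the input format carries no
identity (BED), it is computed as (length − mismatches)/length, and the
BED score column is read as the mismatch count — documented in
`reads.load_reads`; the TSV format carries explicit columns and SAM uses
the `NM` tag.

A read is assignable to a hairpin only when *both* its ends lie inside the
window and the strands match (`strand_mode="both"` relaxes the strand
check; mature miRNAs are strand-specific, so same-strand is the default).
Within the window the category is the unique segment label the read
covers, else `overlap`. There is *no* fuzz tolerance at borders: one
nucleotide past a mature boundary is already an overlap read, while
isomiR-style end variation inside the mature segment still counts as
mature. When several windows fully contain a read (clustered hairpins),
the window whose midpoint is nearest the read midpoint wins; exact ties go
to the lexicographically smallest hairpin id and are logged. The
classifier is verified against an independent position-by-position
labelling oracle in the tests.

Segmental composition tables are emitted in two sample-level views,
matching the two natural readings of "composition": pooled raw counts
(abundant miRNAs dominate) and the unweighted mean of per-miRNA normalized
fractions (each miRNA contributes equally). Normalized rows sum to 1 by
construction.

## Quantification

The count matrix counts every assigned read toward its hairpin (optionally
restricted to mature-only categories). The presence rule pools a group's
replicates: a miRNA is *expressed* in a cell line when the summed raw
reads reach 10 — the "at least 10 reads per cell line" threshold applied
to the pooled triplicates. RPM normalization divides by the per-sample
total of miRNA-assigned reads (not raw library size, since only
miRNA-aligned reads survive upstream); that total is frozen on the matrix
at build time, so presence filtering and RPM scaling commute — a tested
invariant. Replicate correlations default to Pearson on log10(x + 1)
(rank-based by flag): count profiles span orders of magnitude and
log-Pearson is the common choice for such heatmaps. Differential
expression is *not* re-implemented; any externally produced table with
(miRNA, log2FC, adjusted p) is ingested, and `select_significant` applies
the strict adjusted-p < 0.05 cut with significance ordering.

## Comparative layer

Three presence sets are partitioned into the seven exclusive regions of a
three-set Venn diagram by direct membership enumeration (verified against
a brute-force oracle).

Trends discretize a test-vs-reference mean ratio with a ±20% band:
Same iff 0.8 ≤ ratio ≤ 1.2, boundaries inclusive to Same — the literal
reading of "stable within ±20%"; none of the published worked-example
triples lies near the boundary, so the inclusive choice is not
outcome-sensitive, and all 50 published labels reproduce under it (a
tested result). Zero handling is symmetric: 0 → positive is Up, positive
→ 0 is Down, 0 → 0 is Same. Partition percentages are rounded
half-away-from-zero to integers, matching how such tallies are printed.

Literature consistency compares a trend with miRCancer-style per-miRNA
publication counts (n_up, n_down). Precedence: no record — or a record
with zero publications — → `not_available`; 1–2 total publications →
`minimal_support`; both directions present → `mixed`; otherwise unanimous
literature either matches the trend (`consistent`) or contradicts it
(`opposite`). A Same trend has no direction to match against unanimous
literature; we emit `mixed` for that cell and flag the choice here, since
no convention exists for it. The verdict table is total over the
enumerated (trend × literature-state) grid — a tested property.

Fold changes are log2((test + c)/(ref + c)) with a symmetric pseudocount
c = 0.5, keeping zero means finite while vanishing for abundant miRNAs.

## Synthetic data generator

The generator emulates the *structure* of the profiled experiment — three
cell-line groups × three replicates, hairpins with matures near the
termini, genomic clusters, single-arm hairpins, segmental read mixtures,
over-dispersed counts, planted fold changes — with everything a pure
function of (spec, seed).

Defaults and why:

* `n_mirnas=30`, hairpin length 60–110 nt, matures 22 nt within 5 nt of
  the termini — typical miRBase geometry.
* `cluster_fraction=0.2`: a fifth of hairpins are placed 0.2–3 kb after
  their predecessor (chains whose within-chain gaps are provably < 10 kb),
  the rest 11–25 kb away, safely outside the cluster distance.
* `single_arm_fraction=0.35`: enough single-arm hairpins to exercise the
  undefined complement; roughly the share of miRBase hairpins with one
  annotated product.
* mixture (0.55, 0.10, 0.05, 0.12, 0.18) over (mature_5p, mature_3p,
  complement, extension, overlap): mature-dominant with a sizeable overlap
  share, echoing observed SF compositions where mature reads are ~60–68%
  in the cancer lines with substantial overlap and extension fractions.
  Infeasible categories (e.g. complement on a two-arm hairpin) are
  renormalized away per hairpin, with a warning.
* Negative-binomial counts with mean/size parameterization, size
  (`dispersion`) = 10 — variance m + m²/10, a typical replicate-level
  over-dispersion for small-RNA counts.
* Planted trends per non-reference group: 30% Up / 40% Down / 30% Same,
  |log2FC| ∈ [1, 2] for U/D, within-band wobble (×0.85–1.15) for S, and
  30% of Down miRNAs fully absent (fold change 0) to create presence-set
  structure. Trend truth is *derived* from the true means with the same
  ±20% band the comparator uses, so truth and method share one definition.
* Reference-group base means are log-normal across miRNAs, scaled to the
  nominal depth, floored at 40 counts so planted presence is unambiguous
  at the 10-read pooled threshold.
* Overlap reads are realized straddling the 5' border of the first
  mature/complement segment by ≥ 2 nt on each side, staying clear of any
  second border, so their category is unambiguous under the classifier.
* `decoy_fraction=0.05` extra reads alternate between sub-17-nt and
  3-mismatch reads; genuine reads carry ≤ 1 mismatch, so the quality
  filters remove exactly the decoys (tested).

What the generator does **not** emulate: sequence content (no FASTQ, no
alignment errors or multi-mapping across paralogous families), biological
isomiR end-heterogeneity beyond uniform placement inside segments,
non-miRNA contaminant classes, and library-preparation biases. Passing
recovery tests therefore demonstrates the correctness of the
classification, quantification and comparison logic under the stated noise
model — not robustness to alignment artefacts in real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run deliberately small simulations chosen
as the package's own working scale: ~20 hairpins with ≥ 10,000 reads for
the classifier-vs-oracle check, ~2,000 reads/miRNA for mixture recovery
(multinomial error ≈ 1 pp, against the ±3 pp criterion), 60 miRNAs at
~10,000 reads/sample for trend recovery (expected label agreement ≈ 97%
for planted |log2FC| ≥ 1 under the NB noise model, against the 90%
criterion). Determinism is seed-complete: fixtures, reads and matrices are
byte-identical under a repeated seed, and the pipeline embeds a hash of
its analysis-relevant configuration (output directory excluded) in every
summary.

Degenerate inputs are defined rather than accidental: empty read files
load to empty lists with a warning; a zero-assigned-read sample is a
normalization error naming the sample; constant profiles yield missing
correlations; hairpins with no annotated mature are an error (the arms
cannot be oriented); a mature outside its parent is an error, while an
unknown parent skips the record with a warning.

## Known limitations

* The undefined complement is geometric, not thermodynamic; for hairpins
  with unusual duplex registers the star placement may be off by a few
  nucleotides (the overhang parameter is exposed).
* Multi-mapping across miRNA families is resolved to a single deterministic
  assignment (nearest window midpoint) and logged; reads mapping equally
  well to distant paralogues upstream of this package are not modelled.
* The DE model is consumed, not computed: significance ordering is only as
  good as the ingested table.
* Percent rounding is half-away-from-zero; tallies whose percentages sum
  to 99 or 101 are expected and tested for only to ±1.
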