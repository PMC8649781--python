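# Methods

This note records the models, statistics and design choices behind
`tnends`, in the order the pipeline applies them, together with the
numerical conventions and the known limitations of the synthetic
validation.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open; GFF3 is converted on read
and write (1-based inclusive), BED is written half-open. Sequences are
uppercased on ingest and any character outside {A,C,G,T} becomes N. N
never matches anything: scanning skips windows containing N, the repeat
finder treats N as a mismatch, and the background model excludes N from
its counts. This is our choice; how ambiguous bases were handled in the
original analyses is not documented.

## Candidate loci

A locus requires (i) a TnsB HMM hit with bitscore ≥ 60 bits, (ii) at
least one hit to another core model on the same contig, and (iii) two
hit-bearing ORFs forming a putative operon: codirected and separated by
less than 50 bp of noncoding sequence (overlapping ORFs count — overlap
implies ≤ 0 bp of noncoding separation). The gap is measured on genome
coordinates regardless of strand. Whether the TnsB ORF itself must be a
member of the operon pair is ambiguous; by default either reading is
accepted (`require_tnsb_in_operon` switches to the strict reading). Loci
whose hit ORFs lie within 3 kb of a contig edge are discarded as likely
truncations; exactly 3 kb is kept.

## Windows and background

Intergenic regions are maximal non-ORF spans strictly longer than 50 bp,
clipped to 125 kb on either side of the *tnsB* ORF and to the contig.
The background is an order-0 model over the pooled regions with a
pseudocount of 1 per letter — the motif stage's null model, matching the
order-0 background the discovery contract prescribes.

## Inverted-repeat search

The published search used BLASTn with word size 4 and an effectively
non-filtering E-value cutoff; the operative gate is the downstream filter
(length 15–40, ≤ 2 gap openings, ≤ 6 mismatches). We re-implement the
search: exact 4-mer seeds between one region and the reverse complement
of the other, grouped by diagonal; maximal ungapped segments (+2/−3)
reaching score 10 trigger a banded affine local alignment (open −5,
extend −2, band ±4) in a window around the segment cluster. A score
floor of 10 stands in for the permissive E-value cutoff. Two details
matter for correctness:

- *Containment culling before filtering.* Alignments overlapping a
  higher-scoring alignment in both regions are re-trimmings of the same
  physical repeat; they are culled before the length/gap/mismatch filter
  so an over-long repeat cannot re-enter as a shorter passing fragment,
  and so one repeat cannot count twice toward the "two or more shared
  repeats" rule.
- *Adaptive windows.* The alignment window is widened once when a hit is
  flush with the window edge, so long repeats are seen whole (and
  rejected on length) rather than truncated.

Alignments whose only clean stretches are shorter than the 4-bp word are
invisible to the seeded search, exactly as they are to the word-size-4
search it emulates. End pairs must share at least two distinct accepted
repeats, have one region within 20 kb of the *tnsB* start codon
(strand-aware, nearest region edge), and flank the *tnsB* ORF — the last
constraint is implicit in the original description (an element contains
its transposase) and is stated explicitly here.

## Motif discovery

For each end pair, a PWM is fit by EM under an any-number-of-repetitions
site model over both strands of both regions, seeded from enriched exact
8-mers (canonicalized with their reverse complements), with widths 15–20
tried and 4–6 non-overlapping training sites selected by posterior
probability. The PWM uses a pseudocount of 0.1 per cell. Discovered
sites are masked before the next round; up to 10 motifs are returned per
pair.

**Significance.** The discovery statistic is an E-value on the training
sites' total log-likelihood ratio with *the fit inside the null*: the
null distribution is the LLR of a PWM refit to k random background
windows, which per column is the multinomial G-statistic of k draws from
the background. Its distribution is computed exactly (the ≤ 84 count
compositions per column are enumerated and convolved across columns,
with conservative rounding), and the p-value is Bonferroni-scaled by
C(N, k) candidate site selections in log space. This matters: a naive
per-site Bonferroni certifies motifs that EM has overfit to repeated
background noise (the end-pair selection *guarantees* some shared
repeated content), whereas the fit-aware null keeps such motifs near
E ≈ 1 while genuinely planted motifs sit tens of orders of magnitude
below the gates (≤ 0.1 at discovery; ≤ 10⁻⁵ at the motif filter, read as
the motif-level statistic rather than per-site p-values). Motifs whose
training sites lie in one region only or on one strand only are removed.

## Scanning, q-values, occurrence filters

Scanning scores every non-N window on both strands by log-odds against
the background. Exact p-values come from a dynamic program over
discretized column score distributions (≥ 1000 bins; scores are floored,
making p-values conservative); the reverse strand uses the table of the
reverse-complemented PWM, which makes scanning exactly symmetric under
reverse-complementing the input. Every scanned window counts as a test;
windows with p ≤ 10⁻³ enter Benjamini–Hochberg correction with m equal
to the total test count, and occurrences with q ≤ 0.1 are reported.
Overlapping occurrences of a motif on a region are resolved by p-value,
an occurrence being dropped only when a strictly better one overlaps it
— "strictly" keeps the resolution invariant under reverse complement,
and resolving across strands (not only within a strand) prevents a
near-palindromic motif from reporting one physical site twice.

The four occurrence criteria are applied per motif: (i) consecutive
instances on a region ≤ 75 bp apart (end-to-start), (ii) total instance
length per region ≤ 120 bp (inclusive), (iii) instances on fewer than 5
regions, (iv) combined q — the product of the q-values of *all* retained
occurrences — strictly below 0.01. The survivor with the lowest combined
q wins (ties: more occurrences, then lexicographic id). Boundaries are
the outermost occurrence coordinates; on each side the end region is the
region with the most occurrences (ties: nearest *tnsB*), and occurrences
on other regions count toward criterion (iii) but never extend the span.
A winner with occurrences on only one side of *tnsB* yields no call.

Under BH at q ≤ 0.1 with ~7 true sites, roughly 0.8 false occurrences
per scan are expected *by design* of the FDR level, independent of motif
strength. This is the dominant failure mode of the cascade: a spurious
occurrence can push a motif over criterion (iii) or, rarely, the spacing
rule, in which case the locus is reported as "ends not predicted". The
cascade therefore trades a few percent of recall for boundary precision,
which is the published method's behaviour as well.

## Cross-homolog consensus

With a TnsB tree, transposases are grouped by single-linkage at
patristic distance < 1 (branch lengths as given; taxa missing from the
tree become singletons with a warning). Within a group of size ≥ 2 a
motif is kept iff it aligns with ≥ 50% of the other motifs; alignment is
the best ungapped offset over both orientations with ≥ 10 overlapping
columns, scored by mean per-column Pearson r of the probability columns,
accepted at r ≥ 0.6 (the acceptance threshold is not stated anywhere;
0.6 is our default and is configurable, as is the r ≥ 0.95 used to
collapse near-duplicate survivors). Survivors form the motif set for the
final competitive scan.

## CAST validation

Protospacers are full-length, ungapped spacer matches on either strand
with ≤ 2 mismatches (configurable), found by exhaustive sliding
comparison. The distance is measured from the nearest predicted boundary
to the nearest protospacer edge, with the side reported; a protospacer
inside the called span is an error (target sites lie outside the
element). Anchor conventions differ between CAST subtypes; nearest-edge
is our choice.

## Cargo statistics

`cog_enrichment` follows a paired resampling design: each iteration
samples 100 transposons without replacement and, for each, one uniformly
placed locus of identical length from its host genome; category counts
are summed per set (an ORF belongs to a locus when its midpoint falls
inside), the genomic set receives a pseudocount of 1 per category to
avoid empty denominators, and the per-category ratio of relative
frequencies is summarized as the mean with a 2.5–97.5 percentile
interval over 1,000 iterations (defaults; the calibration experiments in
the test-suite use 100 iterations). Sampling without replacement within
an iteration is assumed. Note the ratios are compositional: planting an
enrichment in one category necessarily depresses the others below 1.

`pathway_completeness` is the fraction of a pathway's categories carried
by each transposon; pathways represented in fewer than 10 transposons
are dropped. `consensus_lca` returns the deepest rank at which ≥ 80% of
members share the same taxon path, or "unknown".

## Synthetic data

`generate_locus` plants a left array (plus strand) and a right array
(reverse-complemented) of sites *sampled* from a random PWM of requested
information content (default 18 bp, 1.5 bits/column; the bits are set by
solving for the dominant-base probability), spaced 4–30 bp apart with
20–60 bp margins, around a cargo interior (default 15 kb) containing a
1.5-kb *tnsB* marker ORF and a codirected TnsC ORF at < 50 bp gap, with
gene-dense flanks (~6 kb) so the edge filter passes. Cargo genes abut
the end arrays, as in gene-dense transposon interiors; this also means
end regions are tightly bounded by ORFs. Decoys are direct repeats and
too-short inverted repeats split across the two flanks, exercising the
repeat filters. Everything is deterministic per seed, byte-for-byte.

What the generator does **not** emulate: sequence divergence between
site instances beyond PWM sampling, compositional heterogeneity and
repeat families of real genomes, ORF-calling errors, truncated or nested
elements, and HMM search behaviour (hit tables are fabricated). Passing
tests therefore demonstrate the correctness and calibration of the
cascade under its own model assumptions, not survey-scale recall on real
genomes — the published survey numbers require genome-database-scale
inputs and are out of scope here.

## Validation problem sizes

The test-suite validates boundary accuracy on 50 seeded loci at 1.5
bits/column with cargo drawn 5–30 kb plus 50 negative controls, recovery
of the 3 + 4 Tn7 end architecture at 1.8 bits/column (well-conserved
sites, as in Tn7 itself), exact-oracle equivalences for the p-value DP
(widths ≤ 6), BH, the repeat finder (100 random pairs vs a full
Smith–Waterman oracle) and motif comparison, boundary-value tests at
every published threshold, enrichment calibration over 100 seeded runs
on 400-transposon null fixtures (95% intervals cover ratio 1 in ≥ 93% of
category-runs), and CAST distances on 20 planted offsets. The
acceptance script reports the same quantities at 20 positive + 20
negative loci and 5 architecture replicates (modal site counts), sizes
chosen to characterize the method's behaviour in minutes on one CPU.

## Known limitations

- The discovery EM is a single-restart-per-seed-word fit; pathological
  region pairs can converge to a shifted variant of the planted motif
  (still within the ±25 bp acceptance band, since boundaries come from
  outermost occurrences).
- The combined-q statistic rewards additional occurrences (every factor
  is ≤ 1); criterion (iii) is what prevents degenerate many-occurrence
  motifs from exploiting this.
- Patristic grouping is single-linkage, so one intermediate transposase
  can chain two distant groups.
- The repeat finder inherits the blind spots of word-size-4 seeding.
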