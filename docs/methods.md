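# Methods

## Coordinate conventions

All coordinates are 0-based, half-open (BED convention). Two intervals
overlap iff they share ≥ 1 bp; strand never enters an overlap test and is
used only for gene geometry (upstream/downstream). "Center ± F bp"
standardization produces the half-open window [center − F, center + F) of
width 2F, where the center of an interval is ⌊(start + end)/2⌋ — a
deterministic tie-break for even widths. Overlap percentages are insensitive
to the 2F-vs-2F+1 width choice at the ± 1 bp level. Chromatin-mark peaks are
standardized to a fixed odd width of 149 bp as [center − 74, center + 75).

## Peak calling

Tags are first deduplicated to one per (chromosome, position, strand):
identical tags are overwhelmingly clonal PCR amplicons, not independent
cleavage evidence. Strands are then pooled — fragment-end tags mark cut
sites directly, so there is no strand-shift structure to model, and no
control library exists for this assay.

The caller slides a window of width `window` (default 400 bp, about two
nucleosomal fragments) by `step` (50 bp). A window containing k tags is
scored with the Poisson upper tail P(X ≥ k) under mean λ·window, where λ is
the maximum of the genome-wide tag rate and local rates estimated in spans
of 1/5/10 kb centered on the window. Each local rate excludes the candidate
window's own tags — (count_span − count_window)/(span − window) — so a sharp
cluster cannot inflate its own background; the max-of-rates construction
makes the test conservative in locally dense regions. Windows with
p ≤ `p_threshold` (default 10⁻⁵) and k ≥ `min_tags` (default 5) are merged
when separated by ≤ `merge_gap` (100 bp). A merged region becomes a peak
with: interval = the union of its windows, tag_count = tags in the region,
p_value = the minimum window p, and summit = the tag position maximizing
the tag count within ± window/2 (leftmost on ties). The caller is fully
deterministic given tags and parameters.

Filters then remove peaks overlapping (≥ 1 bp) any satellite-repeat mask
interval (non-specific mapping noise) and peaks on excluded chromosomes
(e.g. chrY for female cell lines); peaks inside known copy-number-altered
regions are kept but flagged "CNV".

Absolute peak counts depend strongly on sequencing depth and caller
parameters and are treated as descriptive, not as reproducible targets.

## Replicate concordance

Both peak sets are standardized to center ± 200 bp windows. The overlap
percentage is asymmetric: the fraction of A peaks whose window shares ≥ 1 bp
with any B window, and vice versa, each rounded to an integer percentage for
reporting. For intensity correlation, each A peak is paired with its
highest-intensity overlapping B peak — a deterministic resolution that is
robust when one replicate fragments a site into several peaks — and Pearson
r is computed on raw tag counts (a log10 switch is provided; no transform is
the default).

## Genomic annotation

Each peak is assigned exactly one category by testing its **center point**
against transcript-model regions in strict priority order:

1. promoter: TSS ± 2.5 kb (strand-aware TSS)
2. exon
3. intron (inside the transcript span, not exonic)
4. 3′ region: 2.5 kb downstream of the transcript end (strand-aware)
5. distal promoter: 2.5–20 kb upstream of the TSS (strand-aware)
6. intergenic: none of the above

Center-point testing gives a strict partition (category counts always sum to
the number of peaks); an any-overlap mode (`mode="interval"`) is available
behind a switch for sensitivity analyses, and the priority order is applied
identically there. The transcripts reported for a peak are those whose
region of the *winning* category contains the center. "Gene-associated"
means any category but intergenic. Gene lists are deduplicated by gene
symbol (case-insensitive, whitespace-stripped), so isoforms of one gene
product count once; transcript lists keep every isoform.

GC content is computed over the union of peak intervals (shared bases count
once); ambiguous bases are excluded from the denominator.

## Enrichment statistics

The random null places n intervals of fixed width (default 400 bp, matching
standardized peaks; width is configurable because a point-vs-interval null
is a modeling choice) uniformly over the genome — chromosome chosen
proportional to length, start uniform — and applies exactly the same
mask/chromosome filters as real peaks.

Mark association counts peaks whose center lies inside ≥ 1 standardized
(149 bp) mark window. Significance uses the one-sided binomial upper tail
P(X ≥ k | n, p₀) with p₀ the association rate of a matched random-null run
(a fixed p₀ may be supplied). The tail is evaluated as a log-sum-exp over
log pmf terms, so the result is carried in log10 space: a reported
"p = 0" is a display convention, and `log10_p` stays finite down to
thousands of orders of magnitude.

Gene and curated-list associations use the Pearson chi-square on a 2×2 table
with 1 df and no continuity correction (a Yates switch exists). For curated
lists the table is hit genes vs the remaining universe genes × curated vs
not; the bound-level conclusions are robust to the alternative construction
(hits vs the whole universe), which the tests assert. No multiple-testing
correction is applied across marks or lists, matching the analysis this
package reimplements. Genome-scale chi-square magnitudes published for the
original libraries do not recompute from their printed 2×2 counts under any
standard construction we identified and are excluded from comparisons; the
p < 0.001 curated-list bounds do recompute and are asserted.

## ΔΔCt validation arithmetic

Replicate means feed the ΔΔCt (wells are not paired):
ΔCt_apop = Ct̄(target, apoptotic) − Ct̄(negctrl, apoptotic), likewise for
genomic template, ΔΔCt = ΔCt_apop − ΔCt_gen, fold = 2^(−ΔΔCt). Double
normalization makes the fold invariant to adding a constant to all Cts
(loading) and to locus-specific copy number (the genomic-DNA term). A
fold-change interval 2^(−(ΔΔCt ± 1.96·SE)) propagates the four technical
SEs in quadrature; technical-replicate QC requires SE < 0.5 cycles, and
amplification efficiency is recorded with a 90–110% bound as metadata only —
the plain 2^(−ΔΔCt) method is used regardless.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
sequence biology. A genome of i.i.d. bases at 41% GC (the human genome-wide
average) carries non-overlapping transcripts (random strand, 8–12 kb spans
placed on a 20 kb grid, disjoint exons) and 149 bp mark peaks at promoters
plus uniform background peaks. Cleavage propensity is a piecewise-constant
landscape: baseline 1, multiplied by `promoter_enrichment_fold` inside the
promoter-window union and by `mark_enrichment_fold` inside the mark union
(multiplicative where both apply). Cut sites are drawn per-base
proportional to weight (inverse-CDF over tiles); each fragment spans
180 bp + Gaussian jitter (sd 10 bp, truncated at ≥ 50 bp — only a ~180–200 bp
band is known, not a distribution); both ends emit strand-aware tags (blunt
ligation sequences both ends; a `five_prime_only` flag restricts to cut-site
tags). Each tag is duplicated with probability `duplicate_rate` as an exact
copy, the clonal-PCR interpretation. A `background_fraction` of fragments
ignores the landscape. All draws descend from `SimConfig.seed` through named
substreams, so every artifact is byte-reproducible.

The enrichment folds are calibration choices, not measured quantities (no
published estimate exists); the default of 10 produces clearly non-random
maps while leaving background visible. The generator does **not** model
mappability, sequencing error, chromatin domains, GC-coverage bias or real
gene architecture — so passing tests demonstrate the statistical machinery
(detection, calibration, parameter recovery), not claims about any real
genome.

With promoter fold f on promoter coverage fraction c, the expected fraction
of non-background cut sites in promoters is f·c/(1 + (f − 1)·c); tests
verify recovery within 3 Monte-Carlo standard errors.

## Problem sizes and tolerances

Tests and the acceptance script run on deliberately small instances chosen
to make the measured properties statistically decisive: 0.2–2 Mb genomes,
10⁴–3·10⁴ fragments, 100–200 seeded runs for error-rate properties, planted
clusters of ≥ 20 tags at ≥ 10-fold local enrichment for recall. Binomial
3σ bounds back every stochastic assertion; exact-arithmetic checks (chi-
square closed form, binomial direct summation, interval-index brute force)
use 10⁻⁹ relative tolerance. The chi-square permutation cross-check accepts
0.01 absolute disagreement, covering both Monte-Carlo noise and the
asymptotic nature of the chi-square null.

## Known limitations

- The peak caller has no paired-end or broad-peak mode and infers no
  fragment-size model; defaults assume ~180 bp fragment tags.
- Center-point annotation undercounts multi-category overlaps by design; the
  interval mode exists for sensitivity checks but is not the default.
- The random null is uniform per base; it does not match peak GC or
  mappability, which a genome-scale study would want.
- Correlation of replicate intensities uses raw counts; heavy-tailed peak
  intensities can make r sensitive to a few strong sites.
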