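# apobreak

Analysis of apoptotic DNA breakpoints mapped by fragment-end sequencing.

During apoptosis, caspase-activated DNase (CAD/DFF) cleaves chromatin between
nucleosomes, producing the classic DNA "ladder" of ~180 bp multiples.
Sequencing the ends of the 180 bp fragments and mapping them back to the
genome turns each fragment end into a single-base, strand-aware **tag**;
regions where tags cluster far above local background are **breakpoint
peaks** — preferred apoptotic cleavage sites. `apobreak` implements the full
desk-side analysis for such data:

- **Peak calling** (`apobreak.peaks`): clonal-PCR duplicate merging, then a
  transparent sliding-window caller that tests each window's tag count k
  against a Poisson background, P(X ≥ k) with rate
  λ = max(λ_genome, λ_1kb, λ_5kb, λ_10kb) per bp (each local rate estimated
  excluding the candidate window), followed by merging of significant
  windows and satellite-mask / chromosome exclusion filters with CNV
  flagging.
- **Replicate concordance** (`apobreak.concordance`): peaks standardized to
  center ± 200 bp windows, asymmetric overlap percentages at the ≥ 1 bp
  rule, and Pearson correlation of matched peak intensities.
- **Genomic annotation** (`apobreak.annotation`): each peak's center point is
  classified against transcript models with strict priority
  promoter (TSS ± 2.5 kb) > exon > intron > 3′ region (2.5 kb downstream) >
  distal promoter (2.5–20 kb upstream) > intergenic; unique-gene counting
  collapses isoforms by gene symbol; GC content over the peak-set union.
- **Enrichment statistics** (`apobreak.enrichment`): uniform random-region
  nulls filtered like real peaks; chromatin-mark association (marks
  standardized to 149 bp, center-in-window rule); Pearson chi-square on 2×2
  tables (no continuity correction); one-sided binomial tails computed in
  log10 space so extreme significance never silently reports 0; curated
  gene-list enrichment against a gene universe.
- **qPCR validation arithmetic** (`apobreak.qpcr`): ΔΔCt double
  normalization — against uncut genomic DNA at the same locus and against a
  negative-control primer — with fold change 2^(−ΔΔCt), replicate-SE QC
  (< 0.5 cycles) and efficiency bounds (90–110%).
- **Synthetic data** (`apobreak.simulate`): a seeded generator for genome,
  gene models, chromatin-mark tracks and fragment-end tags with the
  structure the analysis assumes (180 bp fragments, promoter/open-chromatin
  cleavage enrichment, PCR duplicates, uniform background), so the entire
  pipeline is testable without any download.
- **Pipeline + CLI** (`apobreak.pipeline`, `apobreak` command): end-to-end
  orchestration from a YAML config with subcommands `simulate`, `callpeaks`,
  `compare`, `annotate`, `enrich`, `qpcr`, `run`; fully seeded, so identical
  configs reproduce byte-identical outputs.

## Worked example

```python
from apobreak import PipelineConfig, run_pipeline
from apobreak.simulate import SimConfig

summary = run_pipeline(PipelineConfig(
    outdir="demo",
    simulate=SimConfig(seed=7),   # 2 x 500 kb genome, 40 genes, 20k fragments
    random_n=5_000, random_seed=11,
))
print(summary["tags"])
print(summary["peaks"]["n"], "peaks")
print(summary["annotation"]["category_counts"])
print(round(summary["gc_content"], 3))
m = summary["mark_association"][0]
print(f"mark association {m['k']}/{m['n']} vs null {m['background_rate']:.3f}, "
      f"log10 p = {m['log10_p']:.1f}")
```

prints

```
{'raw': 43951, 'deduplicated': 38356}
34 peaks
{'promoter': 34, 'exon': 0, 'intron': 0, 'three_prime': 0, 'distal_promoter': 0, 'intergenic': 0}
0.409
mark association 8/34 vs null 0.012, log10 p = -8.2
```

Reading: of 43,951 simulated tags, 38,356 survive duplicate merging; 34
breakpoint peaks are called, all falling in promoter windows (the simulated
cleavage landscape enriches promoters 10-fold); peak GC matches the simulated
genome's 41%; 24% of peaks sit in chromatin-mark windows versus 1.2% of
random sites, a binomial tail of about 10⁻⁸.

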