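"""End-to-end orchestration: dedup -> peak calling -> filtering -> replicate
comparison -> annotation -> GC -> random null -> enrichment -> summary.

Everything is driven by a :class:`PipelineConfig` (loadable from YAML); every
random stage has an explicit seed, so re-running an identical config produces
byte-identical outputs.  A MANIFEST records input checksums, output files and
completion state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation as ann
from . import concordance, enrichment, simulate
from .intervals import (
    GenomeIndex,
    GenomicInterval,
    TagSet,
    read_intervals,
    read_tags,
    standardize_window,
    write_intervals,
    write_tags,
)
from .peaks import (
    Peak,
    PeakCallerParams,
    call_peaks,
    deduplicate_tags,
    filter_peaks,
    read_peaks,
    write_peaks,
)

__all__ = ["PipelineConfig", "run_pipeline", "export_peak_sequences"]

log = logging.getLogger("apobreak")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Either ``simulate`` is set (a SimConfig: the synthetic generator produces
    genome/genes/marks/tags in ``outdir``) or the input paths must point to
    existing files.
    """

    outdir: str = "apobreak_out"
    genome_fasta: str | None = None
    tags_bed: str | None = None
    tags_bed_b: str | None = None  # optional second replicate
    genes_table: str | None = None
    mark_beds: dict[str, str] = field(default_factory=dict)
    mask_bed: str | None = None
    flag_bed: str | None = None
    cancer_genes: str | None = None
    translocation_genes: str | None = None
    exclude_chroms: tuple[str, ...] = ("chrY",)
    peak_params: PeakCallerParams = field(default_factory=PeakCallerParams)
    flank: int = 200
    random_n: int = 10_000
    random_width: int = 400
    random_seed: int = 1
    annotation_mode: str = "point"
    simulate: simulate.SimConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "peak_params" in raw:
            raw["peak_params"] = PeakCallerParams(**raw["peak_params"])
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = simulate.SimConfig(**raw["simulate"])
        if "exclude_chroms" in raw:
            raw["exclude_chroms"] = tuple(raw["exclude_chroms"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def export_peak_sequences(
    peaks: list[Peak], genome_fasta, genome: GenomeIndex, path, flank: int = 200
) -> None:
    """FASTA of standardized peak windows; ids are the peak names.

    Windows running past a chromosome end are clamped (with a warning).
    """
    if isinstance(genome_fasta, (str, os.PathLike)):
        import pyfaidx

        genome_fasta = pyfaidx.Fasta(str(genome_fasta))
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            win = standardize_window(p.interval, flank, genome)
            if win.width < 2 * flank:
                log.warning("peak %s window clamped at a chromosome edge", p.name)
            seq = str(genome_fasta[win.chrom][win.start : win.end])
            fh.write(f">{p.name or f'peak_{i + 1}'}\n{seq}\n")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written to
    ``summary.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"inputs": {}, "outputs": [], "completed_stages": []}
    summary: dict = {"config": config.resolved()}

    def done(stage: str) -> None:
        manifest["completed_stages"].append(stage)
        _write_json(outdir / "MANIFEST.json", manifest)

    def record_output(path: Path) -> None:
        manifest["outputs"].append(str(path.name))

    try:
        # --- inputs (simulated or loaded) --------------------------------
        if config.simulate is not None:
            sim = config.simulate
            log.info("simulating inputs (seed=%d)", sim.seed)
            seqs, genome = simulate.generate_genome(sim)
            genome_fasta = outdir / "genome.fa"
            simulate.write_genome(seqs, genome_fasta)
            genes_df = simulate.generate_gene_models(sim, genome)
            genes_path = outdir / "genes.tsv"
            genes_df.to_csv(genes_path, sep="\t", index=False)
            marks = simulate.generate_mark_peaks(sim, genes_df, genome)
            marks_path = outdir / "marks.bed"
            write_intervals(marks, marks_path)
            landscape = simulate.build_cleavage_landscape(genes_df, marks, sim, genome)
            tags = simulate.simulate_tags(landscape, sim)
            tags_path = outdir / "tags.bed"
            write_tags(tags, tags_path)
            simulate.write_metadata(outdir / "simulation.meta.json", sim)
            mark_tracks = {"simulated_mark": marks}
            genes = ann.gene_models_from_table(genes_df)
            mask: list[GenomicInterval] = []
            flags: list[GenomicInterval] = []
            for p in (genome_fasta, genes_path, marks_path, tags_path):
                record_output(Path(p))
        else:
            genome_fasta = Path(config.genome_fasta)
            genome = GenomeIndex.from_fasta(genome_fasta)
            tags = read_tags(config.tags_bed, genome)
            genes = ann.read_gene_models(config.genes_table)
            mark_tracks = {
                name: read_intervals(path) for name, path in config.mark_beds.items()
            }
            mask = read_intervals(config.mask_bed) if config.mask_bed else []
            flags = read_intervals(config.flag_bed) if config.flag_bed else []
            for p in filter(
                None,
                [config.genome_fasta, config.tags_bed, config.genes_table,
                 config.mask_bed, config.flag_bed, *config.mark_beds.values()],
            ):
                manifest["inputs"][str(p)] = _sha256(p)
        done("inputs")

        # --- dedup + peak calling + filters ------------------------------
        n_raw = len(tags)
        tags = deduplicate_tags(tags)
        log.info("tags: %d raw, %d after duplicate merging", n_raw, len(tags))
        peaks = call_peaks(tags, config.peak_params)
        log.info("peaks called: %d", len(peaks))
        peaks = filter_peaks(
            peaks, mask=mask, exclude_chroms=set(config.exclude_chroms),
            flag_regions=flags,
        )
        log.info("peaks after satellite/chromosome filters: %d", len(peaks))
        write_peaks(peaks, outdir / "peaks.bed")
        record_output(outdir / "peaks.bed")
        summary["tags"] = {"raw": n_raw, "deduplicated": len(tags)}
        summary["peaks"] = {
            "n": len(peaks),
            "n_flagged_cnv": sum(1 for p in peaks if "CNV" in p.flags),
        }
        done("peaks")

        # --- optional replicate comparison --------------------------------
        if config.tags_bed_b:
            tags_b = deduplicate_tags(read_tags(config.tags_bed_b, genome))
            peaks_b = filter_peaks(
                call_peaks(tags_b, config.peak_params),
                mask=mask, exclude_chroms=set(config.exclude_chroms),
                flag_regions=flags,
            )
            write_peaks(peaks_b, outdir / "peaks_B.bed")
            record_output(outdir / "peaks_B.bed")
            rep = concordance.overlap_fraction(peaks, peaks_b, genome, config.flank)
            summary["replicate_comparison"] = rep.as_dict()
            try:
                summary["replicate_comparison"]["intensity_r"] = (
                    concordance.intensity_correlation(peaks, peaks_b, genome, config.flank)
                )
            except ValueError:
                summary["replicate_comparison"]["intensity_r"] = None
            done("replicate_comparison")

        # --- annotation + GC ----------------------------------------------
        annot = ann.GeneAnnotator(genes, mode=config.annotation_mode)
        report = ann.annotate_peakset(peaks, annot)
        _write_json(outdir / "annotation.json", {
            k: v for k, v in report.items() if k != "per_peak"
        })
        record_output(outdir / "annotation.json")
        _write_tsv(
            outdir / "annotation_per_peak.tsv",
            ["name", "chrom", "start", "end", "category", "transcripts", "genes"],
            [
                [r["name"], r["chrom"], r["start"], r["end"], r["category"],
                 ",".join(r["transcripts"]), ",".join(r["genes"])]
                for r in report["per_peak"]
            ],
        )
        record_output(outdir / "annotation_per_peak.tsv")
        summary["annotation"] = {
            "category_counts": report["category_counts"],
            "n_gene_associated": report["n_gene_associated"],
            "pct_gene_associated": report["pct_gene_associated"],
            "n_transcripts": len(report["transcripts"]),
            "n_genes": len(report["genes"]),
        }
        if peaks:
            summary["gc_content"] = round(ann.gc_content(peaks, genome_fasta), 4)
        done("annotation")

        # --- random null + mark association --------------------------------
        rand = enrichment.simulate_random_peaks(
            config.random_n, genome, mask=mask,
            exclude_chroms=set(config.exclude_chroms),
            width=config.random_width, seed=config.random_seed,
        )
        write_peaks(rand, outdir / "random_peaks.bed")
        record_output(outdir / "random_peaks.bed")
        rand_report = ann.annotate_peakset(rand, annot)
        summary["random_null"] = {
            "n": len(rand),
            "seed": config.random_seed,
            "pct_gene_associated": rand_report["pct_gene_associated"],
            "category_counts": rand_report["category_counts"],
        }
        # gene association: peaks vs random null, chi-square
        if peaks and rand:
            table = enrichment.ContingencyTable2x2(
                report["n_gene_associated"],
                report["n_peaks"] - report["n_gene_associated"],
                rand_report["n_gene_associated"],
                rand_report["n_peaks"] - rand_report["n_gene_associated"],
            )
            try:
                stat, p = enrichment.chi_square_2x2(table)
                summary["gene_association_vs_random"] = {
                    "table": dataclasses.asdict(table), "chi_square": stat, "p_value": p,
                }
            except ValueError:
                summary["gene_association_vs_random"] = None

        mark_rows = []
        for mark_name, marks_iv in mark_tracks.items():
            obs = enrichment.mark_association(peaks, marks_iv)
            bg = enrichment.mark_association(rand, marks_iv)
            p0 = bg.rate if 0.0 < bg.rate < 1.0 else max(bg.rate, 1.0 / (2 * max(len(rand), 1)))
            res = enrichment.binomial_enrichment(obs.observed_k, obs.n, p0) if obs.n else None
            mark_rows.append(
                {
                    "mark": mark_name,
                    "k": obs.observed_k,
                    "n": obs.n,
                    "rate": obs.rate,
                    "background_k": bg.observed_k,
                    "background_n": bg.n,
                    "background_rate": bg.rate,
                    "log10_p": res.log10_p if res else None,
                    "p_value": res.p_value if res else None,
                }
            )
        summary["mark_association"] = mark_rows
        _write_tsv(
            outdir / "mark_association.tsv",
            ["mark", "k", "n", "rate", "background_k", "background_n",
             "background_rate", "log10_p", "p_value"],
            [[r[c] for c in ("mark", "k", "n", "rate", "background_k",
                             "background_n", "background_rate", "log10_p", "p_value")]
             for r in mark_rows],
        )
        record_output(outdir / "mark_association.tsv")
        done("enrichment")

        # --- curated gene lists --------------------------------------------
        curated_rows = []
        universe = sorted({g.gene_symbol for g in genes})
        for list_name, path in (
            ("cancer", config.cancer_genes),
            ("translocation", config.translocation_genes),
        ):
            if not path:
                continue
            curated = enrichment.read_gene_list(path)
            res, table = enrichment.curated_list_enrichment(
                report["genes"], curated, universe
            )
            curated_rows.append({"list": list_name, **res.as_dict()})
        if curated_rows:
            summary["curated_lists"] = curated_rows
            done("curated_lists")

        # --- peak sequences for external motif tools ----------------------
        if peaks:
            export_peak_sequences(
                peaks, genome_fasta, genome, outdir / "peak_sequences.fa",
                flank=config.flank,
            )
            record_output(outdir / "peak_sequences.fa")
        done("export")

        _write_json(outdir / "summary.json", summary)
        record_output(outdir / "summary.json")
        manifest["status"] = "complete"
    except Exception:
        manifest["status"] = "failed"
        _write_json(outdir / "MANIFEST.json", manifest)
        raise
    _write_json(outdir / "MANIFEST.json", manifest)
    return summary


def _write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(o) if isinstance(o, (frozenset, set)) else list(o)
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, default=default)
        fh.write("\n")


def _write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
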