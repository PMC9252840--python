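"""End-to-end driver: VCF in, ranked regions + exports + plots out.

Wires the stages together exactly as a mapping study would run them:
ingest -> per-sample runs -> shared regions -> (autozygosity refinement)
-> score track -> exports (TSV/BED/VCF/bedGraph) -> plots.  Deterministic
for fixed inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .export import (
    region_query,
    write_bed,
    write_bedgraph,
    write_region_table,
    write_region_vcf,
)
from .genotypes import AnalysisConfig
from .ingest import SampleManifest, read_multisample_vcf, validate_manifest
from .plotting import plot_genome, plot_region_grid
from .roh import map_regions, rank_regions
from .scoring import attach_scores, score_track

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    """Paths and summary counts for one complete pipeline run."""

    region_table: Path
    bed: Path
    vcf: Path
    bedgraph: Path
    genome_plot: Path
    grid_plot: Path | None
    summary: dict

    def __post_init__(self) -> None:
        for p in (self.region_table, self.bed, self.vcf, self.bedgraph,
                  self.genome_plot):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def run_pipeline(
    vcf_path,
    manifest: SampleManifest,
    config: AnalysisConfig | None = None,
    outdir="autozygomap_out",
    top_n: int | None = None,
) -> PipelineResult:
    """Run the full mapping pipeline and write all artefacts to ``outdir``.

    ``top_n`` restricts the exported VCF to the N physically longest
    regions (None = all regions).  Zero detected regions is a valid
    outcome: exports are written empty and the run still succeeds.
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, indels, vcf_samples = read_multisample_vcf(vcf_path, config)
    manifest = validate_manifest(manifest, vcf_samples)
    patients = list(manifest.patients)
    controls = list(manifest.controls)

    regions = map_regions(matrix, patients, config)
    track = score_track(matrix, patients, controls,
                        config.control_weight, config.min_run)
    regions = attach_scores(regions, track)
    ranked = rank_regions(regions)
    if not ranked:
        log.info("no %s regions found (min_run=%d)", config.mode, config.min_run)

    region_table = outdir / "regions.tsv"
    bed = outdir / "regions.bed"
    out_vcf = outdir / "regions.vcf"
    bedgraph = outdir / "score.bedgraph"
    genome_plot = outdir / "genome_score.png"

    write_region_table(ranked, region_table)
    write_bed(ranked, bed)
    n_exported = write_region_vcf(vcf_path, ranked, out_vcf,
                                  top_n=top_n, mode=config.mode)
    write_bedgraph(track, bedgraph)
    plot_genome(track, config.score_fraction, genome_plot, config.min_run)

    grid_plot = None
    if ranked:
        top = ranked[0]
        grid = region_query(
            matrix, f"{top.chrom}:{top.start_bp}-{top.end_bp}",
            patients, controls, min_run=config.min_run)
        grid_plot = outdir / "top_region_grid.png"
        plot_region_grid(grid, grid_plot, region_box=top)

    with open(outdir / "config.json", "w") as fh:
        json.dump({
            **dataclasses.asdict(config),
            "patients": patients,
            "controls": controls,
            "top_n": top_n,
        }, fh, indent=2)

    summary = {
        "input_records": matrix.n_sites + len(indels),
        "n_snvs": matrix.n_sites,
        "n_indels": len(indels),
        "n_regions": len(ranked),
        "mode": config.mode,
        "exported_variants": n_exported,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return PipelineResult(
        region_table=region_table, bed=bed, vcf=out_vcf, bedgraph=bedgraph,
        genome_plot=genome_plot, grid_plot=grid_plot, summary=summary,
    )
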