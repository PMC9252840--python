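"""Streaming a multi-sample VCF into a genotype matrix plus an InDel table.

Only biallelic-or-multiallelic *single-base* substitutions enter the matrix;
insertions, deletions, multi-base substitutions and symbolic alleles are
kept aside verbatim as :class:`IndelRecord` so they can still be exported
with any region of interest, but never influence the mapping itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF

from .genotypes import (
    AnalysisConfig,
    GenotypeMatrix,
    VariantSite,
    classify_alleles,
)

log = logging.getLogger(__name__)

__all__ = [
    "IndelRecord",
    "SampleManifest",
    "ManifestError",
    "IngestError",
    "read_multisample_vcf",
    "validate_manifest",
]


class IngestError(ValueError):
    """Input VCF unusable: missing GT, unsorted, or no mappable SNVs."""


class ManifestError(ValueError):
    """Sample manifest inconsistent with the VCF header."""


@dataclass(frozen=True)
class IndelRecord:
    """A non-SNV record retained verbatim for later region export."""

    site: VariantSite
    gts: tuple[str, ...]  # raw per-sample GT strings, VCF sample order


@dataclass(frozen=True)
class SampleManifest:
    """Which VCF samples are affected (patients) and which are controls."""

    patients: tuple[str, ...]
    controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.patients:
            raise ManifestError("at least one patient sample is required")


def validate_manifest(manifest: SampleManifest, vcf_samples: list[str]) -> SampleManifest:
    """Check every manifest name against the VCF header; roles must not overlap."""
    known = set(vcf_samples)
    missing = [s for s in (*manifest.patients, *manifest.controls) if s not in known]
    if missing:
        raise ManifestError(
            f"unknown sample(s) {', '.join(missing)}; "
            f"VCF contains: {', '.join(vcf_samples)}")
    overlap = set(manifest.patients) & set(manifest.controls)
    if overlap:
        raise ManifestError(f"overlapping roles for sample(s): {', '.join(sorted(overlap))}")
    return manifest


def _gt_string(variant, i: int) -> str:
    g = variant.genotypes[i]
    sep = "|" if g[-1] else "/"
    return sep.join("." if a < 0 else str(a) for a in g[:-1])


def read_multisample_vcf(
    path, config: AnalysisConfig | None = None
) -> tuple[GenotypeMatrix, list[IndelRecord], list[str]]:
    """Read a (possibly bgzipped) VCF into a GenotypeMatrix and an InDel list.

    Applies the coverage rule: a call whose FORMAT/DP is below
    ``config.coverage_threshold`` becomes a no-call.  Records with an
    absent DP are taken at face value (logged once).  The file must be
    coordinate-sorted; duplicate (chrom, pos) SNV records keep the first
    occurrence with a warning.

    Returns ``(matrix, indels, vcf_sample_names)``.
    """
    config = config or AnalysisConfig()
    thr = config.coverage_threshold
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise IngestError(f"{path}: VCF has no sample columns (GT FORMAT required)")

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    indels: list[IndelRecord] = []
    last: dict[str, int] = {}
    dp_missing_logged = False
    n_records = 0
    per_contig: dict[str, int] = {}

    for variant in vcf:
        n_records += 1
        chrom, pos = variant.CHROM, int(variant.POS)
        per_contig[chrom] = per_contig.get(chrom, 0) + 1
        if chrom in last and pos < last[chrom]:
            raise IngestError(
                f"{path}: unsorted input at {chrom}:{pos} (previous {last[chrom]}); "
                "coordinate-sorted VCF required")
        last[chrom] = pos
        ref = variant.REF
        alts = tuple(variant.ALT)
        site = VariantSite(chrom, pos, ref, alts)
        if site.is_indel:
            indels.append(IndelRecord(
                site=site,
                gts=tuple(_gt_string(variant, i) for i in range(len(samples))),
            ))
            continue
        if sites and sites[-1].chrom == chrom and sites[-1].pos == pos:
            log.warning("duplicate SNV record at %s:%d — keeping first", chrom, pos)
            n_records -= 1  # keep the conservation count honest
            continue
        if variant.genotypes is None:
            raise IngestError(f"{path}: no GT FORMAT at {chrom}:{pos}")
        dps = None
        if thr > 0:
            try:
                dp_arr = variant.format("DP")
            except KeyError:
                dp_arr = None
            if dp_arr is None and not dp_missing_logged:
                log.warning("coverage_threshold=%d but no FORMAT/DP field; "
                            "calls treated as above threshold", thr)
                dp_missing_logged = True
            if dp_arr is not None:
                dps = dp_arr.reshape(-1)
        col = np.empty(len(samples), dtype=np.uint8)
        for i in range(len(samples)):
            g = variant.genotypes[i]
            alleles = [None if a < 0 else int(a) for a in g[:-1]]
            dp = None
            if dps is not None:
                d = int(dps[i])
                dp = None if d < 0 else d  # cyvcf2 encodes missing DP as negative
            col[i] = classify_alleles(
                alleles, ref, alts, dp, thr, where=f"{chrom}:{pos}")
        sites.append(site)
        columns.append(col)

    vcf.close()
    if n_records == 0:
        raise IngestError(f"{path}: VCF contains no records")
    if not sites:
        raise IngestError(f"{path}: no mappable sites (every record is an InDel)")
    states = np.stack(columns, axis=1)
    for contig, n in per_contig.items():
        log.info("contig %s: %d records", contig, n)
    matrix = GenotypeMatrix(samples, sites, states)
    return matrix, indels, samples
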