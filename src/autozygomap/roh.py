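"""Run-of-homozygosity detection and shared/autozygous region calling.

The pipeline is: per-sample maximal runs of non-heterozygous markers ->
per-marker intersection across the affected samples (shared homozygous
regions) -> optional refinement into autozygous segments by splitting
wherever patients are homozygous for different alleles.

All interval logic works on marker (column) indices of a
:class:`~autozygomap.genotypes.GenotypeMatrix`; base-pair coordinates are
the positions of the first and last supporting markers.  Regions are ranked
by physical length (bp), not marker count, so sparsely covered stretches do
not outrank genuinely long ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genotypes import (
    AnalysisConfig,
    ConfigError,
    GenotypeMatrix,
    HET_CODE,
    NOCALL_CODE,
)

__all__ = [
    "Run",
    "SharedRegion",
    "find_sample_runs",
    "shared_regions",
    "autozygosity_refine",
    "rank_regions",
    "map_regions",
]


@dataclass(frozen=True)
class Run:
    """A maximal stretch of run-compatible markers in one sample.

    ``n_called`` counts actual homozygous calls; it may be 0 for a run made
    entirely of no-calls, which is how homozygous deletions show up.
    """

    sample: str
    chrom: str
    start_idx: int
    end_idx: int  # inclusive
    start_bp: int
    end_bp: int
    n_markers: int
    n_called: int


@dataclass(frozen=True)
class SharedRegion:
    """A homozygous or autozygous segment shared by the selected patients."""

    chrom: str
    start_idx: int
    end_idx: int  # inclusive
    start_bp: int
    end_bp: int
    n_markers: int
    mode: str  # "homozygous" | "autozygous"
    supporting_patients: tuple[str, ...]
    score_max: float = 0.0  # max relative score inside, filled by scoring

    @property
    def bp_length(self) -> int:
        return self.end_bp - self.start_bp + 1


def _true_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] (inclusive) intervals of True in a 1-D mask."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def find_sample_runs(matrix: GenotypeMatrix, sample: str, min_run: int) -> list[Run]:
    """All maximal runs of >= ``min_run`` non-HET markers for one sample.

    Runs never cross chromosome boundaries and are flanked by a HET marker
    or a chromosome end on both sides.
    """
    codes = matrix.row_codes(sample)
    compat = codes != HET_CODE
    runs: list[Run] = []
    for chrom, a, b in matrix.chrom_blocks:
        for s, e in _true_intervals(compat[a:b]):
            n = e - s + 1
            if n < min_run:
                continue
            lo, hi = a + s, a + e
            n_called = int(np.count_nonzero(codes[lo:hi + 1] != NOCALL_CODE))
            runs.append(Run(
                sample=sample, chrom=chrom, start_idx=lo, end_idx=hi,
                start_bp=int(matrix.positions[lo]), end_bp=int(matrix.positions[hi]),
                n_markers=n, n_called=n_called,
            ))
    return runs


def _in_run_mask(matrix: GenotypeMatrix, sample: str, min_run: int) -> np.ndarray:
    """Boolean per-marker mask: marker lies inside one of the sample's runs."""
    mask = np.zeros(matrix.n_sites, dtype=bool)
    for r in find_sample_runs(matrix, sample, min_run):
        mask[r.start_idx:r.end_idx + 1] = True
    return mask


def shared_regions(
    matrix: GenotypeMatrix,
    patients: Sequence[str],
    min_patients: int | None = None,
    min_run: int = 15,
) -> list[SharedRegion]:
    """Maximal marker intervals where >= ``min_patients`` patients are in a run.

    With a single patient this reduces exactly to that patient's runs.
    ``supporting_patients`` lists the patients whose runs cover the whole
    region.  Returned in genomic order with ``mode="homozygous"``.
    """
    patients = list(patients)
    if not patients:
        raise ConfigError("patients list is empty")
    k = len(patients) if min_patients is None else min_patients
    if not 1 <= k <= len(patients):
        raise ConfigError(f"min_patients={k} out of range for {len(patients)} patients")
    masks = np.stack([_in_run_mask(matrix, p, min_run) for p in patients])
    support = masks.sum(axis=0)
    regions: list[SharedRegion] = []
    for chrom, a, b in matrix.chrom_blocks:
        for s, e in _true_intervals(support[a:b] >= k):
            if e - s + 1 < min_run:
                continue
            lo, hi = a + s, a + e
            covering = tuple(
                p for i, p in enumerate(patients) if masks[i, lo:hi + 1].all())
            regions.append(SharedRegion(
                chrom=chrom, start_idx=lo, end_idx=hi,
                start_bp=int(matrix.positions[lo]), end_bp=int(matrix.positions[hi]),
                n_markers=hi - lo + 1, mode="homozygous",
                supporting_patients=covering,
            ))
    return regions


def _concordance_mask(
    matrix: GenotypeMatrix,
    region: SharedRegion,
    patients: Sequence[str],
    min_run: int,
) -> np.ndarray:
    """Per-marker allele concordance across the patients in-run at each site.

    A site is concordant when all homozygous calls among the in-run patients
    carry the same base; no-calls are wildcards.  HET calls can only occur
    for patients not inside a run at that site and are ignored.
    """
    lo, hi = region.start_idx, region.end_idx
    codes = matrix.codes_array(patients)[:, lo:hi + 1]
    inrun = np.stack(
        [_in_run_mask(matrix, p, min_run)[lo:hi + 1] for p in patients])
    hom = (codes < 4) & inrun
    lo_base = np.min(np.where(hom, codes, np.uint8(4)), axis=0)
    hi_base = np.max(np.where(hom, codes, np.uint8(0)), axis=0)
    any_hom = hom.any(axis=0)
    return ~any_hom | (lo_base == hi_base)


def autozygosity_refine(
    region: SharedRegion,
    matrix: GenotypeMatrix,
    patients: Sequence[str],
    min_run: int = 15,
) -> list[SharedRegion]:
    """Split a shared homozygous region into autozygous sub-segments.

    The region is cut at every site where patients are homozygous for
    different alleles (the discordant marker itself belongs to neither
    side); sub-segments shorter than ``min_run`` markers are dropped.  A
    fully concordant region is returned whole with ``mode="autozygous"``.
    """
    if region.mode != "homozygous":
        raise ValueError("autozygosity_refine expects a homozygous-mode region")
    concord = _concordance_mask(matrix, region, list(patients), min_run)
    out: list[SharedRegion] = []
    for s, e in _true_intervals(concord):
        if e - s + 1 < min_run:
            continue
        lo, hi = region.start_idx + s, region.start_idx + e
        out.append(replace(
            region,
            start_idx=lo, end_idx=hi,
            start_bp=int(matrix.positions[lo]), end_bp=int(matrix.positions[hi]),
            n_markers=hi - lo + 1, mode="autozygous",
        ))
    return out


def rank_regions(regions: Sequence[SharedRegion]) -> list[SharedRegion]:
    """Order regions by physical length (bp) descending.

    Ties break by marker count descending, then genomic position ascending.
    """
    return sorted(
        regions,
        key=lambda r: (-r.bp_length, -r.n_markers, r.chrom, r.start_bp),
    )


def map_regions(
    matrix: GenotypeMatrix,
    patients: Sequence[str],
    config: AnalysisConfig,
) -> list[SharedRegion]:
    """Convenience driver: shared regions, refined if mode is autozygous."""
    k = config.resolve_min_patients(len(patients))
    homo = shared_regions(matrix, patients, k, config.min_run)
    if config.mode == "homozygous":
        return homo
    out: list[SharedRegion] = []
    for region in homo:
        out.extend(autozygosity_refine(region, matrix, patients, config.min_run))
    return out
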