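"""Region export (BED, region-restricted VCF, bedGraph) and genotype grids.

BED output is 0-based half-open; everything else in the package is 1-based
inclusive, matching VCF.  The region-restricted VCF is produced by
filtering the *original* file at the text level so the header and records
survive verbatim — this keeps downstream variant-effect tools happy — with
a single provenance line added.  InDels and sites where patients are
homozygous for different alleles are deliberately kept: the export is a
positional filter, not a genotype filter, because the disease variant
itself may be any of them.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .genotypes import GenotypeMatrix, GenotypeState
from .roh import SharedRegion, rank_regions
from .scoring import ScoreTrack, run_length_track

__all__ = [
    "GridCell",
    "RegionGrid",
    "write_bed",
    "write_region_vcf",
    "write_bedgraph",
    "write_region_table",
    "region_query",
    "parse_region",
    "QueryError",
]


class QueryError(ValueError):
    """Malformed or unresolvable region/gene query."""


def write_bed(regions: Sequence[SharedRegion], path) -> None:
    """One BED line per region: chrom, start-1, end, name=mode:rank, score.

    The score column is ``round(1000 * score_max)`` (UCSC convention);
    lines are sorted by chromosome then start.
    """
    rows = sorted(regions, key=lambda r: (r.chrom, r.start_bp))
    ranked = {id(r): i + 1 for i, r in enumerate(rank_regions(regions))}
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                     f"{r.mode}:{ranked[id(r)]}\t{round(1000 * r.score_max)}\n")


def read_bed_regions(path) -> list[tuple[str, int, int]]:
    """Parse a BED back to 1-based inclusive (chrom, start_bp, end_bp)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


def _open_text(path):
    p = str(path)
    if p.endswith(".gz") or p.endswith(".bgz"):
        return gzip.open(p, "rt")
    return open(p)


def write_region_vcf(
    input_vcf,
    regions: Sequence[SharedRegion],
    path,
    top_n: int | None = None,
    mode: str | None = None,
) -> int:
    """Copy the input VCF records whose POS falls inside a selected region.

    ``top_n`` restricts to the N physically longest regions (rank order);
    the header is preserved verbatim plus one provenance line.  Selection
    is by POS only (1-based inclusive region bounds) so InDels and
    discordant-homozygous sites inside a region are all exported.  Returns
    the number of records written.
    """
    selected = rank_regions(regions)[:top_n] if top_n else list(regions)
    trees: dict[str, IntervalTree] = {}
    for r in selected:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start_bp, r.end_bp + 1)
    n_out = 0
    mode_label = mode or (selected[0].mode if selected else "none")
    with _open_text(input_vcf) as src, open(path, "w") as out:
        for line in src:
            if line.startswith("##"):
                out.write(line)
                continue
            if line.startswith("#CHROM"):
                out.write(f"##autozygomap_regions={len(selected)},mode={mode_label}\n")
                out.write(line)
                continue
            chrom, pos_s = line.split("\t", 2)[:2]
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps_point(int(pos_s)):
                out.write(line)
                n_out += 1
    return n_out


def write_bedgraph(track: ScoreTrack, path, relative: bool = True) -> None:
    """Score track as bedGraph; adjacent equal-score markers are merged.

    Each marker contributes the 0-based half-open interval [pos-1, pos).
    Non-adjacent markers are not bridged, so the track stays honest about
    coverage gaps.
    """
    values = track.relative if relative else track.raw
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="autozygomap_{"rel" if relative else "raw"}"\n')
        for chrom, a, b in track.chrom_blocks:
            run_start = None
            prev_pos = None
            prev_val = None
            for j in range(a, b):
                pos, val = int(track.positions[j]), float(values[j])
                if run_start is not None and (val != prev_val or pos != prev_pos + 1):
                    fh.write(f"{chrom}\t{run_start - 1}\t{prev_pos}\t{prev_val:g}\n")
                    run_start = None
                if run_start is None:
                    run_start = pos
                prev_pos, prev_val = pos, val
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start - 1}\t{prev_pos}\t{prev_val:g}\n")


def write_region_table(regions: Sequence[SharedRegion], path) -> None:
    """TSV region table in rank order (longest bp first)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart_bp\tend_bp\tbp_length\tn_markers\tmode\t"
                 "patients\tscore_max\n")
        for r in rank_regions(regions):
            fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.bp_length}\t"
                     f"{r.n_markers}\t{r.mode}\t"
                     f"{','.join(r.supporting_patients)}\t{r.score_max:.4f}\n")


# ---------------------------------------------------------------------------
# genotype grid queries

@dataclass(frozen=True)
class GridCell:
    """One sample x marker cell of a genotype display grid."""

    state: GenotypeState
    run_length: int  # enclosing-run length in the sample, 0 outside runs
    discordant: bool  # site breaks allele concordance across the patients


@dataclass(frozen=True)
class RegionGrid:
    """Genotype grid over a marker window: rows = samples, cols = markers."""

    chrom: str
    positions: np.ndarray  # 1-based marker positions
    samples: tuple[str, ...]  # patients first, then controls
    n_patients: int
    cells: list  # list of rows, each a list of GridCell

    @property
    def n_markers(self) -> int:
        return len(self.positions)


_REGION_RE = re.compile(r"^([\w.]+):([\d,]+)-([\d,]+)$")


def parse_region(query: str) -> tuple[str, int, int]:
    """Parse 'chrom:start-end' (commas in numbers allowed) to a 1-based span."""
    m = _REGION_RE.match(query.strip())
    if not m:
        raise QueryError(
            f"malformed region {query!r}; expected chrom:start-end")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if start < 1 or end < start:
        raise QueryError(f"invalid span {start}-{end}")
    return chrom, start, end


def _lookup_gene(symbol: str, annotation_bed) -> tuple[str, int, int]:
    with open(annotation_bed) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 4 and parts[3] == symbol:
                return parts[0], int(parts[1]) + 1, int(parts[2])
    raise QueryError(f"gene symbol {symbol!r} not found in annotation BED")


def region_query(
    matrix: GenotypeMatrix,
    query: str,
    patients: Sequence[str],
    controls: Sequence[str] = (),
    annotation_bed=None,
    min_run: int = 15,
) -> RegionGrid:
    """Genotype grid for every SNV marker inside a query span.

    ``query`` is either ``chrom:start-end`` or a gene symbol resolved
    through a user-supplied annotation BED (column 4 = symbol).  The grid
    covers the span regardless of any run of homozygosity; a span with no
    markers yields an empty grid.
    """
    if _REGION_RE.match(query.strip()):
        chrom, start, end = parse_region(query)
    else:
        if annotation_bed is None:
            raise QueryError(
                f"{query!r} looks like a gene symbol; gene queries require "
                "an annotation BED (chrom, start, end, symbol)")
        chrom, start, end = _lookup_gene(query, annotation_bed)

    samples = (*patients, *controls)
    if chrom not in matrix.chroms:
        idx = np.array([], dtype=np.int64)
    else:
        sl = matrix.chrom_slice(chrom)
        pos = matrix.positions[sl]
        inside = np.flatnonzero((pos >= start) & (pos <= end))
        idx = inside + sl.start

    # per-site discordance across patients (wildcard no-calls, HET ignored)
    pat_codes = matrix.codes_array(patients)[:, idx] if idx.size else \
        np.empty((len(patients), 0), dtype=np.uint8)
    hom = pat_codes < 4
    lo = np.min(np.where(hom, pat_codes, np.uint8(4)), axis=0) if idx.size else idx
    hi = np.max(np.where(hom, pat_codes, np.uint8(0)), axis=0) if idx.size else idx
    discordant_col = (hom.any(axis=0) & (lo != hi)) if idx.size else \
        np.array([], dtype=bool)

    cells = []
    for s in samples:
        codes = matrix.row_codes(s)[idx] if idx.size else np.array([], dtype=np.uint8)
        lengths = run_length_track(matrix, s, min_run)[idx] if idx.size else codes
        row = [
            GridCell(
                state=GenotypeState(int(c)),
                run_length=int(l),
                discordant=bool(d) and int(c) < 4,
            )
            for c, l, d in zip(codes, lengths, discordant_col)
        ]
        cells.append(row)
    return RegionGrid(
        chrom=chrom,
        positions=matrix.positions[idx] if idx.size else np.array([], dtype=np.int64),
        samples=samples,
        n_patients=len(patients),
        cells=cells,
    )
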