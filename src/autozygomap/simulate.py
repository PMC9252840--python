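"""Synthetic consanguineous-pedigree VCFs with planted IBD segments.

The generator emulates the data a recessive-disease mapping study sees: a
multi-sample VCF of biallelic SNVs whose genotypes are Hardy-Weinberg draws
from per-site allele frequencies, with planted features layered on top —

* ``autozygous_shared``   all carrier samples homozygous for one shared,
  randomly drawn haplotype (true IBD, e.g. affected sibs in a
  consanguineous family);
* ``homozygous_discordant``  each carrier homozygous for its *own*
  independently drawn haplotype (homozygosity without autozygosity, e.g.
  patients from unrelated families);
* ``hemizygous``          haploid genotype calls (heterozygous deletion /
  loss of heterozygosity);
* ``homozygous_deletion`` missing genotypes at zero coverage.

InDels, no-calls, low-coverage calls and genotype errors are sprinkled at
configurable rates.  Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["PlantedSegment", "SimSpec", "simulate_vcf", "truth_overlap",
           "quartet_spec", "write_truth_tsv"]

SEGMENT_KINDS = (
    "autozygous_shared", "homozygous_discordant", "hemizygous", "homozygous_deletion",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSegment:
    """A ground-truth feature planted into the simulated genotypes."""

    chrom: str
    start_bp: int
    end_bp: int  # inclusive
    kind: str
    carriers: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.end_bp < self.start_bp:
            raise ValueError("segment end before start")


@dataclass
class SimSpec:
    """Study design for one simulated dataset.

    Site positions are uniform along each chromosome (no exome clustering);
    allele frequencies are Uniform(0.05, 0.5) by default so markers are
    polymorphic enough to be informative for ROH detection.  ``low_dp_rate``
    calls keep their genotype but get DP = ``low_dp_value`` so a coverage
    threshold turns them into no-calls; ``genotype_error_rate`` flips
    HOM <-> HET independently per diploid call.
    """

    patients: tuple[str, ...] = ("Patient1", "Patient2")
    controls: tuple[str, ...] = ("Father", "Mother")
    chrom_sites: dict = field(default_factory=lambda: {"chr1": 10000, "chr2": 10000})
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 100_000_000,
                                                         "chr2": 100_000_000})
    af_range: tuple[float, float] = (0.05, 0.5)
    segments: tuple[PlantedSegment, ...] = ()
    indel_rate: float = 0.0
    nocall_rate: float = 0.0
    low_dp_rate: float = 0.0
    genotype_error_rate: float = 0.0
    mean_dp: int = 30
    low_dp_value: int = 3
    seed: int = 0

    @property
    def samples(self) -> tuple[str, ...]:
        return (*self.patients, *self.controls)

    def validate(self) -> None:
        for rate in (self.indel_rate, self.nocall_rate, self.low_dp_rate,
                     self.genotype_error_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if set(self.chrom_sites) != set(self.chrom_lengths):
            raise ValueError("chrom_sites and chrom_lengths disagree on chromosomes")
        for seg in self.segments:
            if seg.chrom not in self.chrom_lengths:
                raise ValueError(f"segment chromosome {seg.chrom} not in spec")
            if seg.end_bp > self.chrom_lengths[seg.chrom]:
                raise ValueError(f"segment {seg} outside chromosome bounds")
            for c in seg.carriers:
                if c not in self.samples:
                    raise ValueError(f"segment carrier {c} not a sample")
        # planted segments must not overlap for any shared carrier
        by_carrier: dict[str, list[PlantedSegment]] = {}
        for seg in self.segments:
            for c in seg.carriers:
                for other in by_carrier.setdefault(c, []):
                    if other.chrom == seg.chrom and not (
                            seg.end_bp < other.start_bp or seg.start_bp > other.end_bp):
                        raise ValueError(f"overlapping planted segments for carrier {c}")
                by_carrier[c].append(seg)


def _site_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions, uniform along the chromosome."""
    if n > length:
        raise ValueError("more sites than base pairs")
    pos = rng.choice(length, size=n, replace=False) + 1
    pos.sort()
    return pos.astype(np.int64)


def quartet_spec(
    seed: int,
    n_sites: int = 20_000,
    segment_markers: int = 500,
    segment_kind: str = "autozygous_shared",
    nocall_rate: float = 0.02,
    indel_rate: float = 0.0,
    chrom_length: int = 100_000_000,
) -> SimSpec:
    """A consanguineous quartet (2 affected sibs, 2 parents as controls)
    with one planted segment of ``segment_markers`` consecutive SNVs
    carried by the two patients, on a single chromosome.

    The segment's bp bounds are anchored to actual simulated marker
    positions so the planted truth spans exactly the requested number of
    markers.
    """
    base = SimSpec(
        chrom_sites={"chr1": n_sites},
        chrom_lengths={"chr1": chrom_length},
        nocall_rate=nocall_rate,
        indel_rate=indel_rate,
        seed=seed,
    )
    rng = np.random.default_rng([seed, 0])  # same stream simulate_vcf uses for chr1
    pos = _site_positions(rng, chrom_length, n_sites)
    start_i = int(np.random.default_rng([seed, 999]).integers(
        n_sites // 10, n_sites - segment_markers - n_sites // 10))
    seg = PlantedSegment(
        chrom="chr1",
        start_bp=int(pos[start_i]),
        end_bp=int(pos[start_i + segment_markers - 1]),
        kind=segment_kind,
        carriers=base.patients,
    )
    return replace(base, segments=(seg,))


def _hw_draw(rng: np.random.Generator, af: np.ndarray, shape) -> np.ndarray:
    """Hardy-Weinberg alt-allele counts (0/1/2) for given alt frequencies."""
    u = rng.random(shape)
    hom_alt = u < af ** 2
    het = (~hom_alt) & (u < af ** 2 + 2 * af * (1 - af))
    return np.where(hom_alt, 2, np.where(het, 1, 0)).astype(np.int8)


def simulate_vcf(spec: SimSpec, path) -> list[PlantedSegment]:
    """Write the simulated multi-sample VCF (GT:DP) and return the truth table.

    Deterministic for a fixed spec (including its seed): identical specs
    produce byte-identical files.
    """
    spec.validate()
    samples = spec.samples
    ns = len(samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    lines: list[str] = ["##fileformat=VCFv4.2",
                        f"##source=autozygomap-simulate(seed={spec.seed})"]
    for chrom in spec.chrom_sites:
        lines.append(f"##contig=<ID={chrom},length={spec.chrom_lengths[chrom]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))

    for ci, (chrom, n_sites) in enumerate(spec.chrom_sites.items()):
        rng = np.random.default_rng([spec.seed, ci])
        length = spec.chrom_lengths[chrom]
        pos = _site_positions(rng, length, n_sites)
        af = rng.uniform(*spec.af_range, size=n_sites)
        ref_i = rng.integers(0, 4, size=n_sites)
        alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
        refs = _BASES[ref_i]
        alts = _BASES[alt_i]
        is_indel = rng.random(n_sites) < spec.indel_rate

        # background: independent Hardy-Weinberg draws per sample
        gt = _hw_draw(rng, af[None, :], (ns, n_sites))  # alt-allele count 0/1/2
        haploid = np.zeros((ns, n_sites), dtype=bool)
        deleted = np.zeros((ns, n_sites), dtype=bool)

        for seg in spec.segments:
            if seg.chrom != chrom:
                continue
            in_seg = (pos >= seg.start_bp) & (pos <= seg.end_bp)
            idx = np.flatnonzero(in_seg)
            rows = [sample_idx[c] for c in seg.carriers]
            if seg.kind == "autozygous_shared":
                shared = (rng.random(idx.size) < af[idx]).astype(np.int8) * 2
                for r in rows:
                    gt[r, idx] = shared
            elif seg.kind == "homozygous_discordant":
                for r in rows:
                    own = (rng.random(idx.size) < af[idx]).astype(np.int8) * 2
                    gt[r, idx] = own
            elif seg.kind == "hemizygous":
                for r in rows:
                    gt[r, idx] = (rng.random(idx.size) < af[idx]).astype(np.int8) * 2
                    haploid[r, idx] = True
            elif seg.kind == "homozygous_deletion":
                for r in rows:
                    deleted[r, idx] = True

        # noise layers
        errors = rng.random((ns, n_sites)) < spec.genotype_error_rate
        nocall = rng.random((ns, n_sites)) < spec.nocall_rate
        low_dp = rng.random((ns, n_sites)) < spec.low_dp_rate
        dp = rng.poisson(spec.mean_dp, size=(ns, n_sites)).astype(np.int64)
        np.maximum(dp, 1, out=dp)
        dp[low_dp] = spec.low_dp_value
        dp[deleted] = 0

        diploid = ~(haploid | deleted)
        flip = errors & diploid
        # HOM -> HET; HET -> random HOM
        was_het = gt == 1
        gt[flip & ~was_het] = 1
        hom_repl = (rng.random((ns, n_sites)) < 0.5).astype(np.int8) * 2
        hethom = flip & was_het
        gt[hethom] = hom_repl[hethom]

        gt_strings = np.empty((ns, n_sites), dtype=object)
        for code, s in ((0, "0/0"), (1, "0/1"), (2, "1/1")):
            gt_strings[gt == code] = s
        gt_strings[haploid & (gt == 0)] = "0"
        gt_strings[haploid & (gt == 2)] = "1"
        gt_strings[nocall & ~haploid] = "./."
        gt_strings[nocall & haploid] = "."
        gt_strings[deleted] = "./."

        for j in range(n_sites):
            if is_indel[j]:
                ref_field = refs[j] + str(_BASES[rng.integers(0, 4)])
                alt_field = ref_field[0] if rng.random() < 0.5 else ref_field + "A"
            else:
                ref_field, alt_field = refs[j], alts[j]
            cells = "\t".join(
                f"{gt_strings[i, j]}:{dp[i, j]}" for i in range(ns))
            lines.append(f"{chrom}\t{pos[j]}\t.\t{ref_field}\t{alt_field}"
                         f"\t.\tPASS\t.\tGT:DP\t{cells}")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return list(spec.segments)


def write_truth_tsv(segments: Sequence[PlantedSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart_bp\tend_bp\tkind\tcarriers\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp}\t{s.end_bp}\t{s.kind}\t"
                     f"{','.join(s.carriers)}\n")


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Intersection over union of two 1-based inclusive bp intervals."""
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    union = max(a_end, b_end) - min(a_start, b_start) + 1
    return inter / union


def truth_overlap(detected, truth: Sequence[PlantedSegment]) -> list[float]:
    """Best reciprocal overlap of each truth segment with any detected region.

    ``detected`` is any sequence of objects with chrom/start_bp/end_bp
    attributes (e.g. :class:`~autozygomap.roh.SharedRegion`).
    """
    out = []
    for seg in truth:
        best = 0.0
        for r in detected:
            if r.chrom != seg.chrom:
                continue
            best = max(best, reciprocal_overlap(
                r.start_bp, r.end_bp, seg.start_bp, seg.end_bp))
        out.append(best)
    return out
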