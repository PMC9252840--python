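"""Genotype states, bit-coded storage, and allele-compatibility rules.

A SNV genotype is collapsed to one of six states: homozygous for one of the
four bases, heterozygous, or no-call.  Keeping the *real* homozygous allele
(rather than a ref/non-ref dichotomy) is what makes autozygosity detection
possible: two patients are only identical by descent at a site if their
homozygous genotypes carry the same base.

No-calls are deliberately treated as compatible with homozygosity (wildcard
states).  Genuinely missing stretches — homozygous deletions — then surface
as long runs of "homozygosity", which is diagnostically useful, and isolated
dropouts do not break up real runs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenotypeState",
    "VariantSite",
    "GenotypeMatrix",
    "AnalysisConfig",
    "MalformedRecordError",
    "ConfigError",
    "classify_genotype",
    "classify_alleles",
    "is_run_compatible",
    "is_allele_concordant",
]

_BASES = "ACGT"


class MalformedRecordError(ValueError):
    """A VCF record whose genotype refers to a nonexistent allele, etc."""


class ConfigError(ValueError):
    """An analysis parameter outside its valid range."""


class GenotypeState(enum.IntEnum):
    """One sample's collapsed call at one SNV site (six states, 3 bits)."""

    HOM_A = 0
    HOM_C = 1
    HOM_G = 2
    HOM_T = 3
    HET = 4
    NOCALL = 5

    @classmethod
    def hom(cls, base: str) -> "GenotypeState":
        try:
            return cls(_BASES.index(base.upper()))
        except ValueError:
            raise MalformedRecordError(f"not a single-base allele: {base!r}") from None

    @property
    def is_hom(self) -> bool:
        return self.value < 4

    @property
    def base(self) -> str:
        """Homozygous base, e.g. 'A' for HOM_A. Raises for HET/NOCALL."""
        if not self.is_hom:
            raise ValueError(f"{self.name} has no base")
        return _BASES[self.value]

    def encode(self) -> int:
        return int(self.value)

    @classmethod
    def decode(cls, code: int) -> "GenotypeState":
        return cls(code)


#: integer codes, convenient for numpy work on raw state arrays
HET_CODE = int(GenotypeState.HET)
NOCALL_CODE = int(GenotypeState.NOCALL)


def is_run_compatible(state: GenotypeState | int) -> bool:
    """True if the state can sit inside a run of homozygosity.

    Homozygous states qualify by definition; no-calls are treated as
    homozygous wildcards so that coverage gaps and homozygous deletions do
    not interrupt runs.  Only heterozygous calls terminate a run.
    """
    return int(state) != HET_CODE


def is_allele_concordant(states: Iterable[GenotypeState | int]) -> bool:
    """True if all homozygous states among ``states`` share one base.

    No-calls act as wildcards (compatible with any base); a set with no
    homozygous call at all is vacuously concordant.  Heterozygous input
    violates the precondition — callers must filter to run-compatible
    states first.
    """
    seen: int | None = None
    for s in states:
        code = int(s)
        if code == HET_CODE:
            raise ValueError("heterozygous state passed to is_allele_concordant")
        if code == NOCALL_CODE:
            continue
        if seen is None:
            seen = code
        elif code != seen:
            return False
    return True


def classify_alleles(
    alleles: Sequence[int | None],
    ref: str,
    alts: Sequence[str],
    dp: int | None = None,
    coverage_threshold: int = 0,
    where: str = "?",
) -> GenotypeState:
    """Collapse a genotype given as allele indices (``None`` = missing).

    Rules: any missing allele, or DP below the coverage threshold, gives
    NOCALL; equal indices (or a haploid call) give the homozygous state of
    that allele's base; unequal indices give HET.
    """
    if dp is not None and dp < coverage_threshold:
        return GenotypeState.NOCALL
    if len(alleles) == 0 or any(a is None for a in alleles):
        return GenotypeState.NOCALL
    first = alleles[0]
    if any(a != first for a in alleles[1:]):
        return GenotypeState.HET
    allele_strings = [ref, *alts]
    if not 0 <= first < len(allele_strings):
        raise MalformedRecordError(
            f"allele index {first} out of range for {where} (ref={ref}, alts={list(alts)})"
        )
    return GenotypeState.hom(allele_strings[first])


def classify_genotype(
    gt_field: str,
    ref: str,
    alts: Sequence[str],
    dp: int | None = None,
    coverage_threshold: int = 0,
    where: str = "?",
) -> GenotypeState:
    """Collapse a raw VCF GT string into a :class:`GenotypeState`.

    Accepts diploid ``a/b`` or ``a|b`` (phase is ignored), haploid ``a``
    (hemizygous calls count as homozygous), and missing ``.``/``./.``.
    Half-calls such as ``./1`` are NOCALL — one observed allele cannot
    establish homozygosity.  A DP below ``coverage_threshold`` forces
    NOCALL regardless of the GT value.
    """
    raw = gt_field.replace("|", "/").split("/")
    alleles: list[int | None] = []
    for tok in raw:
        if tok == "." or tok == "":
            alleles.append(None)
        else:
            try:
                alleles.append(int(tok))
            except ValueError:
                raise MalformedRecordError(f"unparseable GT {gt_field!r} at {where}") from None
    return classify_alleles(alleles, ref, alts, dp, coverage_threshold, where)


@dataclass(frozen=True)
class VariantSite:
    """One variant locus: chromosome, 1-based position, and alleles."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MalformedRecordError(f"position must be >= 1, got {self.pos}")

    @property
    def is_indel(self) -> bool:
        """True unless ref and every alt are plain single bases (a SNV)."""
        def _single_base(a: str) -> bool:
            return len(a) == 1 and a.upper() in _BASES
        return not (_single_base(self.ref) and len(self.alts) > 0
                    and all(_single_base(a) for a in self.alts))


@dataclass
class AnalysisConfig:
    """Parameters steering the mapping run.

    min_run
        Minimum number of consecutive run-compatible markers for a stretch
        to count as a run of homozygosity (default 15); also applied to
        shared and autozygous segments.
    coverage_threshold
        FORMAT/DP below this forces a no-call; 0 disables the filter.
    score_fraction
        Relative-score cutoff for candidate highlighting (default 0.6,
        strict inequality).
    control_weight
        Weight of the control run-length sum subtracted from the patient
        score (default 1.0).
    min_patients
        Markers need at least this many patients inside a run to belong to
        a shared region; ``None`` means all patients.
    mode
        ``"homozygous"`` (any allele) or ``"autozygous"`` (shared allele).
    """

    min_run: int = 15
    coverage_threshold: int = 0
    score_fraction: float = 0.6
    control_weight: float = 1.0
    min_patients: int | None = None  # None == all patients
    mode: str = "autozygous"

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ConfigError(f"min_run must be >= 1, got {self.min_run}")
        if not 0 < self.score_fraction <= 1:
            raise ConfigError(f"score_fraction must be in (0, 1], got {self.score_fraction}")
        if self.control_weight < 0:
            raise ConfigError(f"control_weight must be >= 0, got {self.control_weight}")
        if self.mode not in ("homozygous", "autozygous"):
            raise ConfigError(f"mode must be homozygous or autozygous, got {self.mode!r}")
        if self.min_patients is not None and self.min_patients < 1:
            raise ConfigError(f"min_patients must be >= 1, got {self.min_patients}")

    def resolve_min_patients(self, n_patients: int) -> int:
        k = n_patients if self.min_patients is None else self.min_patients
        if k > n_patients:
            raise ConfigError(f"min_patients={k} exceeds the {n_patients} patients given")
        return k


def _pack3(codes: np.ndarray) -> np.ndarray:
    """Pack an array of 3-bit codes (0..5) into a byte array."""
    bits = (codes[:, None] >> np.array([2, 1, 0], dtype=np.uint8)) & 1
    return np.packbits(bits.astype(np.uint8).ravel())


def _unpack3(packed: np.ndarray, n: int) -> np.ndarray:
    bits = np.unpackbits(packed, count=3 * n).reshape(n, 3)
    return (bits[:, 0] << 2 | bits[:, 1] << 1 | bits[:, 2]).astype(np.uint8)


class GenotypeMatrix:
    """Samples x SNV-sites genotype store, 3 bits per genotype.

    Sites are ordered by chromosome (order of first appearance) and
    strictly increasing position within each chromosome; InDels never enter
    the matrix.  Rows are packed per sample with :func:`numpy.packbits`, so
    a 4-sample exome costs ~3 bits per call while row access stays a single
    vectorised unpack.
    """

    def __init__(self, samples: Sequence[str], sites: Sequence[VariantSite],
                 states: np.ndarray) -> None:
        states = np.asarray(states, dtype=np.uint8)
        if states.shape != (len(samples), len(sites)):
            raise ValueError(f"states shape {states.shape} != ({len(samples)}, {len(sites)})")
        if states.size and states.max() > NOCALL_CODE:
            raise ValueError("invalid genotype code > 5")
        self.samples = list(samples)
        self.sites = list(sites)
        for s in self.sites:
            if s.is_indel:
                raise ValueError(f"InDel site {s.chrom}:{s.pos} cannot enter the SNV matrix")
        self._sample_index = {name: i for i, name in enumerate(self.samples)}
        self.positions = np.array([s.pos for s in self.sites], dtype=np.int64)
        # contiguous per-chromosome column blocks, in order of first appearance
        self.chrom_blocks: list[tuple[str, int, int]] = []
        seen: dict[str, int] = {}
        for j, site in enumerate(self.sites):
            if not self.chrom_blocks or site.chrom != self.chrom_blocks[-1][0]:
                if site.chrom in seen:
                    raise ValueError(f"chromosome {site.chrom} appears in two blocks")
                seen[site.chrom] = len(self.chrom_blocks)
                if self.chrom_blocks:
                    c, s0, _ = self.chrom_blocks[-1]
                    self.chrom_blocks[-1] = (c, s0, j)
                self.chrom_blocks.append((site.chrom, j, len(self.sites)))
            elif site.pos <= self.sites[j - 1].pos:
                raise ValueError(
                    f"sites not strictly increasing at {site.chrom}:{site.pos}")
        self._rows = [_pack3(states[i]) for i in range(len(self.samples))]
        self._n_sites = len(self.sites)

    # -- basic access -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self._n_sites

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(
                f"unknown sample {sample!r}; have {', '.join(self.samples)}") from None

    def row_codes(self, sample: str) -> np.ndarray:
        """All state codes for one sample (uint8 array over all sites)."""
        return _unpack3(self._rows[self.sample_index(sample)], self._n_sites)

    def lookup(self, sample: str, site_index: int) -> GenotypeState:
        if not 0 <= site_index < self._n_sites:
            raise IndexError(f"site index {site_index} out of range")
        return GenotypeState(int(self.row_codes(sample)[site_index]))

    def codes_array(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Dense (samples x sites) uint8 code array (decoded view)."""
        names = self.samples if samples is None else list(samples)
        return np.stack([self.row_codes(s) for s in names]) if names else \
            np.empty((0, self._n_sites), dtype=np.uint8)

    def chrom_slice(self, chrom: str) -> slice:
        for c, a, b in self.chrom_blocks:
            if c == chrom:
                return slice(a, b)
        raise KeyError(f"chromosome {chrom!r} not in matrix")

    @property
    def chroms(self) -> list[str]:
        return [c for c, _, _ in self.chrom_blocks]

    # -- (de)serialisation for the ingest cache ---------------------------
    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            version=np.array([1]),
            samples=np.array(self.samples, dtype=object),
            chrom=np.array([s.chrom for s in self.sites], dtype=object),
            pos=self.positions,
            ref=np.array([s.ref for s in self.sites], dtype=object),
            alts=np.array([",".join(s.alts) for s in self.sites], dtype=object),
            states=self.codes_array(),
        )

    @classmethod
    def from_npz(cls, path) -> "GenotypeMatrix":
        with np.load(path, allow_pickle=True) as z:
            if int(z["version"][0]) != 1:
                raise ValueError("unsupported matrix cache version")
            sites = [
                VariantSite(str(c), int(p), str(r), tuple(str(a).split(",")))
                for c, p, r, a in zip(z["chrom"], z["pos"], z["ref"], z["alts"])
            ]
            return cls([str(s) for s in z["samples"]], sites, z["states"])
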