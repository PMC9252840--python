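"""Genome-wide homozygosity score track and candidate-region calling.

The per-marker score S(m) sums, over the patients, the length (in markers)
of the run of homozygosity enclosing m — so long shared runs build tall
plateaus — and subtracts ``control_weight`` times the same sum over the
controls, floored at zero: homozygosity that controls share with the
patients is uninformative for a recessive disease locus.  The relative
score R(m) = S(m)/max(S) is normalised over the whole genome, so exactly
one stretch reaches 1 and candidate regions are called where R exceeds a
fraction of the maximum (default 0.6, strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import ConfigError, GenotypeMatrix
from .roh import SharedRegion, find_sample_runs

__all__ = ["ScoreTrack", "run_length_track", "score_track", "candidate_regions"]


@dataclass(frozen=True)
class ScoreTrack:
    """Raw and max-normalised per-marker homozygosity scores.

    ``raw`` and ``relative`` are arrays over all matrix columns (all
    chromosomes concatenated, in matrix order); ``relative`` is all-zero
    when no marker scores (max(raw) == 0).
    """

    chrom_blocks: tuple[tuple[str, int, int], ...]
    positions: np.ndarray
    raw: np.ndarray
    relative: np.ndarray

    @property
    def max_raw(self) -> float:
        return float(self.raw.max()) if self.raw.size else 0.0

    def chrom_slice(self, chrom: str) -> slice:
        for c, a, b in self.chrom_blocks:
            if c == chrom:
                return slice(a, b)
        raise KeyError(chrom)


def run_length_track(matrix: GenotypeMatrix, sample: str, min_run: int) -> np.ndarray:
    """Per-marker length of the sample's enclosing run (0 outside runs)."""
    track = np.zeros(matrix.n_sites, dtype=np.int64)
    for r in find_sample_runs(matrix, sample, min_run):
        track[r.start_idx:r.end_idx + 1] = r.n_markers
    return track


def score_track(
    matrix: GenotypeMatrix,
    patients: Sequence[str],
    controls: Sequence[str] = (),
    control_weight: float = 1.0,
    min_run: int = 15,
) -> ScoreTrack:
    """Compute S(m) = max(0, sum_p L_p(m) - w * sum_c L_c(m)) and R = S/max(S)."""
    if not patients:
        raise ConfigError("patients list is empty")
    s = np.zeros(matrix.n_sites, dtype=np.float64)
    for p in patients:
        s += run_length_track(matrix, p, min_run)
    for c in controls:
        s -= control_weight * run_length_track(matrix, c, min_run)
    np.maximum(s, 0.0, out=s)
    m = s.max() if s.size else 0.0
    rel = s / m if m > 0 else np.zeros_like(s)
    return ScoreTrack(
        chrom_blocks=tuple(matrix.chrom_blocks),
        positions=matrix.positions.copy(),
        raw=s,
        relative=rel,
    )


def candidate_regions(
    track: ScoreTrack, score_fraction: float = 0.6, min_run: int = 15
) -> list[SharedRegion]:
    """Maximal intervals with relative score strictly above ``score_fraction``.

    Intervals shorter than ``min_run`` markers are dropped; an all-zero
    track yields no candidates.  Returned in genomic order as score-mode
    regions (no supporting-patient bookkeeping).
    """
    if not 0 < score_fraction <= 1:
        raise ConfigError(f"score_fraction must be in (0, 1], got {score_fraction}")
    above = track.relative > score_fraction
    out: list[SharedRegion] = []
    for chrom, a, b in track.chrom_blocks:
        sub = above[a:b]
        if not sub.any():
            continue
        padded = np.concatenate(([False], sub, [False]))
        d = np.diff(padded.astype(np.int8))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1) - 1):
            if e - s + 1 < min_run:
                continue
            lo, hi = a + int(s), a + int(e)
            out.append(SharedRegion(
                chrom=chrom, start_idx=lo, end_idx=hi,
                start_bp=int(track.positions[lo]), end_bp=int(track.positions[hi]),
                n_markers=hi - lo + 1, mode="homozygous",
                supporting_patients=(),
                score_max=float(track.relative[lo:hi + 1].max()),
            ))
    return out


def attach_scores(regions: Sequence[SharedRegion], track: ScoreTrack) -> list[SharedRegion]:
    """Return regions with ``score_max`` filled from the relative track."""
    from dataclasses import replace

    out = []
    for r in regions:
        sub = track.relative[r.start_idx:r.end_idx + 1]
        out.append(replace(r, score_max=float(sub.max()) if sub.size else 0.0))
    return out
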