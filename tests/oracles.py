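"""Independent brute-force oracles for interval detection.

These deliberately avoid the package's vectorised diff/mask machinery:
everything is itertools.groupby and per-marker Python loops, so agreement
with the implementation is a genuine cross-check rather than the same code
twice.
"""

from __future__ import annotations

from itertools import groupby

HET = 4
NOCALL = 5


def oracle_runs(codes, blocks, min_run):
    """Maximal non-HET stretches >= min_run as (chrom, start, end) index triples."""
    out = []
    for chrom, a, b in blocks:
        i = a
        for compat, grp in groupby(codes[a:b], key=lambda c: c != HET):
            n = len(list(grp))
            if compat and n >= min_run:
                out.append((chrom, i, i + n - 1))
            i += n
    return out


def oracle_support_intervals(masks, blocks, k, min_run):
    """Maximal intervals where >= k of the boolean masks are True per marker."""
    support = [sum(m[j] for m in masks) >= k for j in range(len(masks[0]))]
    out = []
    for chrom, a, b in blocks:
        i = a
        for ok, grp in groupby(support[a:b]):
            n = len(list(grp))
            if ok and n >= min_run:
                out.append((chrom, i, i + n - 1))
            i += n
    return out


def oracle_inrun_mask(codes, blocks, min_run):
    """Per-marker in-run flags derived from oracle_runs."""
    mask = [False] * len(codes)
    for _, s, e in oracle_runs(codes, blocks, min_run):
        for j in range(s, e + 1):
            mask[j] = True
    return mask


def oracle_concordant_site(column):
    """Allele concordance for one site: HOM codes must agree, NOCALL wild."""
    bases = {c for c in column if c < 4}
    return len(bases) <= 1


def oracle_refine(region_start, region_end, per_patient_codes, inrun_masks,
                  chrom, min_run):
    """Split [region_start, region_end] at discordant sites, groupby-style."""
    concord = []
    for j in range(region_start, region_end + 1):
        col = [codes[j] for codes, m in zip(per_patient_codes, inrun_masks)
               if m[j]]
        concord.append(oracle_concordant_site(col))
    out = []
    i = region_start
    for ok, grp in groupby(concord):
        n = len(list(grp))
        if ok and n >= min_run:
            out.append((chrom, i, i + n - 1))
        i += n
    return out


def oracle_candidates(relative, blocks, fraction, min_run):
    """Maximal stretches with relative score strictly above the fraction."""
    above = [r > fraction for r in relative]
    return oracle_support_intervals([above], blocks, 1, min_run)


def oracle_run_length_track(codes, blocks, min_run):
    """Per-marker enclosing-run length via the groupby oracle."""
    track = [0] * len(codes)
    for _, s, e in oracle_runs(codes, blocks, min_run):
        for j in range(s, e + 1):
            track[j] = e - s + 1
    return track
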