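"""Shared fixtures and the compact genotype-string notation used in tests.

Matrices are written as strings, one per sample, e.g. ``"AAAH..G"``:
``A/C/G/T`` = homozygous for that base, ``H`` = heterozygous,
``.`` = no-call.  Positions default to 10, 20, 30, ... on chr1.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from autozygomap.genotypes import GenotypeMatrix, VariantSite

settings.register_profile("det", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("det")

CHAR_TO_CODE = {
    "A": 0, "C": 1, "G": 2, "T": 3, "H": 4, ".": 5,
}
CODE_TO_CHAR = {v: k for k, v in CHAR_TO_CODE.items()}


def make_matrix(rows, samples=None, chrom="chr1", positions=None,
                chroms=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from genotype strings.

    ``chroms`` may be a list assigning a chromosome per column (columns of
    one chromosome must be contiguous); positions restart per chromosome.
    """
    n_sites = len(rows[0])
    assert all(len(r) == n_sites for r in rows)
    samples = samples or [f"S{i+1}" for i in range(len(rows))]
    if chroms is None:
        chroms = [chrom] * n_sites
    if positions is None:
        positions, counter, prev = [], 0, None
        for c in chroms:
            counter = counter + 10 if c == prev else 10
            prev = c
            positions.append(counter)
    sites = [VariantSite(c, p, "A", ("G",)) for c, p in zip(chroms, positions)]
    states = np.array([[CHAR_TO_CODE[ch] for ch in row] for row in rows],
                      dtype=np.uint8)
    return GenotypeMatrix(samples, sites, states)


def random_rows(rng, n_samples, n_sites, p_het=0.35, p_nocall=0.1):
    """Random genotype strings with tunable HET/no-call mix."""
    out = []
    for _ in range(n_samples):
        chars = []
        for _ in range(n_sites):
            u = rng.random()
            if u < p_het:
                chars.append("H")
            elif u < p_het + p_nocall:
                chars.append(".")
            else:
                chars.append("ACGT"[rng.integers(0, 4)])
        out.append("".join(chars))
    return out


@pytest.fixture
def quartet_matrix():
    """2 patients sharing a homozygous-A run (cols 2..21), parents HET-rich."""
    shared = "A" * 20
    p1 = "HH" + shared + "HGH"
    p2 = "GH" + shared + "HHT"
    dad = "HAHHHAHAHHHAHHAHAHHHAHHHG"
    mom = "AHHAHHHAHAHHHAHHAHHAHHHHA"
    return make_matrix([p1, p2, dad, mom],
                       samples=["P1", "P2", "F", "M"])
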