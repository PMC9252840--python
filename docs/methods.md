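# Methods

## Genotype model

Each sample's call at a biallelic-or-multiallelic single-base SNV is
collapsed to one of six states: homozygous for A, C, G or T, heterozygous,
or no-call. Collapsing to the *base* (rather than the allele index) makes
the four homozygous states comparable across sites and call sets, which is
the prerequisite for testing autozygosity: two patients are compatible with
identity by descent at a site only if their homozygous genotypes carry the
same base. States are stored bit-packed at 3 bits per genotype
(`numpy.packbits`), one packed row per sample, so a WES-scale matrix stays
small and a whole sample row decodes in a single vectorised operation.

Classification rules:

* two equal non-missing alleles → HOM(base); two unequal → HET;
* haploid calls (`1`) → HOM — hemizygous stretches (heterozygous deletions,
  sex chromosomes) thus appear as ordinary homozygosity, which is the
  desired behaviour for mapping;
* any missing allele, including half-calls (`./1`), → no-call: a single
  observed allele cannot establish homozygosity;
* a call whose FORMAT/DP is below `coverage_threshold` → no-call,
  regardless of GT. The threshold defaults to 0 (disabled); when enabled
  but DP is absent, calls are taken at face value rather than silently
  discarded (logged once).

No-calls are *run-compatible* wildcards: they never interrupt a run of
homozygosity and they are concordant with any homozygous base. Two
consequences are intentional. First, stretches of missing genotypes at zero
coverage — homozygous deletions — are detected as runs, which can itself be
diagnostic. Second, isolated dropouts cannot fragment a real IBD segment.
The cost is that a long low-coverage region can masquerade as a run; the
`min_run` marker threshold (below) is the guard against this.

InDels (any ref/alt that is not a plain single base, including symbolic
alleles) are kept out of the genotype matrix entirely — their open-ended
allele space defeats the fixed six-state encoding and they are more prone
to alignment artefacts — but are retained verbatim and re-emerge in the
region-restricted VCF export.

## Runs, shared regions, autozygous segments

A **run of homozygosity** is a maximal stretch of run-compatible markers of
at least `min_run = 15` consecutive markers (default), flanked by a
heterozygous call or a chromosome end. The marker threshold, rather than a
bp threshold, protects against spurious "long" regions supported by only a
few genotypes flanking a coverage gap. Runs consisting entirely of no-calls
are retained (`n_called` may be 0) for the deletion-detection behaviour
above.

**Shared homozygous regions** are maximal marker intervals at which at
least `min_patients` patients (default: all) lie inside one of their own
runs, again subject to `min_run`. `min_run` is applied uniformly to
per-sample runs, shared regions, and autozygous segments. The
`supporting_patients` recorded for a region are those whose runs cover the
whole region; with the default `min_patients = all` this is exactly the
patient set.

**Autozygous segments** are produced by splitting each shared region at
every site where the in-run patients' homozygous calls disagree on the
base. Concordance at a site is evaluated over the patients inside a run at
that site (no-calls wildcard); the discordant marker itself is excluded
from both flanking sub-segments, mirroring the display convention in which
a discordant site terminates the autozygous part. Sub-segments below
`min_run` are dropped. Hence autozygous output is always contained in the
homozygous output for the same inputs — a property the test suite asserts
on randomised matrices.

Region boundaries in bp are the positions of the first and last supporting
markers; no extension toward flanking heterozygous markers is applied.
Regions are ranked by physical length (`end_bp − start_bp + 1`)
descending, with ties broken by marker count, then genomic position.
Physical length is the ranking criterion because marker density varies by
orders of magnitude between WES capture targets and WGS.

## Homozygosity score

The per-marker score is

    S(m) = max(0, Σ_patients L_p(m) − control_weight · Σ_controls L_c(m))

where L(m) is the marker length of the sample's run enclosing m (0 outside
runs). This convention — sum of enclosing-run lengths, minus a weighted
control term, floored at zero — is this package's own definition: it makes
long runs shared by many patients dominate, penalises homozygosity that
healthy controls share (uninformative for a recessive locus), and
reproduces the display semantics in which colour intensity grows with run
length. `control_weight` defaults to 1.0; 0 recovers the control-free
track exactly.

The relative score R(m) = S(m)/max S is normalised over the whole genome
(not per chromosome), so exactly one stretch attains R = 1 and relative
heights are comparable across chromosomes. Candidate regions are maximal
stretches with R *strictly* above `score_fraction` (default 0.6) and at
least `min_run` markers. The genome plot highlights exactly the candidate
regions' markers — the highlight set is computed from the same call, so
plot and caller cannot drift apart.

When controls outweigh patients everywhere the track is identically zero;
the relative track is then defined as all-zero and no candidates are
called.

## Exports

* **BED**: 0-based half-open, `name = mode:rank`,
  `score = round(1000·R_max)`; re-parsing reproduces the 1-based inclusive
  region bounds exactly.
* **Region VCF**: the original file filtered at the text level so header
  and records are preserved byte-for-byte (one `##autozygomap_regions=`
  provenance line added). Selection keys on POS only, 1-based inclusive
  region bounds; InDel spans are not extended by REF length. All records
  in a region are exported — InDels and discordant-homozygous SNVs
  included — because the export is a positional filter and the causal
  variant may be any of them. `--longest-only N` restricts to the N
  longest regions by rank.
* **bedGraph**: per-marker score with adjacent equal-valued markers
  merged; gaps between non-adjacent markers are not bridged.

## Synthetic data

The simulator emulates the study design the tool targets: a multi-sample
VCF from a consanguineous nuclear family. Defaults: two affected sibs and
two parent controls; 10,000 uniformly placed SNVs per 100-Mb chromosome;
alt-allele frequencies Uniform(0.05, 0.5) so markers are polymorphic
enough to be informative for ROH detection; genotypes drawn independently
per sample under Hardy–Weinberg outside planted segments; DP ~
Poisson(30). Planted segment types: `autozygous_shared` (one haplotype
drawn per site, all carriers homozygous for it), `homozygous_discordant`
(independent haplotype per carrier), `hemizygous` (haploid GT), and
`homozygous_deletion` (missing GT at DP 0). No-calls, low-DP calls,
HOM↔HET genotype errors, and InDels are layered on at configurable rates
(all default 0 except where a scenario states otherwise). Everything is
deterministic under the spec's seed.

What the simulator does **not** model: linkage disequilibrium, recombination
maps, exome target clustering, pedigree-consistent transmission outside the
planted segment, multi-nucleotide or overlapping variants, and strand or
alignment artefacts. Passing tests therefore demonstrate the interval
logic, the genotype semantics, and the export contracts — not calibrated
performance on real sequencing data, where marker density and error
processes are less benign.

The quartet scenario used by the tests and the acceptance script plants one
500-marker segment in 20,000 SNVs with a 2% no-call rate, fifty seeds;
detection requires reciprocal overlap (intersection over union in bp)
≥ 0.95 with the truth interval. Because background homozygosity can extend
a detected run a few markers past the planted boundary (expected extension
≈ 1/heterozygosity ≈ 2–3 markers per side), overlap very close to but not
exactly 1.0 is the norm.

For mode discrimination, a discordant segment's concordant chunks have
expected length ≈ 1/(per-site discordance) ≈ 3 markers, far below
`min_run`, so the segment is absent or fragmented in autozygous mode; the
check asserts the segment is found in homozygous mode (overlap ≥ 0.8) and
never recovered intact in autozygous mode (no region with overlap ≥ 0.5),
which tolerates the occasional chance concordant chunk reaching `min_run`
inside a long segment.

## Numerical and procedural choices

* Input VCFs must be coordinate-sorted (standard pipeline output);
  sorting in memory would defeat WGS-scale streaming. Unsorted input is a
  fatal data error, as are absent GT FORMAT and a file with no SNV records.
* Duplicate (chrom, pos) SNV records: first kept, warning logged —
  deterministic and conservative.
* Contigs are processed in order of first appearance; no human karyotype
  is assumed, so non-human data works unchanged.
* Phase separators (`|`) are ignored; the mapping is phase-unaware by
  design (unphased IBD detection).
* The ingest cache (`autozygomap ingest --cache`) is a versioned `.npz`
  holding samples, sites, and states; re-mapping different sample subsets
  (per-family analyses under locus heterogeneity) reuses it without
  re-parsing the VCF.
* Problem sizes in the test suite — 1,000 random matrices up to
  5 × 500, fifty 20,000-SNV quartets, one 50,000-variant exome — were
  chosen to exercise every code path at study-representative scale while
  keeping the suite comfortably fast on a single CPU.
* CLI exit codes: 0 success (including zero regions found), 1 data error,
  2 usage or configuration error.

## Known limitations

* No statistical significance measures, LOD scores, or population-
  frequency weighting of markers — the score is a descriptive ranking
  device, and candidate calling is relative to the in-sample maximum, so
  it always highlights *something* when any run exists.
* Genotype likelihoods (PL/GL) are ignored; only GT and DP are consulted.
* The no-call-as-homozygous rule means systematically missing regions
  (e.g. segmental duplications) can produce runs; inspect the grid display
  (grey cells) before believing a region built on no-calls.
* VCF region export filters by POS only; a deletion starting before a
  region boundary but overlapping it is not captured.
* Gene-symbol queries require a user-supplied annotation BED; no gene
  models ship with the package, and no genome-build awareness exists.
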